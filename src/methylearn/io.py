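"""Reading and assembling whole-genome bisulphite methylation calls.

The entry point of the analysis is the per-cytosine CpG report (one file
per sample, Bismark dialect): tab-separated rows of
``chromosome, position, strand, count_methylated, count_unmethylated,
context, trinucleotide`` with no header.  From these the module builds a
sample x CpG matrix of methylation intensities (0-100%), after

* merging the two cytosines of each strand-symmetric CpG dyad into a
  single site addressed by the plus-strand coordinate,
* excluding sites covered by fewer than 10 reads within a sample, and
* taking the union of positions across samples (absent entries are
  missing and may later be mean-imputed).

Sample identifiers follow the field convention
``<PROVENANCE:3 letters><genotype:int><site:IH|PA><tissue:X|L>[M][Rep]``,
e.g. ``POR12IHX`` or ``ROS1PAL``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_COVERAGE = 10

CPG = "CpG"
CONTEXTS = frozenset({"CpG", "CHG", "CHH"})

_SAMPLE_NAME_RE = re.compile(
    r"^(?P<provenance>[A-Z]{3})"
    r"(?P<genotype>\d+)"
    r"(?P<site>IH|PA)"
    r"(?P<tissue>X|L)"
    r"(?P<mature>M)?"
    r"(?P<rep>Rep)?$"
)


class SampleNameError(ValueError):
    """Raised when a sample identifier does not follow the naming convention."""


class CytosineReportError(ValueError):
    """Raised on a malformed row in a per-cytosine report."""


class CytosineRecord(NamedTuple):
    """One cytosine call: counts of methylated / unmethylated reads."""

    chrom: str
    pos: int  # 1-based
    strand: str  # '+' or '-'
    count_meth: int
    count_unmeth: int
    context: str  # CpG | CHG | CHH

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass(frozen=True)
class SampleMetadata:
    """Decomposition of a sample identifier into its design factors."""

    sample_id: str
    provenance: str
    genotype: int
    site: str
    tissue: str
    mature_leaf: bool = False
    technical_rep: bool = False

    def to_name(self) -> str:
        return (
            f"{self.provenance}{self.genotype}{self.site}{self.tissue}"
            f"{'M' if self.mature_leaf else ''}"
            f"{'Rep' if self.technical_rep else ''}"
        )


def parse_sample_name(name: str) -> SampleMetadata:
    """Parse a sample identifier such as ``POR12IHX`` or ``ROS1PAL``.

    The first three letters are the provenance code, the following number
    the genotype within that provenance, then the common-garden site
    (``IH`` or ``PA``) and the tissue (``X`` xylem, ``L`` leaf), with
    optional ``M`` (mature leaf) and ``Rep`` (technical replicate)
    suffixes.  Re-serialising the result reproduces the input.
    """
    if not name:
        raise SampleNameError("empty sample name")
    m = _SAMPLE_NAME_RE.match(name)
    if m is None:
        raise SampleNameError(
            f"sample name {name!r} does not match "
            "<PROV><genotype><IH|PA><X|L>[M][Rep]"
        )
    return SampleMetadata(
        sample_id=name,
        provenance=m.group("provenance"),
        genotype=int(m.group("genotype")),
        site=m.group("site"),
        tissue=m.group("tissue"),
        mature_leaf=m.group("mature") is not None,
        technical_rep=m.group("rep") is not None,
    )


def read_cytosine_report(path: str | Path) -> Iterator[CytosineRecord]:
    """Stream records from a Bismark-dialect CpG report.

    Rows are tab-separated with columns chromosome, 1-based position,
    strand, methylated count, unmethylated count, context and
    trinucleotide.  Non-CpG contexts are retained (flagged via
    ``context``); downstream strand merging drops them.
    """
    path = Path(path)
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CytosineReportError(
                    f"{path}:{lineno}: expected >= 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise CytosineReportError(
                    f"{path}:{lineno}: non-integer field ({exc})"
                ) from None
            if pos < 1:
                raise CytosineReportError(f"{path}:{lineno}: position {pos} < 1")
            if meth < 0 or unmeth < 0:
                raise CytosineReportError(
                    f"{path}:{lineno}: negative read count"
                )
            if strand not in ("+", "-"):
                raise CytosineReportError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            if context not in CONTEXTS:
                raise CytosineReportError(
                    f"{path}:{lineno}: unknown context {context!r}"
                )
            yield CytosineRecord(chrom, pos, strand, meth, unmeth, context)


def merge_strand_symmetric(
    records: Iterable[CytosineRecord],
) -> Iterator[CytosineRecord]:
    """Collapse each palindromic CpG dyad to one plus-strand site.

    Counts of the plus-strand cytosine at position ``p`` and the
    minus-strand cytosine at ``p + 1`` are summed into a single record at
    ``p`` (strand ``+``).  Unpaired records pass through (a lone
    minus-strand call is re-addressed to ``p - 1``).  Non-CpG contexts
    are dropped.  Input must be sorted by (chromosome, position).
    """
    pending: CytosineRecord | None = None
    last_key: tuple[str, int] | None = None
    for rec in records:
        if rec.context != CPG:
            continue
        key = (rec.chrom, rec.pos)
        if last_key is not None and key < last_key:
            raise ValueError(
                f"records not sorted by (chrom, pos): {key} after {last_key}"
            )
        last_key = key
        if pending is not None:
            if (
                rec.strand == "-"
                and rec.chrom == pending.chrom
                and rec.pos == pending.pos + 1
            ):
                yield CytosineRecord(
                    pending.chrom,
                    pending.pos,
                    "+",
                    pending.count_meth + rec.count_meth,
                    pending.count_unmeth + rec.count_unmeth,
                    CPG,
                )
                pending = None
                continue
            yield pending
            pending = None
        if rec.strand == "+":
            pending = rec
        else:
            # lone minus-strand cytosine: address its dyad by the + position
            yield CytosineRecord(
                rec.chrom,
                max(rec.pos - 1, 1),
                "+",
                rec.count_meth,
                rec.count_unmeth,
                CPG,
            )
    if pending is not None:
        yield pending


def position_id(chrom: str, pos: int) -> str:
    """Render the canonical ``Chrom.pos`` site identifier (e.g. Chr05.8103103)."""
    return f"{chrom}.{pos}"


def split_position_id(pid: str) -> tuple[str, int]:
    chrom, _, pos = pid.rpartition(".")
    return chrom, int(pos)


def compute_intensities(
    records: Iterable[CytosineRecord],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> dict[str, float]:
    """Per-site methylation intensity, 100 * meth / coverage.

    Sites covered by fewer than ``min_coverage`` reads are excluded
    (treated as missing), the standard prefilter for noisy proportion
    estimates from low read depth.
    """
    out: dict[str, float] = {}
    for rec in records:
        cov = rec.coverage
        if cov < min_coverage:
            continue
        out[position_id(rec.chrom, rec.pos)] = 100.0 * rec.count_meth / cov
    return out


@dataclass
class MethylomeMatrix:
    """Sample x CpG matrix of methylation intensities (percent, NaN = missing).

    Wraps a :class:`pandas.DataFrame` with samples as rows and
    ``Chrom.pos`` site identifiers as columns, sorted by genomic
    coordinate.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.columns.duplicated().any():
            raise ValueError("duplicate position ids")
        if df.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = df.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 100))
        if bad:
            raise ValueError("intensities must lie in [0, 100] or be missing")
        order = sorted(df.columns, key=split_position_id)
        if list(df.columns) != order:
            self.data = df.loc[:, order]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def position_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def missing_fraction(self) -> float:
        n = self.data.size
        return self.n_missing() / n if n else 0.0

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylomeMatrix":
        return MethylomeMatrix(self.data.loc[list(sample_ids)].copy())

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MethylomeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA")
        df.index.name = None
        return cls(df)


def assemble_matrix(
    intensity_maps: Mapping[str, Mapping[str, float]]
    | Sequence[tuple[str, Mapping[str, float]]],
) -> MethylomeMatrix:
    """Assemble per-sample intensity maps into one matrix.

    Columns are the union of positions over all samples; a (sample,
    position) pair absent from its map is missing.  Duplicate sample ids
    are an error.
    """
    if isinstance(intensity_maps, Mapping):
        items = list(intensity_maps.items())
    else:
        items = list(intensity_maps)
    if not items:
        raise ValueError("need at least one sample")
    seen: set[str] = set()
    for sid, _ in items:
        if sid in seen:
            raise ValueError(f"duplicate sample id {sid!r}")
        seen.add(sid)
    positions: set[str] = set()
    for _, m in items:
        positions.update(m.keys())
    cols = sorted(positions, key=split_position_id)
    col_index = {c: i for i, c in enumerate(cols)}
    values = np.full((len(items), len(cols)), np.nan)
    for r, (_, m) in enumerate(items):
        for pid, v in m.items():
            values[r, col_index[pid]] = v
    df = pd.DataFrame(values, index=[sid for sid, _ in items], columns=cols)
    return MethylomeMatrix(df)


def impute_missing(matrix: MethylomeMatrix) -> MethylomeMatrix:
    """Replace missing entries by the column mean over observed samples.

    Imputation is performed within the given matrix only: callers that
    keep training and test samples independent impute the two subsets
    separately so no statistic crosses the split.
    """
    df = matrix.data
    all_missing = df.columns[df.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            "cannot impute all-missing column(s): "
            + ", ".join(all_missing[:5])
            + ("..." if len(all_missing) > 5 else "")
        )
    values = df.to_numpy(dtype=float)
    col_means = np.nanmean(values, axis=0)
    filled = np.where(np.isnan(values), col_means[None, :], values)
    return MethylomeMatrix(
        pd.DataFrame(filled, index=df.index, columns=df.columns)
    )


def import_reports(
    directory: str | Path,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    pattern: str = "*.CpG_report.txt",
) -> MethylomeMatrix:
    """Read every cytosine report in a directory into one intensity matrix.

    The sample id is the file name up to the first dot.
    """
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} files under {directory}")
    maps = []
    for f in files:
        sid = f.name.split(".", 1)[0]
        records = merge_strand_symmetric(read_cytosine_report(f))
        maps.append((sid, compute_intensities(records, min_coverage)))
    return assemble_matrix(maps)


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV, or derive one from sample ids if absent."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "provenance", "genotype", "site", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return df


def metadata_from_sample_ids(sample_ids: Iterable[str]) -> pd.DataFrame:
    """Build a metadata table by parsing each sample identifier."""
    rows = [parse_sample_name(s).__dict__ for s in sample_ids]
    return pd.DataFrame(rows)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a per-tree trait TSV keyed by (provenance, genotype, site)."""
    df = pd.read_csv(path, sep="\t")
    required = {"provenance", "genotype", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    return df
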