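"""Synthetic methylome studies with planted, recoverable structure.

The generator emulates the statistical regime of a two-common-garden
tree methylome study: a balanced design of provenances x genotypes x
sites x tissues, a bimodal baseline CpG methylation landscape, planted
tissue-, provenance- and trait-associated CpG, binomial read-sampling
noise on Poisson coverage with a minimum-coverage filter, and uniform
missingness on top.  Every downstream stage of the pipeline (parsing,
differential methylation, model fitting, interpretation) can therefore
be exercised against a known ground truth without any sequencing data.

Latent methylation model, per CpG ``j`` and sample ``s``::

    base_j       ~ two-component Beta mixture on (0, 1)
    p_det        = clip(base_j + shift_pp(s, j) / 100, 0.001, 0.999)
    logit(p)     = logit(p_det) + trait_load(s, j) + eps(s, j)
    latent       = sigmoid(logit(p))

where ``shift_pp`` carries the planted tissue and provenance effects in
percentage points, ``trait_load`` is a per-tree factor loading on the
trait-associated CpG (shared by both tissues of a tree unless the
effect is restricted to one tissue), and ``eps`` is logit-scale
biological noise.  Observed data are ``coverage ~ Poisson(mean)``,
``meth ~ Binomial(coverage, latent)``, intensity ``100 * meth /
coverage``; entries with coverage below 10 reads or hit by the
missingness mask are absent.

Provenance-associated CpG place the provenance classes at latent levels
ordered along one fixed class sequence (the generator's analogue of an
optimal ordering of classes with respect to methylation level), which is
what lets response-curve interpretation recover a class sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    DEFAULT_MIN_COVERAGE,
    MethylomeMatrix,
    position_id,
)

#: Provenance codes used for synthetic designs, in the fixed class
#: sequence along which provenance-associated CpG are ordered.
PROVENANCE_CODES = ("LOV", "SOU", "FRE", "WHR", "BOY", "WOL", "ROS", "LAR", "POR")


class ConfigurationError(ValueError):
    """Raised when a synthetic study configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic methylome study.

    Defaults are scaled-down study conditions: 9 provenances, balanced
    genotypes replicated over two sites and two tissues, 20,000 CpG with
    200 planted CpG per effect class, a 25-percentage-point tissue
    effect, Poisson(30) coverage and 3.1% missingness.
    """

    n_provenances: int = 9
    genotypes_per_provenance: int = 2
    sites: tuple[str, ...] = ("IH", "PA")
    tissues: tuple[str, ...] = ("X", "L")
    n_cpg: int = 20_000
    n_tissue_cpg: int = 200
    n_provenance_cpg: int = 200
    n_trait_cpg: int = 200
    tissue_effect: float = 25.0  # percentage points between the two tissues
    provenance_effect_step: float = 7.0  # pp between adjacent provenance classes
    trait_effect: float = 0.25  # trait units per percentage point
    #: (low-mode mean, high-mode mean, concentration, weight of low mode)
    baseline_mixture: tuple[float, float, float, float] = (0.08, 0.85, 12.0, 0.45)
    mean_coverage: float = 30.0
    missing_rate: float = 0.031
    trait_noise_sd: float = 0.5  # trait units
    trait_intercept: float = 11.4  # trait units (population mean)
    sample_noise_sd: float = 0.35  # logit-scale biological noise per methylome
    trait_loading_sd: float = 0.8  # logit-scale per-tree loading on trait CpG
    trait_tissue: str | None = None  # restrict trait-CpG effect to one tissue
    min_coverage: int = DEFAULT_MIN_COVERAGE
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_provenances,
            self.genotypes_per_provenance,
            self.n_cpg,
            self.n_tissue_cpg,
            self.n_provenance_cpg,
            self.n_trait_cpg,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("counts must be nonnegative")
        if self.n_tissue_cpg + self.n_provenance_cpg + self.n_trait_cpg > self.n_cpg:
            raise ConfigurationError("planted CpG classes exceed n_cpg")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.n_provenances > len(PROVENANCE_CODES):
            raise ConfigurationError(
                f"at most {len(PROVENANCE_CODES)} provenances supported"
            )
        if len(self.tissues) != 2:
            raise ConfigurationError("design requires exactly two tissues")
        if self.trait_tissue is not None and self.trait_tissue not in self.tissues:
            raise ConfigurationError("trait_tissue must be one of the tissues")
        if self.mean_coverage < 0:
            raise ConfigurationError("mean_coverage must be nonnegative")

    @property
    def provenances(self) -> tuple[str, ...]:
        return PROVENANCE_CODES[: self.n_provenances]

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sites"] = list(self.sites)
        d["tissues"] = list(self.tissues)
        d["baseline_mixture"] = list(self.baseline_mixture)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("sites", "tissues", "baseline_mixture"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticStudy:
    """A simulated study: intensity matrix, design tables and ground truth.

    ``truth`` maps each effect class (``tissue``, ``provenance``,
    ``trait``) to the planted CpG position ids; ``counts`` retains the
    read-level data so cytosine reports can be written and round-tripped.
    """

    config: SyntheticConfig
    matrix: MethylomeMatrix
    metadata: pd.DataFrame
    traits: pd.DataFrame
    truth: dict[str, list[str]]
    latent: np.ndarray  # (n_samples, n_cpg) latent methylation proportions
    coverage: np.ndarray  # (n_samples, n_cpg) int read coverage
    meth_counts: np.ndarray  # (n_samples, n_cpg) int methylated reads
    dropped_mask: np.ndarray  # True where the missingness mask removed the site

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids

    @property
    def position_ids(self) -> list[str]:
        return self.matrix.position_ids

    def write_truth(self, path: str | Path) -> None:
        rows = [
            {"effect_class": cls, "position_id": pid}
            for cls, pids in self.truth.items()
            for pid in pids
        ]
        pd.DataFrame(rows, columns=["effect_class", "position_id"]).to_csv(
            path, sep="\t", index=False
        )


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _make_positions(n_cpg: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Spread CpG over 19 chromosomes with >= 2 bp between dyad starts."""
    if n_cpg == 0:
        return []
    n_chrom = min(19, n_cpg)
    per = np.full(n_chrom, n_cpg // n_chrom)
    per[: n_cpg % n_chrom] += 1
    positions: list[tuple[str, int]] = []
    for c, count in enumerate(per, start=1):
        gaps = rng.integers(10, 500, size=count)
        pos = np.cumsum(gaps) + 100
        positions.extend((f"Chr{c:02d}", int(p)) for p in pos)
    return positions


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Simulate a complete methylome study from a configuration.

    Deterministic given ``config.seed``: repeated calls return
    bit-identical studies.
    """
    rng = np.random.default_rng(config.seed)
    provs = config.provenances
    samples: list[dict] = []
    for prov in provs:
        for g in range(1, config.genotypes_per_provenance + 1):
            for site in config.sites:
                for tissue in config.tissues:
                    samples.append(
                        {
                            "sample_id": f"{prov}{g}{site}{tissue}",
                            "provenance": prov,
                            "genotype": g,
                            "site": site,
                            "tissue": tissue,
                            "mature_leaf": False,
                            "technical_rep": False,
                        }
                    )
    metadata = pd.DataFrame(
        samples,
        columns=[
            "sample_id",
            "provenance",
            "genotype",
            "site",
            "tissue",
            "mature_leaf",
            "technical_rep",
        ],
    )
    n_samples = len(metadata)
    n_cpg = config.n_cpg

    coords = _make_positions(n_cpg, rng)
    pids = [position_id(c, p) for c, p in coords]

    # disjoint planted CpG index sets
    n_planted = config.n_tissue_cpg + config.n_provenance_cpg + config.n_trait_cpg
    planted = rng.choice(n_cpg, size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    tissue_idx = np.sort(planted[: config.n_tissue_cpg])
    prov_idx = np.sort(
        planted[config.n_tissue_cpg : config.n_tissue_cpg + config.n_provenance_cpg]
    )
    trait_idx = np.sort(planted[config.n_tissue_cpg + config.n_provenance_cpg :])

    # baseline beta mixture (per CpG)
    lo, hi, conc, w_lo = config.baseline_mixture
    low_mode = rng.random(n_cpg) < w_lo
    means = np.where(low_mode, lo, hi)
    base = rng.beta(means * conc, (1.0 - means) * conc) if n_cpg else np.empty(0)
    base = np.clip(base, 1e-3, 1.0 - 1e-3)

    # deterministic percentage-point shifts (tissue + provenance effects)
    shift_pp = np.zeros((n_samples, n_cpg))
    tissue_sign = np.where(
        metadata["tissue"].to_numpy() == config.tissues[0], 0.5, -0.5
    )
    if len(tissue_idx):
        shift_pp[:, tissue_idx] += np.outer(
            tissue_sign, np.full(len(tissue_idx), config.tissue_effect)
        )
    prov_rank = metadata["provenance"].map({p: i for i, p in enumerate(provs)})
    prov_centered = prov_rank.to_numpy() - (len(provs) - 1) / 2.0
    if len(prov_idx):
        shift_pp[:, prov_idx] += np.outer(
            prov_centered, np.full(len(prov_idx), config.provenance_effect_step)
        )

    # per-tree loading on trait CpG, shared across tissues of a tree
    tree_key = metadata["provenance"] + metadata["genotype"].astype(str) + metadata["site"]
    trees = sorted(tree_key.unique())
    tree_index = tree_key.map({t: i for i, t in enumerate(trees)}).to_numpy()
    tree_score = rng.normal(0.0, 1.0, size=len(trees))
    trait_load = np.zeros((n_samples, n_cpg))
    if len(trait_idx):
        loading = np.full(len(trait_idx), config.trait_loading_sd)
        per_sample_score = tree_score[tree_index]
        if config.trait_tissue is not None:
            in_tissue = (metadata["tissue"] == config.trait_tissue).to_numpy()
            per_sample_score = np.where(in_tissue, per_sample_score, 0.0)
        trait_load[:, trait_idx] = np.outer(per_sample_score, loading)

    p_det = np.clip(base[None, :] + shift_pp / 100.0, 1e-3, 1.0 - 1e-3)
    eps = rng.normal(0.0, config.sample_noise_sd, size=(n_samples, n_cpg))
    latent = _sigmoid(_logit(p_det) + trait_load + eps)
    latent = np.clip(latent, 1e-3, 1.0 - 1e-3)

    coverage = rng.poisson(config.mean_coverage, size=(n_samples, n_cpg))
    meth = rng.binomial(coverage, latent)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(coverage > 0, 100.0 * meth / np.maximum(coverage, 1), np.nan)

    dropped = rng.random((n_samples, n_cpg)) < config.missing_rate
    observed = (coverage >= config.min_coverage) & ~dropped
    values = np.where(observed, intensity, np.nan)

    matrix = MethylomeMatrix(
        pd.DataFrame(values, index=metadata["sample_id"].tolist(), columns=pids)
    )

    # quantitative trait per tree from the causal latent methylation (the
    # tree-level trait loading, independent of tissue / read sampling)
    trait_rows = []
    trait_noise = rng.normal(0.0, config.trait_noise_sd, size=len(trees))
    if len(trait_idx):
        base_trait = base[trait_idx]
        causal_pct = np.empty(len(trees))
        for t in range(len(trees)):
            z = _logit(np.clip(base_trait, 1e-3, 1 - 1e-3)) + tree_score[t] * config.trait_loading_sd
            causal_pct[t] = 100.0 * _sigmoid(z).mean()
        causal_centered = causal_pct - causal_pct.mean()
    else:
        causal_pct = np.zeros(len(trees))
        causal_centered = causal_pct
    for t, tree in enumerate(trees):
        row = metadata.loc[tree_index == t].iloc[0]
        biomass = (
            config.trait_intercept
            + config.trait_effect * causal_centered[t]
            + trait_noise[t]
        )
        trait_rows.append(
            {
                "provenance": row["provenance"],
                "genotype": row["genotype"],
                "site": row["site"],
                "biomass": biomass,
                "density": biomass * 0.02 + rng.normal(0.35, 0.02),
                "soluble_lignin": rng.normal(3.5, 0.4),
                "mannose": rng.normal(2.2, 0.3),
                "causal_methylation": causal_pct[t],
            }
        )
    traits = pd.DataFrame(trait_rows)

    truth = {
        "tissue": [pids[i] for i in tissue_idx],
        "provenance": [pids[i] for i in prov_idx],
        "trait": [pids[i] for i in trait_idx],
    }
    return SyntheticStudy(
        config=config,
        matrix=matrix,
        metadata=metadata,
        traits=traits,
        truth=truth,
        latent=latent,
        coverage=coverage,
        meth_counts=meth,
        dropped_mask=dropped,
    )


def write_cytosine_reports(study: SyntheticStudy, directory: str | Path) -> list[Path]:
    """Write one Bismark-dialect CpG report per sample.

    Counts at each dyad are split between the plus-strand cytosine at
    ``pos`` and the minus-strand cytosine at ``pos + 1`` so the reader's
    strand merging is exercised; merging restores the totals exactly.
    Sites removed by the missingness mask are omitted from their file;
    sites below the coverage filter are written and excluded again on
    read.  Reading the files back reproduces ``study.matrix`` exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coords = [pid.rpartition(".") for pid in study.position_ids]
    written: list[Path] = []
    for s, sid in enumerate(study.sample_ids):
        path = directory / f"{sid}.CpG_report.txt"
        with path.open("w") as out:
            for j, (chrom, _, pos_s) in enumerate(coords):
                if study.dropped_mask[s, j]:
                    continue
                pos = int(pos_s)
                m = int(study.meth_counts[s, j])
                u = int(study.coverage[s, j]) - m
                m_plus, m_minus = m // 2, m - m // 2
                u_plus, u_minus = u // 2, u - u // 2
                out.write(
                    f"{chrom}\t{pos}\t+\t{m_plus}\t{u_plus}\tCpG\tCGA\n"
                    f"{chrom}\t{pos + 1}\t-\t{m_minus}\t{u_minus}\tCpG\tCGT\n"
                )
        written.append(path)
    return written
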