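"""Per-CpG differential methylation and feature-selection strategies.

Each CpG is tested for a mean intensity difference between two groups of
methylomes with Welch's unequal-variance t-test; p-values are adjusted
across the tested family with the Benjamini-Hochberg step-up FDR
procedure.  Selections feed the model input layer and come in four
flavours: by significance thresholds, by a target feature count (the
FDR cutoff is searched to hit, e.g., 8000 +/- 100 CpG), by pooling the
top of several tests, or uniformly at random as a negative control.
Quantitative traits are turned into two groups by splitting at the
training mean (strictly-above vs. the rest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MethylomeMatrix, split_position_id


class GroupError(ValueError):
    """Raised on invalid group definitions for a two-group test."""


class SelectionError(ValueError):
    """Raised when a requested CpG selection cannot be constructed."""


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, its degrees of freedom and p.

    ``t = (mean(a) - mean(b)) / sqrt(s2a/na + s2b/nb)`` with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value from
    Student's t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise GroupError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise GroupError("both groups have zero variance: statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def test_all_cpg(
    matrix: MethylomeMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Welch's t-test at every CpG between two disjoint sample groups.

    Returns a DataFrame indexed like the matrix columns with columns
    ``position_id, t, df, p, q``; ``q`` is BH-adjusted over the tested
    family.  Columns where both groups have zero variance have an
    undefined statistic: they are excluded from the family and reported
    with NaN statistics (a warning states how many were skipped).
    """
    df = matrix.data if isinstance(matrix, MethylomeMatrix) else matrix
    group_a = list(group_a)
    group_b = list(group_b)
    if set(group_a) & set(group_b):
        raise GroupError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise GroupError("each group needs at least 2 samples")
    A = df.loc[group_a].to_numpy(dtype=float)
    B = df.loc[group_b].to_numpy(dtype=float)
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("matrix contains missing values; impute first")

    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    defined = (va > 0) | (vb > 0)
    n_skipped = int((~defined).sum())
    if n_skipped:
        warnings.warn(
            f"{n_skipped} position(s) with zero variance in both groups "
            "skipped and excluded from the FDR family"
        )

    t = np.full(df.shape[1], np.nan)
    dfree = np.full(df.shape[1], np.nan)
    p = np.full(df.shape[1], np.nan)
    if defined.any():
        with warnings.catch_warnings():
            # near-identical columns trigger a scipy precision warning; the
            # zero-variance family exclusion above already handles the
            # genuinely degenerate cases
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                A[:, defined], B[:, defined], axis=0, equal_var=False
            )
        t[defined] = res.statistic
        dfree[defined] = res.df
        p[defined] = res.pvalue
    q = np.full(df.shape[1], np.nan)
    if defined.any():
        q[defined] = bh_fdr(p[defined])
    return pd.DataFrame(
        {
            "position_id": df.columns,
            "t": t,
            "df": dfree,
            "p": p,
            "q": q,
        }
    )


@dataclass
class CpGSelection:
    """An ordered set of CpG sites defining a model's input features."""

    position_ids: list[str]
    origin: str  # differential | random | pooled | fixed
    stats: pd.DataFrame | None = None
    selection_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.position_ids)) != len(self.position_ids):
            raise SelectionError("position ids must be unique")

    def __len__(self) -> int:
        return len(self.position_ids)

    def to_tsv(self, path) -> None:
        if self.stats is not None:
            sub = self.stats.set_index("position_id").loc[self.position_ids]
            out = sub.reset_index()
        else:
            out = pd.DataFrame({"position_id": self.position_ids})
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        out.to_csv(path, sep="\t", index=False)


def _ordered_by_significance(results: pd.DataFrame) -> pd.DataFrame:
    """Order by ascending q, then p, then position id (deterministic ties)."""
    return results.sort_values(
        ["q", "p", "position_id"], kind="mergesort"
    )


def select_by_significance(
    results: pd.DataFrame,
    alpha: float = 0.01,
    fdr_cutoff: float = 1.0,
) -> CpGSelection:
    """Keep positions with ``p <= alpha`` and ``q <= fdr_cutoff``."""
    if results.empty:
        raise SelectionError("no test results to select from")
    keep = results[(results["p"] <= alpha) & (results["q"] <= fdr_cutoff)]
    keep = _ordered_by_significance(keep)
    if keep.empty:
        warnings.warn("selection is empty at the given thresholds")
    return CpGSelection(
        position_ids=keep["position_id"].tolist(),
        origin="differential",
        stats=results,
        selection_params={"alpha": alpha, "fdr_cutoff": fdr_cutoff},
    )


def select_to_count(
    results: pd.DataFrame,
    target: int,
    tolerance: int = 0,
    alpha: float = 0.01,
) -> CpGSelection:
    """Find an FDR cutoff yielding ``target +/- tolerance`` positions.

    Bisection over the achievable counts (the sorted q values of
    positions passing ``p <= alpha``); ties in q are kept or dropped
    together, so the nearest achievable counts are reported when the
    target cannot be hit within tolerance.
    """
    if results.empty:
        raise SelectionError("no test results to select from")
    eligible = _ordered_by_significance(results[results["p"] <= alpha])
    n = len(eligible)
    if target - tolerance > n:
        raise SelectionError(
            f"target {target} (- tolerance {tolerance}) exceeds the {n} "
            f"positions with p <= {alpha}"
        )
    target = min(target, n)
    q = eligible["q"].to_numpy()
    # count achievable at cutoff q[k-1] is the number of q <= q[k-1]
    counts = np.searchsorted(q, q, side="right")
    achievable = np.unique(counts)
    idx = int(np.argmin(np.abs(achievable - target)))
    best = int(achievable[idx])
    if abs(best - target) > tolerance:
        lower = achievable[achievable < target]
        upper = achievable[achievable > target]
        raise SelectionError(
            f"no FDR cutoff yields {target} +/- {tolerance} positions; "
            f"nearest achievable counts: "
            f"{int(lower[-1]) if len(lower) else 'none'} below, "
            f"{int(upper[0]) if len(upper) else 'none'} above"
        )
    cutoff = float(q[best - 1]) if best > 0 else 0.0
    chosen = eligible.iloc[:best]
    return CpGSelection(
        position_ids=chosen["position_id"].tolist(),
        origin="differential",
        stats=results,
        selection_params={
            "alpha": alpha,
            "target_count": target,
            "tolerance": tolerance,
            "fdr_cutoff": cutoff,
        },
    )


def dichotomize_at_mean(
    values: Mapping[str, float] | pd.Series,
) -> tuple[list[str], list[str]]:
    """Split samples into (strictly above mean, at-or-below mean) groups.

    The "high" group is strictly above the mean; values exactly at the
    mean fall to the "low" complement.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 4:
        raise GroupError("need at least 4 values to dichotomize")
    if s.nunique() == 1:
        raise GroupError("all values equal: cannot dichotomize")
    mean = s.mean()
    high = s.index[s > mean].tolist()
    low = s.index[s <= mean].tolist()
    return high, low


def pooled_selection(
    selections: Sequence[CpGSelection], counts: Sequence[int]
) -> CpGSelection:
    """Union of the top-q ``counts[i]`` positions of each selection.

    Duplicates keep their first occurrence; origin is ``pooled``.
    """
    if len(selections) != len(counts):
        raise SelectionError("selections and counts must align")
    pooled: list[str] = []
    seen: set[str] = set()
    for sel, k in zip(selections, counts):
        if k > len(sel):
            raise SelectionError(
                f"requested {k} positions from a selection of {len(sel)}"
            )
        for pid in sel.position_ids[:k]:
            if pid not in seen:
                seen.add(pid)
                pooled.append(pid)
    return CpGSelection(
        position_ids=pooled,
        origin="pooled",
        selection_params={"counts": list(counts)},
    )


def random_selection(
    universe: Sequence[str], n: int, seed: int
) -> CpGSelection:
    """Uniform selection of ``n`` positions without replacement."""
    universe = list(universe)
    if n > len(universe):
        raise SelectionError(f"cannot draw {n} from a universe of {len(universe)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(universe), size=n, replace=False)
    return CpGSelection(
        position_ids=[universe[i] for i in chosen],
        origin="random",
        selection_params={"n": n, "seed": seed},
    )
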