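"""Cohort-level statistics for deviation parameters.

Per-group descriptive summaries (median, IQR with linear-interpolation
quantiles, range), a paired Wilcoxon signed-rank comparison with a
Hodges-Lehmann location estimate and distribution-based 95% CI, and the
Spearman rank correlation.

The signed-rank test is implemented with an exact tie-aware null
distribution for n <= 25 paired differences (zeros dropped, mid-ranks
for ties, null distribution by generating-function convolution over the
2^n sign assignments) and a normal approximation with continuity and
tie corrections for larger n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, spearmanr

from dentasym.geometry import PROFILE_PARAMETERS

__all__ = [
    "CohortSummary",
    "PairedComparison",
    "CohortResult",
    "summarize",
    "wilcoxon_paired",
    "spearman",
    "run_cohort_analysis",
]

EXACT_MAX_N = 25


@dataclass(frozen=True)
class CohortSummary:
    parameter: str
    group: str
    n: int
    median: float
    iqr: float
    range_min: float
    range_max: float


@dataclass(frozen=True)
class PairedComparison:
    p_value: float
    median_difference_estimate: float
    ci95: tuple[float, float]
    n_nonzero: int
    method: str  # "exact" | "approx"


@dataclass(frozen=True)
class CohortResult:
    summaries: list[CohortSummary]
    comparison: PairedComparison
    spearman_r: float
    compared_group: str


def summarize(values: Sequence[float], parameter: str = "", group: str = "") -> CohortSummary:
    """Median, IQR (linear-interpolation quantiles) and range of *values*."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return CohortSummary(
        parameter=parameter,
        group=group,
        n=int(v.size),
        median=float(med),
        iqr=float(q3 - q1),
        range_min=float(v.min()),
        range_max=float(v.max()),
    )


def _signed_rank_null_cdf(ranks: np.ndarray) -> np.ndarray:
    """Exact null pmf of the positive-rank sum W for given mid-ranks.

    Mid-ranks are half-integers at worst; doubling makes them integers
    and W's support a lattice, enumerated by convolving the per-pair
    generating functions (1 + t^{2 r_i}) / 2.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(pmf)
        shifted[d:] = pmf[: total + 1 - d]
        pmf = 0.5 * (pmf + shifted)
    return pmf  # index = 2W


def _exact_two_sided_p(ranks: np.ndarray, w: float) -> float:
    pmf = _signed_rank_null_cdf(ranks)
    idx = int(round(2 * w))
    p_le = float(pmf[: idx + 1].sum())
    p_ge = float(pmf[idx:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def _walsh_averages(diffs: np.ndarray) -> np.ndarray:
    sums = diffs[:, None] + diffs[None, :]
    return np.sort(sums[np.triu_indices(len(diffs))] / 2.0)


def wilcoxon_paired(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05, exact: bool | None = None
) -> PairedComparison:
    """Two-sided paired Wilcoxon signed-rank test with Hodges-Lehmann CI.

    Zero differences are dropped before ranking (signed-rank
    convention); ties receive mid-ranks.  *exact* forces the exact or
    approximate null; the default uses exact for n <= 25 nonzero
    differences.  The location estimate is the median of the Walsh
    averages of the differences, with a distribution-based CI.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    diffs = xv - yv
    nonzero = diffs[diffs != 0.0]
    n = nonzero.size
    if n == 0:
        return PairedComparison(1.0, 0.0, (0.0, 0.0), 0, "degenerate")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")

    ranks = rankdata(np.abs(nonzero))
    w_pos = float(ranks[nonzero > 0].sum())
    use_exact = exact if exact is not None else n <= EXACT_MAX_N

    if use_exact:
        p = _exact_two_sided_p(ranks, w_pos)
        method = "exact"
    else:
        mean_w = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts**3 - counts) / 48.0).sum())
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        delta = w_pos - mean_w
        z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var_w) if var_w > 0 else 0.0
        p = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "approx"

    walsh = _walsh_averages(diffs)  # all differences, zeros included
    estimate = float(np.median(walsh))
    m = walsh.size

    # CI from the signed-rank null on the nonzero-diff count: the CI is
    # [walsh_(k), walsh_(m+1-k)] with k the largest order statistic whose
    # coverage reaches 1 - alpha.
    if use_exact:
        pmf = _signed_rank_null_cdf(rankdata(np.arange(1, n + 1)))
        cdf = np.cumsum(pmf)
        # lattice index = 2W; critical value on W for lower tail
        k_w = 0
        for idx in range(len(cdf)):
            if cdf[idx] <= alpha / 2.0:
                k_w = idx / 2.0
            else:
                break
        k = int(k_w) + 1
    else:
        mean_w = n * (n + 1) / 4.0
        sd_w = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        k = int(math.floor(mean_w - norm.ppf(1 - alpha / 2.0) * sd_w)) + 1
    k = max(1, min(k, (m + 1) // 2))
    ci = (float(walsh[k - 1]), float(walsh[m - k]))
    return PairedComparison(p, estimate, ci, n, method)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1 or xv.size < 3:
        raise ValueError("x and y must be 1-D, equal length, n >= 3")
    if np.unique(xv).size < 2 or np.unique(yv).size < 2:
        raise ValueError("correlation undefined: zero rank variance")
    r = spearmanr(xv, yv).statistic
    return float(r)


def run_cohort_analysis(
    profiles: pd.DataFrame,
    compared_group: str = "A",
    min_group_n: int = 5,
) -> CohortResult:
    """Per-group summaries of all parameters plus the paired midline comparison.

    *profiles* holds one row per subject with columns ``subject``,
    ``group`` and the seven parameter names.  The Wilcoxon comparison
    and Spearman correlation relate the dental-midline deviation
    (``dentMid_facMP``) to the skeletal-midline deviation at the same
    level (``maxMP_facMP_at_dentMid``) within *compared_group*.
    """
    missing = [c for c in ("subject", "group", *PROFILE_PARAMETERS) if c not in profiles]
    if missing:
        raise ValueError(f"profiles table lacks columns: {missing}")

    summaries = [
        summarize(sub[param].to_numpy(), parameter=param, group=str(grp))
        for grp, sub in profiles.groupby("group", sort=True)
        for param in PROFILE_PARAMETERS
    ]

    grp = profiles[profiles["group"] == compared_group]
    if len(grp) < min_group_n:
        raise ValueError(
            f"group {compared_group!r} has {len(grp)} subjects; need >= {min_group_n}"
        )
    dent = grp["dentMid_facMP"].to_numpy()
    skel = grp["maxMP_facMP_at_dentMid"].to_numpy()
    comparison = wilcoxon_paired(dent, skel)
    rho = spearman(dent, skel)
    return CohortResult(summaries, comparison, rho, compared_group)


def comparison_report(result: CohortResult) -> Mapping[str, object]:
    """JSON-ready report of the paired comparison and correlation."""
    return {
        "compared_group": result.compared_group,
        "wilcoxon_p": result.comparison.p_value,
        "median_difference": result.comparison.median_difference_estimate,
        "ci95_low": result.comparison.ci95[0],
        "ci95_high": result.comparison.ci95[1],
        "n_nonzero": result.comparison.n_nonzero,
        "method": result.comparison.method,
        "spearman_r": result.spearman_r,
    }
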