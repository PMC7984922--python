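"""Split-GFR combination and rater-agreement statistics.

Two things live here: the precise split-GFR formula

    pGFR_left  = gGFR'_left  / (gGFR'_left + gGFR'_right) × tGFR
    pGFR_right = gGFR'_right / (gGFR'_left + gGFR'_right) × tGFR

which apportions the plasma-clearance total between the kidneys using the
blank-background Gates ratio, and the statistics used to evaluate it:
tie-corrected Kendall's coefficient of concordance W across raters and the
Pearson correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import RaterTable, SplitGfrResult

__all__ = [
    "ConcordanceResult",
    "CorrelationResult",
    "split_pgfr",
    "kendalls_w",
    "pearson_r",
    "rater_study",
]


@dataclass
class ConcordanceResult:
    """Kendall's W with its chi-square approximation."""

    w: float
    chi2: float
    df: int
    p_value: float
    tie_corrected: bool
    n_subjects: int
    n_raters: int


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float


def split_pgfr(ggfr_left_prime: float, ggfr_right_prime: float, tgfr: float) -> SplitGfrResult:
    """Apportion a total GFR between kidneys by the gGFR' ratio.

    The right-kidney value is computed as ``tgfr − pgfr_left`` so that the
    conservation ``pgfr_left + pgfr_right == tgfr`` holds exactly in
    floating point (the two forms agree to rounding).
    """
    if ggfr_left_prime < 0 or ggfr_right_prime < 0:
        raise ValueError("per-kidney gGFR' values must be non-negative")
    if tgfr < 0:
        raise ValueError("tGFR must be non-negative")
    total = ggfr_left_prime + ggfr_right_prime
    if total == 0:
        raise ValueError("no renal uptake to apportion")
    frac_left = ggfr_left_prime / total
    pgfr_left = frac_left * tgfr
    pgfr_right = tgfr - pgfr_left
    return SplitGfrResult(
        pgfr_left=pgfr_left,
        pgfr_right=pgfr_right,
        tgfr=tgfr,
        split_fraction_left=frac_left,
    )


def _tie_term(ranks: np.ndarray) -> float:
    """Σ(t³ − t) over the tie groups of one rater's ranks."""
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kendalls_w(
    table: RaterTable,
    tie_correction: bool = True,
    p_method: str = "chi2",
) -> ConcordanceResult:
    """Kendall's coefficient of concordance across raters.

    Subjects are ranked within each rater (average ranks for ties); with
    rank sums ``R_i`` and ``S = Σ(R_i − R̄)²``,

        W = 12·S / (m²(n³ − n) − m·ΣT),   T = Σ(t³ − t) per rater,

    and the tie term is dropped when ``tie_correction`` is off.  The
    p-value is the upper tail of ``χ² = m(n−1)·W`` with ``n−1`` degrees of
    freedom; ``p_method="exact"`` enumerates all rater orderings instead
    (tie-free tables with a small enumeration space only).

    Raises
    ------
    ValueError
        For invalid tables, and for constant tables where every rater ties
        all subjects, which leaves W undefined.
    """
    bad = table.violations()
    if bad:
        raise ValueError("; ".join(bad))
    X = table.values
    n, m = X.shape
    ranks = np.apply_along_axis(sps.rankdata, 0, X)
    R = ranks.sum(axis=1)
    S = float(np.sum((R - R.mean()) ** 2))
    tie_sum = sum(_tie_term(ranks[:, j]) for j in range(m))
    denom = m * m * (n**3 - n) - (m * tie_sum if tie_correction else 0.0)
    if denom <= 0:
        raise ValueError(
            "Kendall's W is undefined: every rater ties all subjects (constant table)"
        )
    w = 12.0 * S / denom
    chi2 = m * (n - 1) * w
    df = n - 1
    if p_method == "chi2":
        p = float(sps.chi2.sf(chi2, df))
    elif p_method == "exact":
        p = _exact_w_pvalue(ranks, w, tie_correction)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return ConcordanceResult(
        w=w,
        chi2=chi2,
        df=df,
        p_value=p,
        tie_corrected=tie_correction,
        n_subjects=n,
        n_raters=m,
    )


def _exact_w_pvalue(ranks: np.ndarray, w_obs: float, tie_correction: bool) -> float:
    """Permutation p-value: W is invariant to a common relabelling of
    subjects, so one rater is held fixed and the others range over all n!
    orderings.  Tie-free tables only."""
    n, m = ranks.shape
    if any(_tie_term(ranks[:, j]) > 0 for j in range(m)):
        raise ValueError("exact p-value supports tie-free tables only")
    n_perm = math.factorial(n) ** (m - 1)
    if n_perm > 500_000:
        raise ValueError("exact p-value enumeration too large; use p_method='chi2'")
    base = np.arange(1.0, n + 1)
    denom = m * m * (n**3 - n)
    count = total = 0
    for perms in itertools.product(itertools.permutations(base), repeat=m - 1):
        R = base + np.sum(np.asarray(perms), axis=0)
        wp = 12.0 * float(np.sum((R - R.mean()) ** 2)) / denom
        count += wp >= w_obs - 1e-12
        total += 1
    return count / total


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    ``r²`` is the (always non-negative) square of ``r``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), r_squared=float(res.statistic) ** 2,
                             p_value=float(res.pvalue))


def rater_study(
    per_rater_values: Sequence[Sequence[float]],
    subject_ids: Optional[Sequence] = None,
    rater_ids: Optional[Sequence] = None,
    tie_correction: bool = True,
) -> ConcordanceResult:
    """Concordance across raters from one value vector per rater.

    Each rater must cover the same subjects in the same order (per-kidney
    values may be stacked as separate subjects upstream).
    """
    lengths = {len(v) for v in per_rater_values}
    if len(lengths) != 1:
        raise ValueError("raters cover different subject sets")
    values = np.column_stack([np.asarray(v, dtype=float) for v in per_rater_values])
    table = RaterTable(values=values, subject_ids=subject_ids, rater_ids=rater_ids)
    return kendalls_w(table, tie_correction=tie_correction)
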