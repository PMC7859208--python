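"""Statistical primitives shared across the pipeline.

Set-overlap measures (Jaccard index, one-sided hypergeometric overlap test),
the two-group Wilcoxon rank-sum test, simple linear regression, residualization,
and Benjamini-Hochberg FDR adjustment.

Conventions
-----------
* The Wilcoxon statistic ``W`` is the Mann-Whitney U of the *first* sample:
  the number of pairs ``(x_i, y_j)`` with ``x_i > y_j``, ties counting 1/2.
  Two-group rank tests are conventionally reported under this convention.
* The hypergeometric overlap p-value is the upper tail
  ``P(X >= |A ∩ B|)`` with ``X ~ Hypergeometric(N=|universe|, K=|A|, n=|B|)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OverlapResult",
    "OLSFit",
    "jaccard",
    "hypergeom_overlap_test",
    "wilcoxon_rank_sum",
    "ols",
    "residuals_on",
    "bh_adjust",
]


@dataclass(frozen=True)
class OverlapResult:
    """Jaccard index and hypergeometric overlap test between two gene sets."""

    jaccard: float
    overlap: int
    size_a: int
    size_b: int
    universe: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "jaccard": self.jaccard,
            "overlap": self.overlap,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "universe": self.universe,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class OLSFit:
    """Simple linear regression fit (one predictor plus intercept)."""

    slope: float
    intercept: float
    stderr: float
    p_value: float
    pearson_r: float
    residuals: np.ndarray = field(repr=False)


def jaccard(a: set, b: set) -> float:
    """Jaccard index ``|A ∩ B| / |A ∪ B|``; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def hypergeom_overlap_test(a: set, b: set, universe: set) -> float:
    """One-sided (enrichment) hypergeometric test of the overlap of two sets.

    Returns the upper-tail probability of observing at least ``|A ∩ B|``
    elements in common when ``|B|`` elements are drawn from the universe
    without replacement.
    """
    a, b, universe = set(a), set(b), set(universe)
    if not a <= universe:
        raise ValueError(f"set A has {len(a - universe)} members outside the universe")
    if not b <= universe:
        raise ValueError(f"set B has {len(b - universe)} members outside the universe")
    overlap = len(a & b)
    # sf(k-1) = P(X >= k)
    return float(sps.hypergeom.sf(overlap - 1, len(universe), len(a), len(b)))


def overlap_result(a: set, b: set, universe: set) -> OverlapResult:
    """Bundle :func:`jaccard` and :func:`hypergeom_overlap_test`."""
    p = hypergeom_overlap_test(a, b, universe)
    a, b = set(a), set(b)
    return OverlapResult(
        jaccard=jaccard(a, b),
        overlap=len(a & b),
        size_a=len(a),
        size_b=len(b),
        universe=len(set(universe)),
        p_value=p,
    )


_EXACT_LIMIT = 400  # n_x * n_y at or below this (and tie-free) -> exact p


def wilcoxon_rank_sum(x, y) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(W, p, method)`` where ``W`` is the Mann-Whitney U statistic of
    ``x`` (pairs with ``x_i > y_j``, ties as 1/2) and ``method`` reports the
    regime used: ``"exact"`` for tie-free samples with ``n_x * n_y <= 400``,
    otherwise ``"asymptotic"`` (normal approximation with tie and continuity
    corrections).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and x.size * y.size <= _EXACT_LIMIT
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue), "exact" if exact else "asymptotic"


def ols(y, x) -> OLSFit:
    """Simple OLS of ``y`` on ``x`` with an intercept.

    The slope standard error uses residual variance on ``n - 2`` degrees of
    freedom and the p-value is the two-sided t-test of zero slope. The Pearson
    correlation of ``(x, y)`` is included alongside the fit.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if y.size < 3:
        raise ValueError("at least 3 points are required")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    fit = sps.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    return OLSFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr=float(fit.stderr),
        p_value=float(fit.pvalue),
        pearson_r=float(fit.rvalue),
        residuals=resid,
    )


def residuals_on(y, x) -> np.ndarray:
    """Residuals of the OLS regression of ``y`` on ``x`` (mean ~ 0)."""
    return ols(y, x).residuals


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
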