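"""Hypothesis tests for comparing expression and score distributions.

Two-group comparisons use the Mann–Whitney U rank-sum test (exact null
enumeration for small tie-free samples, tie-corrected normal approximation
otherwise); multi-group comparisons use Kruskal–Wallis.  Parametric
counterparts — one-way ANOVA across cell lines / treatments and the paired
t-test for within-sample treatment contrasts — are included because the
mitochondrial-expression comparisons are run on per-sample aggregates.
Sidedness is always an explicit argument, never inferred from the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: combined sample size at or below which the Mann–Whitney p is computed by
#: exact enumeration of rank assignments (tie-free data only)
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    sidedness: str
    group_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_arrays(*groups):
    out = [np.asarray(g, dtype=float) for g in groups]
    for g in out:
        if g.size == 0:
            raise ValueError("empty group")
    return out


def mann_whitney_u(a, b, alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U test of a vs b.

    ``alternative='greater'`` tests whether values in ``a`` tend to exceed
    those in ``b``.  Exact enumeration when the combined size is ≤ 12 and
    the data are tie-free; tie-corrected normal approximation otherwise.
    All values tied across both groups degenerates to p = 1.
    """
    a, b = _as_arrays(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("Mann–Whitney: all values identical; p = 1")
        return TestResult("mann-whitney-u", len(a) * len(b) / 2.0, 1.0,
                          alternative, (len(a), len(b)))
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= EXACT_MW_LIMIT and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult("mann-whitney-u", float(res.statistic), float(res.pvalue),
                      alternative, (len(a), len(b)))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H test across ≥ 2 groups (tie-corrected, χ² on k−1 df)."""
    groups = _as_arrays(*groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal-wallis", 0.0, 1.0, "two-sided",
                          tuple(len(g) for g in groups))
    h, p = stats.kruskal(*groups)
    return TestResult("kruskal-wallis", float(h), float(p), "two-sided",
                      tuple(len(g) for g in groups))


def one_way_anova(groups) -> TestResult:
    """One-way ANOVA F test across ≥ 2 groups of n ≥ 2 each.

    Zero within-group variance everywhere with unequal means is logged and
    reported as p = 0 (infinite F); with equal means it is F = 0, p = 1.
    """
    groups = _as_arrays(*groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n ≥ 2")
    sizes = tuple(len(g) for g in groups)
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = [g.mean() for g in groups]
    if within == 0:
        if np.allclose(means, means[0]):
            return TestResult("one-way-anova", 0.0, 1.0, "two-sided", sizes)
        logger.warning("ANOVA: zero within-group variance with unequal means; p = 0")
        return TestResult("one-way-anova", np.inf, 0.0, "two-sided", sizes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    return TestResult("one-way-anova", float(f), float(p), "two-sided", sizes)


def paired_t_test(a, b, alternative: str = "two-sided") -> TestResult:
    """Paired t-test on the per-pair differences a − b (n−1 df).

    Zero-variance differences: p = 1 if the mean difference is 0, else an
    error (the t statistic is unbounded and no finite p is meaningful).
    """
    a, b = _as_arrays(a, b)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.all(diff == diff[0]):
        if diff[0] == 0:
            return TestResult("paired-t", 0.0, 1.0, alternative, (len(a), len(b)))
        raise ValueError("zero-variance nonzero differences: t is unbounded")
    res = stats.ttest_rel(a, b, alternative=alternative)
    return TestResult("paired-t", float(res.statistic), float(res.pvalue),
                      alternative, (len(a), len(b)))


def aggregate_mito_expression(matrix, how: str = "sum") -> np.ndarray:
    """Per-sample total (or mean) expression of the mitochondrial genes."""
    mito = matrix.mitochondrial()
    if mito.n_genes == 0:
        raise ValueError("matrix has no mitochondrial genes")
    values = mito.values()
    if how == "sum":
        return values.sum(axis=0)
    if how == "mean":
        return values.mean(axis=0)
    raise ValueError(f"unknown aggregation {how!r}")
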