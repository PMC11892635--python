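"""Nonparametric tests and Pearson correlation with exact small-sample behavior."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TestResult", "wilcoxon_rank_sum", "kruskal_wallis", "pearson",
           "benjamini_hochberg"]

# exact two-sided rank-sum p only when total n is small and rank ties are absent
_EXACT_MAX_N = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when ``len(x)+len(y) <= 12`` and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(float(x.size * y.size) / 2.0, 1.0,
                          "wilcoxon_rank_sum_normal", (x.size, y.size))
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= _EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "wilcoxon_rank_sum_exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        method = "wilcoxon_rank_sum_normal"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      method, (x.size, y.size))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >=2 groups, each with >=1 observation")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis", tuple(g.size for g in groups))
    res = stats.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "kruskal_wallis", tuple(g.size for g in groups))


def pearson(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "pearson", (x.size,))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (off by default everywhere; opt-in)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float))
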