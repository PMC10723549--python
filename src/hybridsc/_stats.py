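"""Shared statistical primitives: rank tests, fold changes, p adjustment."""

from __future__ import annotations

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_sum_pvalues",
    "mann_whitney_greater",
    "log2_fold_change",
    "bonferroni",
    "bh_adjust",
    "welch_t",
]


def rank_sum_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values per column of ``a`` vs ``b``.

    Exact null distribution (full enumeration) is used automatically for
    small tie-free groups; the tie-corrected normal approximation otherwise.
    """
    res = scipy.stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    return np.atleast_1d(res.pvalue)


def mann_whitney_greater(a, b) -> float:
    """One-sided (a stochastically greater than b) Mann-Whitney p-value."""
    return float(scipy.stats.mannwhitneyu(a, b, alternative="greater").pvalue)


def log2_fold_change(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """Seurat-convention log2 fold change between groups of log1p values.

    ``log2(mean(expm1(a)) + 1) - log2(mean(expm1(b)) + 1)`` per gene, so the
    sign and scale match the thresholds the field quotes (|lfc| >= 1 etc.).
    """
    mean_a = np.expm1(norm_a).mean(axis=0)
    mean_b = np.expm1(norm_b).mean(axis=0)
    return np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)


def bonferroni(p: np.ndarray, n: int | None = None) -> np.ndarray:
    n = len(p) if n is None else n
    return np.minimum(1.0, np.asarray(p, dtype=float) * n)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: ``(t, df, two-sided p)``.

    Uses the unequal-variance statistic with Welch-Satterthwaite degrees of
    freedom.  Requires at least two values per group and some variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("both groups have zero variance")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
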