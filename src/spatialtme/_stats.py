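"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptyGroupError


def geomean(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.exp(np.mean(np.log(x))))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when both samples are small and tie-free, otherwise the normal
    approximation with tie correction (scipy's `auto` policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyGroupError("both groups must be non-empty for the rank-sum test")
    if np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(min(res.pvalue, 1.0))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with tie-corrected ranks and two-sided p."""
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
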