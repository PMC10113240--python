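"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats


def rank_sum_test(x, y) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value.

    Exact null distribution when both groups have <= 10 observations and
    the pooled data carry no ties; normal approximation with tie
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires two non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def round_half_away(x) -> np.ndarray:
    """Round half away from zero (2.5 -> 3), elementwise."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)
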