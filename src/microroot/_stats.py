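"""Shared statistical primitives.

Small-sample rank tests are computed by exact enumeration over the pooled
values (so ties are handled without approximation); larger arms use the
tie-corrected normal approximation. Benjamini-Hochberg adjustment wraps
statsmodels.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: both arms at or below this size use exact enumeration
EXACT_MAX_ARM = 8


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def rank_sum_exact_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumeration of all arm assignments.

    Enumerates every C(n1+n2, n1) split of the pooled sample, computes the
    rank sum of the first arm under midranks (ties allowed), and doubles the
    smaller tail probability, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    n = len(pooled)
    total = 0
    n_ge = 0
    n_le = 0
    eps = 1e-9
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if w >= w_obs - eps:
            n_ge += 1
        if w <= w_obs + eps:
            n_le += 1
    p = 2.0 * min(n_ge, n_le) / total
    return min(1.0, p)


def rank_sum_test(x, y) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both arms have <= 8 observations, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both arms must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(x) <= EXACT_MAX_ARM and len(y) <= EXACT_MAX_ARM:
        return rank_sum_exact_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def signed_rank_test(x, center: float) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p of x against a center."""
    d = np.asarray(x, dtype=float) - center
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    mode = "exact" if len(d) <= 25 and len(np.unique(np.abs(d))) == len(d) else "approx"
    return float(stats.wilcoxon(d, alternative="two-sided", mode=mode).pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    flat = p.ravel()
    q = multipletests(flat, method="fdr_bh")[1]
    return q.reshape(p.shape)


def pearson_with_p(a, b) -> tuple[float, float]:
    """Pearson r with the two-sided p from the t transform.

    Raises on zero variance in either vector.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def robust_effect(strain_vals, control_vals) -> float:
    """Standardized median difference: (median_s - median_c) / MAD_c.

    MAD is scaled by 1.4826 to be SD-consistent under normality. A zero MAD
    falls back to the pooled SD of both arms; if that is also zero the effect
    is 0 (all values tied).
    """
    x = np.asarray(strain_vals, dtype=float)
    c = np.asarray(control_vals, dtype=float)
    diff = np.median(x) - np.median(c)
    scale = stats.median_abs_deviation(c, scale="normal")
    if scale == 0:
        scale = np.concatenate([x, c]).std(ddof=1)
    if scale == 0:
        return 0.0
    return float(diff / scale)
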