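"""Shared statistical helpers used across modules.

The cohort-level convention throughout the pipeline is non-parametric:
Mann-Whitney U for two groups, Kruskal-Wallis for three or more, Spearman
rank correlation for associations, Benjamini-Hochberg for multiplicity.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "mann_whitney_p",
    "kruskal_p",
    "spearman_grid",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    flat = p.ravel()
    ok = np.isfinite(flat)
    q = np.full(flat.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    return q.reshape(p.shape)


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value; 1.0 for degenerate (constant) input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return 1.0
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def kruskal_p(*groups) -> float:
    """Kruskal-Wallis p-value; 1.0 for degenerate input."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if pooled.size == 0 or np.ptp(pooled) == 0:
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def spearman_grid(A: np.ndarray, B: np.ndarray):
    """Pairwise tie-corrected Spearman correlation between columns of A and B.

    Returns (r, p) arrays of shape (A.shape[1], B.shape[1]).  Constant
    columns yield NaN entries (undefined rank correlation).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValueError("A and B must be 2-D with matching row counts")
    ka, kb = A.shape[1], B.shape[1]
    r = np.full((ka, kb), np.nan)
    p = np.full((ka, kb), np.nan)
    const_a = np.ptp(A, axis=0) == 0
    const_b = np.ptp(B, axis=0) == 0
    for i in range(ka):
        if const_a[i]:
            continue
        for j in range(kb):
            if const_b[j]:
                continue
            res = stats.spearmanr(A[:, i], B[:, j])
            r[i, j] = res.statistic
            p[i, j] = res.pvalue
    return r, p
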