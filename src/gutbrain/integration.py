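"""Cross-omics integration: NMDS, Procrustes/PROTEST, dbRDA, Spearman
grids, and multivariable regression.

Procrustes uses the symmetric statistic (both configurations centered and
scaled to unit total variance before the optimal rotation), so the
residual M^2 lies in [0, 1]; PROTEST significance comes from seeded row
permutations of the second configuration.  dbRDA regresses the positive
principal-coordinate axes of a distance matrix on constraint variables.
Regression confidence intervals use t-quantiles (small-n practice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import procrustes as _scipy_procrustes
from sklearn.manifold import MDS

from ._stats import bh_adjust, spearman_grid
from .microbiome import pcoa


def nmds(
    d: pd.DataFrame, k: int = 2, seed: int | None = None, n_restarts: int = 10
) -> dict:
    """Non-metric multidimensional scaling of a distance matrix.

    Kruskal stress-1 is minimized by iterative majorization (SMACOF) with
    monotone regression; the best of ``n_restarts`` seeded starts is
    returned with its stress.
    """
    if seed is None:
        raise ValueError("a seed is required")
    n = d.shape[0]
    if n < k + 2:
        raise ValueError("need at least k + 2 samples")
    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
        eps=1e-9,
    )
    coords = mds.fit_transform(np.asarray(d, dtype=float))
    labels = list(d.index) if isinstance(d, pd.DataFrame) else list(range(n))
    return {
        "coordinates": pd.DataFrame(
            coords, index=labels, columns=[f"NMDS{i+1}" for i in range(k)]
        ),
        "stress": float(mds.stress_),
        "converged": bool(mds.n_iter_ < 500),
    }


@dataclass
class ProcrustesResult:
    m2: float
    p: float
    n_perm: int


def _procrustes_m2(X: np.ndarray, Y: np.ndarray) -> float:
    # scipy's disparity is the symmetric statistic: both matrices are
    # centered, scaled to unit sum of squares, and optimally superimposed.
    _, _, disparity = _scipy_procrustes(X, Y)
    return float(disparity)


def procrustes_protest(
    X: pd.DataFrame, Y: pd.DataFrame, n_perm: int = 10000, seed: int | None = None
) -> ProcrustesResult:
    """Symmetric Procrustes M^2 with PROTEST permutation significance.

    Rows must be matched (same labels).  p = (1 + #{permuted M^2 <=
    observed}) / (1 + n_perm) under row permutations of Y.
    """
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    if isinstance(X, pd.DataFrame) and isinstance(Y, pd.DataFrame):
        if list(X.index) != list(Y.index):
            raise ValueError("row labels of the two configurations do not match")
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("row counts do not match")
    # with both configurations centered and scaled to unit sum of squares,
    # M^2 = 1 - (sum of singular values of X'Y)^2, so each draw only needs
    # an SVD of the k x k cross-product
    def standardize(M: np.ndarray) -> np.ndarray:
        M = M - M.mean(axis=0)
        return M / np.linalg.norm(M)

    Xs, Ys = standardize(Xa), standardize(Ya)
    m2_obs = 1.0 - np.linalg.svd(Xs.T @ Ys, compute_uv=False).sum() ** 2
    rng = np.random.default_rng(seed)
    n = Xa.shape[0]
    count = 0
    for _ in range(n_perm):
        C = Xs.T @ Ys[rng.permutation(n)]
        m2 = 1.0 - np.linalg.svd(C, compute_uv=False).sum() ** 2
        if m2 <= m2_obs:
            count += 1
    return ProcrustesResult(m2_obs, (1 + count) / (1 + n_perm), n_perm)


@dataclass
class DbRdaResult:
    constrained_proportion: float
    axis_eigenvalues: np.ndarray
    dropped_constraints: list


def db_rda(d: pd.DataFrame, constraints: pd.DataFrame) -> DbRdaResult:
    """Distance-based redundancy analysis.

    Positive-eigenvalue principal coordinates of ``d`` are regressed on
    the constraint matrix; the constrained proportion is the fitted
    variance over the total positive-eigenvalue variance.  Rank-deficient
    constraint columns are dropped with a warning entry in the result.
    """
    if isinstance(constraints, pd.DataFrame) and isinstance(d, pd.DataFrame):
        constraints = constraints.loc[list(d.index)]
    ord_res = pcoa(d)
    pos = ord_res.eigenvalues > 1e-10
    Ypc = ord_res.coordinates.values[:, pos]
    lam = ord_res.eigenvalues[pos]
    Z = np.asarray(constraints, dtype=float)
    n = Z.shape[0]
    # drop constant / collinear columns
    names = list(constraints.columns) if isinstance(constraints, pd.DataFrame) else [
        str(i) for i in range(Z.shape[1])
    ]
    keep, dropped = [], []
    M = np.ones((n, 1))
    for j, name in enumerate(names):
        cand = np.column_stack([M, Z[:, [j]]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(M):
            M = cand
            keep.append(j)
        else:
            dropped.append(name)
    Zk = np.column_stack([np.ones(n), Z[:, keep]]) if keep else np.ones((n, 1))
    # hat-matrix projection of the PCo axes onto the constraint space
    beta, *_ = np.linalg.lstsq(Zk, Ypc, rcond=None)
    fitted = Zk @ beta
    centered = fitted - fitted.mean(axis=0)
    fitted_ss = (centered**2).sum()
    total_ss = lam.sum()
    # eigenvalues of the constrained (fitted) coordinates
    _, s, _ = np.linalg.svd(centered, full_matrices=False)
    return DbRdaResult(
        float(min(fitted_ss / total_ss, 1.0)) if total_ss > 0 else 0.0,
        s**2,
        dropped,
    )


def correlation_grid(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    """Tidy Spearman grid between the columns of two subject-indexed frames.

    Subjects are intersected; BH correction is applied across the full
    grid.  Constant features yield NaN entries.
    """
    common = A.index.intersection(B.index)
    if len(common) < 5:
        raise ValueError("need at least 5 overlapping subjects")
    r, p = spearman_grid(
        A.loc[common].values.astype(float), B.loc[common].values.astype(float)
    )
    q = bh_adjust(p)
    rows = []
    for i, a in enumerate(A.columns):
        for j, b in enumerate(B.columns):
            rows.append({"feature_a": a, "feature_b": b, "r": r[i, j], "p": p[i, j], "q": q[i, j]})
    return pd.DataFrame(rows)


@dataclass
class RegressionFit:
    table: pd.DataFrame  # beta, se, ci_low, ci_high, p per predictor
    n: int
    r2: float


def multivariable_ols(y: pd.Series, X: pd.DataFrame) -> RegressionFit:
    """OLS with an intercept and t-quantile 95% Wald confidence intervals."""
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X).astype(float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        corr = np.abs(np.corrcoef(design.values[:, 1:], rowvar=False))
        np.fill_diagonal(np.atleast_2d(corr), 0)
        raise ValueError(
            f"singular design matrix (rank {rank} < {design.shape[1]}); "
            f"check columns {list(X.columns)}"
        )
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
    return RegressionFit(table, int(fit.nobs), float(fit.rsquared))


def gene_score_association(clinical: pd.DataFrame, alpha_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Named Spearman summary of the gene burden score against severity and diversity.

    Correlates ``gene_score`` with CARS and ABC (and with alpha diversity
    indices when an alpha table is supplied), via the shared correlation
    grid.
    """
    if "gene_score" not in clinical.columns:
        raise ValueError("clinical table has no gene_score column")
    left = clinical[["gene_score"]]
    right = clinical[[c for c in ("CARS", "ABC") if c in clinical.columns]].copy()
    if alpha_table is not None:
        common = clinical.index.intersection(alpha_table.index)
        right = right.loc[common].join(alpha_table.loc[common])
        left = left.loc[common]
    return correlation_grid(left, right)
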