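"""Metabolomics screening and weighted co-expression module detection.

Differential screening (Mann-Whitney volcano with BH correction, PLS-DA
variable importance) and the weighted co-expression pipeline: selection of
the most variable metabolites, soft-threshold choice at a scale-free fit
R^2 >= 0.85, unsigned correlation adjacency raised to the chosen power,
topological overlap matrix (TOM), average-linkage clustering of the TOM
dissimilarity with a minimum-module-size tree cut, size-ranked color
labels, module eigenprofiles (first principal component of the
standardized members), and module-trait Spearman correlation.

The tree cut used here is a static cut of the dendrogram at a high merge
height followed by min-size merging into ``grey`` -- a documented
simplification of adaptive branch cutting; planted-partition recovery, not
equivalence with any particular reference tool, is its correctness
criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.cross_decomposition import PLSRegression

from ._stats import bh_adjust, mann_whitney_p, spearman_grid

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)


def preprocess(m: pd.DataFrame, top_k: int = 1000) -> pd.DataFrame:
    """log(1+x) transform and retain the ``top_k`` most variable metabolites.

    ``m`` is samples x metabolites with non-negative intensities.  top_k
    larger than the metabolite count is clamped with a warning.
    """
    if (m.values < 0).any():
        raise ValueError("intensities must be non-negative")
    logged = np.log1p(m)
    if top_k > m.shape[1]:
        warnings.warn(f"top_k={top_k} exceeds metabolite count {m.shape[1]}; clamped")
        top_k = m.shape[1]
    variances = logged.var(axis=0, ddof=1)
    order = variances.sort_values(ascending=False, kind="stable").index[:top_k]
    # preserve original column order among the selected
    selected = [c for c in m.columns if c in set(order)]
    return logged[selected]


def volcano(
    m: pd.DataFrame,
    groups,
    fc_min: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-metabolite Mann-Whitney volcano with log2 fold change of raw means.

    ``m`` is samples x metabolites on the raw intensity scale; fold change
    is case mean over control mean with a pseudo-count; calls are up/down
    when q < alpha and |log2FC| >= fc_min.
    """
    groups = pd.Series(list(groups), index=m.index)
    uniques = list(pd.unique(groups))
    if len(uniques) != 2:
        raise ValueError("volcano requires exactly two groups")
    case, control = uniques
    if (groups == case).sum() < 3 or (groups == control).sum() < 3:
        raise ValueError("each group needs at least 3 samples")
    Xc = m.loc[groups == case].values.astype(float)
    Xn = m.loc[groups == control].values.astype(float)
    log2fc = np.log2((Xc.mean(axis=0) + pseudocount) / (Xn.mean(axis=0) + pseudocount))
    pvals = np.array(
        [mann_whitney_p(Xc[:, j], Xn[:, j]) for j in range(m.shape[1])]
    )
    q = np.maximum(bh_adjust(pvals), pvals)
    call = np.where(
        (q < alpha) & (np.abs(log2fc) >= fc_min),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "q": q, "call": call}, index=m.columns
    )


def pls_da_vip(m: pd.DataFrame, groups, n_components: int = 2) -> pd.Series:
    """Variable importance in projection from a PLS-DA fit.

    Standardized intensities are regressed on the binary class indicator;
    VIP_j = sqrt(p * sum_a(ss_a * (w_aj/||w_a||)^2) / sum_a ss_a) with
    ss_a the Y-variance explained by component a, so mean(VIP^2) = 1.
    """
    groups = pd.Series(list(groups), index=m.index)
    uniques = list(pd.unique(groups))
    if len(uniques) != 2:
        raise ValueError("PLS-DA requires exactly two groups")
    y = (groups == uniques[0]).astype(float).values
    X = m.values.astype(float)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y - y.mean())
    T = pls.x_scores_  # n x a
    W = pls.x_weights_  # p x a
    Q = pls.y_loadings_  # 1 x a
    p = X.shape[1]
    ss = (Q[0] ** 2) * (T**2).sum(axis=0)  # Y-variance explained per component
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    vip = np.sqrt(p * ((W**2) / wnorm2 * ss).sum(axis=1) / ss.sum())
    return pd.Series(vip, index=m.columns, name="VIP")


@dataclass
class ScaleFreeFit:
    table: pd.DataFrame  # power, r2, mean_connectivity
    power: int
    reached_threshold: bool


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free fit R^2 of log10 p(k) vs log10 k (negative if slope > 0)."""
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() > 0:
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.array(xs), np.array(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * xs + intercept
    ss_res = ((ys - fitted) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2) if slope != 0 else float(r2)


def correlation_adjacency(m: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned adjacency |cor(i, j)|^beta with zero diagonal (Pearson)."""
    X = m.values.astype(float)
    if (np.ptp(X, axis=0) == 0).any():
        raise ValueError("constant metabolite columns must be removed first")
    C = np.corrcoef(X, rowvar=False)
    A = np.abs(C) ** beta
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=m.columns, columns=m.columns)


def pick_soft_threshold(
    m: pd.DataFrame, powers=range(1, 21), r2_min: float = 0.85
) -> ScaleFreeFit:
    """Choose the smallest power whose scale-free fit reaches ``r2_min``.

    If no power reaches the threshold the argmax is returned with a
    warning flag on the result.
    """
    if m.shape[1] < 20:
        raise ValueError("need at least 20 metabolites")
    X = m.values.astype(float)
    C = np.abs(np.corrcoef(X, rowvar=False))
    np.fill_diagonal(C, 0.0)
    rows = []
    for beta in powers:
        A = C**beta
        k = A.sum(axis=1)
        rows.append(
            {"power": int(beta), "r2": _scale_free_r2(k), "mean_connectivity": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    reached = table[table["r2"] >= r2_min]
    if len(reached):
        power = int(reached.iloc[0]["power"])
        flag = True
    else:
        power = int(table.loc[table["r2"].idxmax(), "power"])
        flag = False
        warnings.warn(f"no power reached scale-free R^2 {r2_min}; using argmax {power}")
    return ScaleFreeFit(table, power, flag)


def tom(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix of an adjacency with zero diagonal.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, and 1 on the diagonal.  Note TOM_ij >= a_ij does not hold in
    general.
    """
    A = adjacency.values if isinstance(adjacency, pd.DataFrame) else np.asarray(adjacency, float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    T = (shared + A) / denom
    np.fill_diagonal(T, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(T, index=adjacency.index, columns=adjacency.columns)
    return T


@dataclass
class ModulePartition:
    labels: pd.Series  # metabolite -> color ("grey" = unassigned)
    min_size: int

    @property
    def modules(self) -> dict:
        return {
            c: list(self.labels.index[self.labels == c])
            for c in self.labels.unique()
            if c != "grey"
        }


def detect_modules(
    tom_matrix: pd.DataFrame,
    min_size: int = 30,
    n_scan: int = 200,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a height-scan tree cut.

    The dendrogram is cut at the merge height that maximizes the number
    of clusters of size >= ``min_size`` (scanned over ``n_scan`` height
    quantiles; the highest height wins ties, so sub-branches of one
    module are absorbed before distinct modules merge).  Clusters below
    ``min_size`` are merged into grey;
    surviving modules get colors by decreasing size from the conventional
    palette.
    """
    names = list(tom_matrix.index)
    n = len(names)
    if n < min_size:
        return ModulePartition(pd.Series("grey", index=names), min_size)
    D = 1.0 - tom_matrix.values
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = average(squareform(D, checks=False))
    heights = np.unique(Z[:, 2])
    if len(heights) > n_scan:
        heights = np.quantile(heights, np.linspace(0.0, 1.0, n_scan))
    best_cut, best_count = heights[-1], -1
    for h in heights:
        labs = fcluster(Z, t=h, criterion="distance")
        count = int((np.bincount(labs) >= min_size).sum())
        if count >= best_count:
            best_count, best_cut = count, h
    assign = fcluster(Z, t=best_cut, criterion="distance")
    sizes = pd.Series(assign).value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_size]
    big.sort(key=lambda c: (-sizes[c], c))
    color_of = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(big)}
    labels = pd.Series(
        [color_of.get(c, "grey") for c in assign], index=names, name="module"
    )
    return ModulePartition(labels, min_size)


def refine_modules(
    m: pd.DataFrame, partition: ModulePartition, kme_min: float = 0.5
) -> ModulePartition:
    """Refine a tree-cut partition by module-membership correlation (kME).

    Each metabolite is reassigned to the module whose eigenprofile it
    correlates with most strongly; metabolites with maximal |kME| below
    ``kme_min`` become grey, and modules falling under the minimum size
    dissolve.  Colors are re-ranked by size.  This is the conventional
    membership clean-up applied after branch cutting; spurious clusters
    of uncorrelated features dissolve because their members have weak
    membership everywhere.
    """
    if not partition.modules:
        return partition
    eig = eigenprofiles(m, partition)
    E = eig.profiles
    X = m.values.astype(float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    kme = (Z.T @ (E.values - E.values.mean(axis=0))) / len(Z)
    kme /= E.values.std(axis=0, ddof=0) * Z.std(axis=0).reshape(-1, 1).clip(min=1e-12)
    best = np.abs(kme).argmax(axis=1)
    best_val = np.abs(kme).max(axis=1)
    cols = list(E.columns)
    labels = pd.Series(
        [cols[b] if v >= kme_min else "grey" for b, v in zip(best, best_val)],
        index=m.columns, name="module",
    )
    sizes = labels[labels != "grey"].value_counts()
    keep = [c for c in sizes.index if sizes[c] >= partition.min_size]
    keep.sort(key=lambda c: (-sizes[c], c))
    rename = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(keep)}
    labels = labels.map(lambda c: rename.get(c, "grey"))
    return ModulePartition(labels, partition.min_size)


@dataclass
class ModuleEigenProfile:
    profiles: pd.DataFrame  # samples x modules, unit-norm columns
    variance_explained: pd.Series


def eigenprofiles(m: pd.DataFrame, partition: ModulePartition) -> ModuleEigenProfile:
    """First principal component per module on standardized member columns.

    Each profile has unit norm and is oriented so its mean correlation
    with the member metabolites is non-negative.
    """
    modules = partition.modules
    if not modules:
        raise ValueError("no non-grey modules")
    profiles = {}
    varexp = {}
    for color, members in modules.items():
        X = m[members].values.astype(float)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=0)) / sd
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        profile = U[:, 0]
        varexp[color] = float(S[0] ** 2 / (S**2).sum())
        corr_mean = np.mean([np.corrcoef(profile, Z[:, j])[0, 1] for j in range(Z.shape[1])])
        if corr_mean < 0:
            profile = -profile
        profiles[color] = profile
    df = pd.DataFrame(profiles, index=m.index)
    return ModuleEigenProfile(df, pd.Series(varexp, name="variance_explained"))


def module_trait(
    eigen: ModuleEigenProfile, clinical: pd.DataFrame, traits=None
) -> pd.DataFrame:
    """Module x trait Spearman correlation (binary traits rank-encoded).

    Returns a tidy frame with columns module, trait, r, p.  Constant
    traits yield NaN (flagged undefined).
    """
    common = eigen.profiles.index.intersection(clinical.index)
    if len(common) < 5:
        raise ValueError("need sample overlap of at least 5 subjects")
    E = eigen.profiles.loc[common]
    traits = list(traits) if traits is not None else [
        c for c in clinical.columns if pd.api.types.is_numeric_dtype(clinical[c])
    ]
    T = clinical.loc[common, traits].astype(float)
    r, p = spearman_grid(E.values, T.values)
    rows = []
    for i, mod in enumerate(E.columns):
        for j, tr in enumerate(traits):
            rows.append({"module": mod, "trait": tr, "r": r[i, j], "p": p[i, j]})
    return pd.DataFrame(rows)
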