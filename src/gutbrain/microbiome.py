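"""Community profiling for the genus-level 16S abundance table.

Rank aggregation, relative abundance, alpha diversity (observed species,
Shannon, Simpson, Pielou evenness, bias-corrected Chao1, ACE), Bray-Curtis
dissimilarity, principal coordinates analysis, PERMANOVA, per-taxon group
tests with BH correction, and an LDA-effect-size biomarker procedure with
the conventional LDA > 2 reporting threshold.  Two-group (ASD/TD) and
three-group (ASD_D/ASD_noD/TD) designs are both supported.

Shannon uses the natural logarithm; evenness is Pielou's H/ln(S).  Counts
are never rarefied; depth differences are handled by relative abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, kruskal_p, mann_whitney_p

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon-delimited ``k__...;p__...`` lineage into rank labels.

    Missing ranks (empty after the prefix, or absent) yield empty strings;
    prefixes are optional.
    """
    parts = [p.strip() for p in lineage.split(";")]
    labels = []
    for i in range(len(RANKS)):
        lab = parts[i] if i < len(parts) else ""
        if lab.startswith(RANK_PREFIXES[i]):
            lab = lab[len(RANK_PREFIXES[i]):]
        labels.append(lab)
    return tuple(labels)


def format_lineage(labels) -> str:
    return ";".join(pref + lab for pref, lab in zip(RANK_PREFIXES, labels))


@dataclass
class CountTable:
    """Taxa x samples integer counts with semicolon rank lineages."""

    lineages: list[str]
    samples: list[str]
    counts: np.ndarray
    sample_groups: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.lineages), len(self.samples)):
            raise ValueError("counts shape does not match lineages x samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.sample_groups is not None:
            self.sample_groups = pd.Series(self.sample_groups).reindex(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.lineages, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_groups=None) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.values, sample_groups)


def read_count_table(path, sample_groups=None) -> CountTable:
    """Read an abundance TSV: first column ``lineage``, remaining columns samples.

    Lines starting with ``#`` are metadata and skipped.  A malformed row
    raises a ValueError naming the file and line number.
    """
    lineages, rows = [], []
    samples: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if samples is None:
                samples = parts[1:]
                if not samples:
                    raise ValueError(f"{path}:{lineno}: header has no sample columns")
                continue
            if len(parts) != len(samples) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(parts)}"
                )
            try:
                counts = [int(float(x)) for x in parts[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric count ({exc})") from None
            if any(c < 0 for c in counts):
                raise ValueError(f"{path}:{lineno}: negative count")
            lineages.append(parts[0])
            rows.append(counts)
    if samples is None or not rows:
        raise ValueError(f"{path}: empty abundance table")
    return CountTable(lineages, samples, np.array(rows, dtype=int), sample_groups)


def aggregate_rank(t: CountTable, rank: str) -> CountTable:
    """Sum counts over lineages truncated at ``rank``.

    Taxa with no label at that rank are pooled into an ``unclassified``
    row.  Per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    depth = RANKS.index(rank) + 1
    keys = []
    for lin in t.lineages:
        labels = parse_lineage(lin)
        if labels[depth - 1] == "":
            keys.append("unclassified")
        else:
            keys.append(format_lineage(list(labels[:depth]) + [""] * (len(RANKS) - depth)))
    df = t.to_frame()
    df.index = keys
    agg = df.groupby(level=0, sort=False).sum()
    return CountTable(list(agg.index), t.samples, agg.values, t.sample_groups)


def relative_abundance(t: CountTable) -> pd.DataFrame:
    """Per-sample proportions (columns sum to 1)."""
    totals = t.counts.sum(axis=0)
    zero = np.asarray(totals == 0).nonzero()[0]
    if zero.size:
        raise ValueError(f"zero-total sample(s): {[t.samples[i] for i in zero]}")
    return pd.DataFrame(t.counts / totals, index=t.lineages, columns=t.samples)


def _ace(counts: np.ndarray, rare_cutoff: int = 10) -> float:
    c = counts[counts > 0]
    rare = c[c <= rare_cutoff]
    abund = c[c > rare_cutoff]
    s_rare, s_abund = len(rare), len(abund)
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    if n_rare == f1:  # all rare taxa are singletons: C_ace = 0
        return float(len(c))
    c_ace = 1.0 - f1 / n_rare
    fi = np.array([(rare == i).sum() for i in range(1, rare_cutoff + 1)])
    i = np.arange(1, rare_cutoff + 1)
    gamma2 = max(
        (s_rare / c_ace) * (i * (i - 1) * fi).sum() / (n_rare * (n_rare - 1)) - 1.0,
        0.0,
    ) if n_rare > 1 else 0.0
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def alpha_diversity(t: CountTable) -> pd.DataFrame:
    """Per-sample alpha diversity indices.

    shannon = -sum p ln p; simpson = 1 - sum p^2; evenness = H/ln(S)
    (0 when S <= 1); chao1 bias-corrected = S + F1(F1-1)/(2(F2+1)); ACE
    with the standard rare/abundant split at 10 reads.
    """
    rows = []
    for j, sample in enumerate(t.samples):
        c = np.asarray(t.counts[:, j], dtype=float)
        total = c.sum()
        if total <= 0:
            raise ValueError(f"zero-total sample: {sample}")
        present = c[c > 0]
        p = present / total
        s = len(present)
        shannon = float(-(p * np.log(p)).sum())
        simpson = float(1.0 - (p**2).sum())
        evenness = shannon / np.log(s) if s > 1 else 0.0
        f1 = int((present == 1).sum())
        f2 = int((present == 2).sum())
        chao1 = s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        rows.append(
            {
                "sample": sample,
                "observed_species": s,
                "shannon": shannon,
                "simpson": simpson,
                "evenness": float(evenness),
                "chao1": float(chao1),
                "ace": _ace(present.astype(int)),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def bray_curtis(m: pd.DataFrame | np.ndarray, labels=None) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity over samples (columns).

    d(x, y) = sum|x - y| / sum(x + y).  A pair of all-zero samples has
    distance 0 (with a warning).
    """
    if isinstance(m, pd.DataFrame):
        labels = list(m.columns)
        X = m.values
    else:
        X = np.asarray(m, dtype=float)
        labels = labels if labels is not None else list(range(X.shape[1]))
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative data")
    n = X.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[:, i : i + 1] - X[:, i + 1 :]).sum(axis=0)
        tot = (X[:, i : i + 1] + X[:, i + 1 :]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        if (tot == 0).any():
            warnings.warn("all-zero sample pair; Bray-Curtis distance set to 0")
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: pd.DataFrame) -> OrdinationResult:
    """Principal coordinates by Gower double-centering and eigendecomposition.

    Axes are sorted by decreasing eigenvalue.  Negative eigenvalues (the
    Bray-Curtis semi-metric can produce them) are reported but excluded
    from the proportion-explained denominator, and their axes carry zero
    coordinates.
    """
    D = np.asarray(d, dtype=float)
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    evals, evecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    scale = np.abs(evals).max() if n else 0.0
    pos[pos < 1e-12 * max(scale, 1.0)] = 0.0  # numerically-zero axes carry no coordinates
    coords = evecs * np.sqrt(pos)
    denom = pos.sum()
    prop = pos / denom if denom > 0 else np.zeros_like(pos)
    labels = list(d.index) if isinstance(d, pd.DataFrame) else list(range(n))
    cols = [f"PCo{i+1}" for i in range(n)]
    return OrdinationResult(
        pd.DataFrame(coords, index=labels, columns=cols), evals, prop
    )


def _permanova_f(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.asarray(codes == g).nonzero()[0]
        if idx.size > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    d: pd.DataFrame, groups, n_perm: int = 999, seed: int | None = None
) -> dict:
    """Distance-based PERMANOVA: pseudo-F and seeded permutation p.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm) under free label
    permutation.
    """
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    D = np.asarray(d, dtype=float)
    groups = pd.Series(list(groups))
    codes, uniques = pd.factorize(groups)
    k = len(uniques)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 samples")
    D2 = D**2
    f_obs = _permanova_f(D2, codes, k)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_f(D2, perm, k) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return {"pseudo_F": float(f_obs), "p": float(p), "n_perm": n_perm, "n_groups": k}


def diff_abundance(rel: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-taxon group test (Mann-Whitney for 2 groups, Kruskal-Wallis for >=3).

    BH correction across taxa; direction is the group with the highest
    mean; a constant taxon gets p = 1 by convention.
    """
    groups = pd.Series(list(groups), index=rel.columns)
    uniques = list(pd.unique(groups))
    if len(uniques) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for taxon in rel.index:
        vals = rel.loc[taxon]
        by_group = [vals[groups == g].values for g in uniques]
        if len(uniques) == 2:
            p = mann_whitney_p(by_group[0], by_group[1])
        else:
            p = kruskal_p(*by_group)
        means = {f"mean_{g}": float(v.mean()) for g, v in zip(uniques, by_group)}
        direction = uniques[int(np.argmax([v.mean() for v in by_group]))]
        rows.append({"taxon": taxon, **means, "p": p, "direction": direction})
    df = pd.DataFrame(rows).set_index("taxon")
    df["q"] = np.maximum(bh_adjust(df["p"].values), df["p"].values)
    return df


def _discriminant_effect(X: np.ndarray, in_a: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Per-feature effect of a regularized Fisher discriminant, class A vs rest.

    The discriminant direction is w = (S_pooled + ridge*tr(S)/p * I)^{-1}
    (mu_A - mu_B), normalized to unit length.  The effect attributed to
    feature i averages the raw between-class mean difference with the
    component of the projected difference carried by that feature:
    0.5 * (|mu_A_i - mu_B_i| + |w_i * (mu_A_i - mu_B_i)|).  On a
    one-feature problem w = 1, so the effect reduces to the rescaled mean
    difference itself.
    """
    A, B = X[in_a], X[~in_a]
    mu_diff = A.mean(axis=0) - B.mean(axis=0)
    Sa = np.cov(A, rowvar=False, bias=True) * len(A)
    Sb = np.cov(B, rowvar=False, bias=True) * len(B)
    S = (Sa + Sb) / max(len(X) - 2, 1)
    S = np.atleast_2d(S)
    lam = ridge * max(np.trace(S) / S.shape[0], 1.0)
    w = np.linalg.solve(S + lam * np.eye(S.shape[0]), mu_diff)
    norm = np.linalg.norm(w)
    w = w / norm if norm > 0 else np.zeros_like(mu_diff)
    return 0.5 * (np.abs(mu_diff) + np.abs(w * mu_diff))


def lda_effect_size(
    rel: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
    rescale_to: float = 1e6,
) -> pd.DataFrame:
    """LEfSe-style biomarker scores with the LDA > threshold convention.

    Stage 1 filters taxa by Kruskal-Wallis (Mann-Whitney for two classes)
    at ``alpha``.  Stage 2 rescales abundances to a common [0, rescale_to]
    range and, over ``n_boot`` bootstrap resamples, averages the absolute
    between-class difference of the regularized linear-discriminant
    projection attributable to each taxon (one-against-all for three
    classes).  The reported score is log10(1 + effect); taxa are retained
    when the score exceeds ``lda_threshold`` and assigned to the class with
    the highest mean abundance.
    """
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    groups = pd.Series(list(groups), index=rel.columns)
    classes = list(pd.unique(groups))
    if not (2 <= len(classes) <= 3):
        raise ValueError("2 or 3 classes required")
    sizes = groups.value_counts()
    if (sizes < 3).any():
        raise ValueError("every class needs at least 3 samples")

    # stage 1: per-taxon rank test
    keep = []
    for taxon in rel.index:
        vals = rel.loc[taxon]
        by = [vals[groups == g].values for g in classes]
        p = mann_whitney_p(*by) if len(classes) == 2 else kruskal_p(*by)
        if p < alpha:
            keep.append((taxon, p))
    if not keep:
        return pd.DataFrame(columns=["enriched", "lda_score", "kw_p"])

    taxa = [t for t, _ in keep]
    pvals = {t: p for t, p in keep}
    X = rel.loc[taxa].T.values.astype(float)  # samples x taxa
    span = X.max() - X.min()
    X = (X - X.min()) / (span if span > 0 else 1.0) * rescale_to

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    pairs = (
        [(classes[0], None)]
        if len(classes) == 2
        else [(c, None) for c in classes]  # one-against-all per class
    )
    effects = np.zeros((len(pairs), len(taxa)))
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb = X[idx]
        gb = groups.values[idx]
        for k, (cls, _) in enumerate(pairs):
            in_a = gb == cls
            if in_a.sum() < 2 or (~in_a).sum() < 2:
                continue
            effects[k] += _discriminant_effect(Xb, in_a)
    effects /= n_boot
    effect = effects.max(axis=0)

    rows = []
    class_means = np.stack([X[groups.values == c].mean(axis=0) for c in classes])
    for j, taxon in enumerate(taxa):
        score = float(np.log10(1.0 + effect[j]))
        if score > lda_threshold:
            rows.append(
                {
                    "taxon": taxon,
                    "enriched": classes[int(np.argmax(class_means[:, j]))],
                    "lda_score": score,
                    "kw_p": pvals[taxon],
                }
            )
    return pd.DataFrame(rows).set_index("taxon") if rows else pd.DataFrame(
        columns=["enriched", "lda_score", "kw_p"]
    )
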