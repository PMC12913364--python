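"""Signed microbial co-occurrence networks and spectral robustness.

Per-group networks are built from pairwise Spearman correlations between
taxa (prevalence-filtered), keeping pairs that pass both a BH-adjusted
significance cut and an absolute-correlation floor.  Topology metrics
(connectance, average degree, negative-edge ratio), natural connectivity
(the log of the mean exponential of the adjacency eigenvalues), and
robustness curves under sequential node removal follow.

Natural connectivity is computed on the unweighted 0/1 adjacency spectrum
by default (the metric's standard definition); a weighted |rho| variant is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from ._stats import bh_adjust


@dataclass
class CoNetwork:
    """Undirected signed co-occurrence graph with its build parameters."""

    nodes: list[str]
    edges: pd.DataFrame  # columns u, v, rho, q, sign
    rho_min: float = 0.6
    fdr: float = 0.05
    min_prevalence: float = 0.2

    def __post_init__(self) -> None:
        if len(self.edges):
            if (self.edges["u"] == self.edges["v"]).any():
                raise ValueError("self-loops are not allowed")
            key = self.edges.apply(lambda r: frozenset((r["u"], r["v"])), axis=1)
            if key.duplicated().any():
                raise ValueError("duplicate edges")
            if (self.edges["rho"].abs() < self.rho_min - 1e-12).any():
                raise ValueError("edge below correlation threshold")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, r in self.edges.iterrows():
            g.add_edge(r["u"], r["v"], rho=float(r["rho"]), sign=int(r["sign"]))
        return g

    def adjacency(self, nodes=None, weighted: bool = False) -> np.ndarray:
        nodes = list(self.nodes) if nodes is None else list(nodes)
        pos = {n: i for i, n in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for _, r in self.edges.iterrows():
            if r["u"] in pos and r["v"] in pos:
                w = abs(float(r["rho"])) if weighted else 1.0
                i, j = pos[r["u"]], pos[r["v"]]
                A[i, j] = A[j, i] = w
        return A


def build_network(
    rel: pd.DataFrame,
    rho_min: float = 0.6,
    fdr: float = 0.05,
    min_prevalence: float = 0.2,
) -> CoNetwork:
    """Build a signed co-occurrence network from one group's proportions.

    Taxa present in fewer than ``min_prevalence`` of samples, and constant
    taxa (undefined rank correlation), are excluded.  Pairwise Spearman
    with tie correction; BH across all pairs; an edge needs q < fdr and
    |rho| >= rho_min.
    """
    if rel.shape[1] < 5:
        raise ValueError("need at least 5 samples to build a network")
    prevalence = (rel.values > 0).mean(axis=1)
    keep = prevalence >= min_prevalence
    sub = rel.loc[keep]
    sub = sub.loc[np.ptp(sub.values, axis=1) > 0]
    taxa = list(sub.index)
    m = len(taxa)
    if m < 2:
        return CoNetwork(taxa, pd.DataFrame(columns=["u", "v", "rho", "q", "sign"]),
                         rho_min, fdr, min_prevalence)
    if m == 2:  # scipy returns scalars for a single pair
        res = stats.spearmanr(sub.values[0], sub.values[1])
        rho = np.array([[1.0, res.statistic], [res.statistic, 1.0]])
        p = np.array([[0.0, res.pvalue], [res.pvalue, 0.0]])
    else:
        rho, p = stats.spearmanr(sub.values.T)
    iu = np.triu_indices(m, 1)
    q = bh_adjust(p[iu])
    rows = []
    for (i, j), qv in zip(zip(*iu), q):
        r = rho[i, j]
        if qv < fdr and abs(r) >= rho_min:
            rows.append(
                {"u": taxa[i], "v": taxa[j], "rho": float(r), "q": float(qv),
                 "sign": 1 if r > 0 else -1}
            )
    edges = pd.DataFrame(rows, columns=["u", "v", "rho", "q", "sign"])
    return CoNetwork(taxa, edges, rho_min, fdr, min_prevalence)


@dataclass
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    connectance: float
    average_degree: float
    negative_ratio: float
    zero_edges: bool = False


def topology(net_or_counts: CoNetwork | tuple) -> TopologyMetrics:
    """Connectance 2E/(n(n-1)), average degree 2E/n, negative-edge ratio.

    Accepts either a CoNetwork or a bare (n_nodes, n_edges[, n_negative])
    tuple, so the identities can also be evaluated on reported counts.
    """
    if isinstance(net_or_counts, CoNetwork):
        n = len(net_or_counts.nodes)
        e = len(net_or_counts.edges)
        neg = int((net_or_counts.edges["sign"] == -1).sum()) if e else 0
    else:
        n, e, *rest = net_or_counts
        neg = rest[0] if rest else 0
    if n < 2:
        raise ValueError("need at least 2 nodes")
    connectance = 2.0 * e / (n * (n - 1))
    avg_degree = 2.0 * e / n
    neg_ratio = neg / e if e else 0.0
    return TopologyMetrics(n, e, connectance, avg_degree, neg_ratio, zero_edges=(e == 0))


def nodes_from_connectance(n_edges: int, connectance: float) -> int:
    """Invert connectance = 2E/(n(n-1)) for the node count (rounded)."""
    # n^2 - n - 2E/c = 0
    disc = 1.0 + 8.0 * n_edges / connectance
    return int(round((1.0 + np.sqrt(disc)) / 2.0))


def natural_connectivity(
    net: CoNetwork | np.ndarray, nodes=None, weighted: bool = False
) -> float:
    """Natural connectivity ln((1/n) sum_i exp(lambda_i)) of the adjacency.

    Computed with an overflow-safe log-sum-exp over the eigenvalues of the
    symmetric (by default unweighted) adjacency matrix.  The empty graph
    gives 0.
    """
    if isinstance(net, CoNetwork):
        A = net.adjacency(nodes=nodes, weighted=weighted)
    else:
        A = np.asarray(net, dtype=float)
    n = A.shape[0]
    if n == 0:
        return 0.0
    evals = np.linalg.eigvalsh(A)
    return float(logsumexp(evals) - np.log(n))


@dataclass
class RobustnessCurve:
    mode: str
    fraction_removed: np.ndarray
    connectivity: np.ndarray  # mean over repeats (random mode)
    connectivity_sd: np.ndarray
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction_removed": self.fraction_removed,
                "natural_connectivity": self.connectivity,
                "sd": self.connectivity_sd,
            }
        )


def robustness(
    net: CoNetwork,
    mode: str = "random",
    step_fraction: float = 0.05,
    n_repeat: int = 20,
    seed: int | None = None,
) -> RobustnessCurve:
    """Natural-connectivity decay under cumulative node removal.

    ``random`` removes seeded random orders (mean and sd over
    ``n_repeat`` repeats); ``degree-descending`` removes highest-degree
    nodes first, ties broken by node identifier for determinism.
    """
    if mode not in ("random", "degree-descending"):
        raise ValueError(f"unknown removal mode {mode!r}")
    n = len(net.nodes)
    if n < 10:
        raise ValueError("need at least 10 nodes for a robustness curve")
    A_full = net.adjacency()
    step = max(int(round(step_fraction * n)), 1)
    removal_counts = list(range(0, n + 1, step))
    if removal_counts[-1] != n:
        removal_counts.append(n)
    fractions = np.array([k / n for k in removal_counts])

    def curve_for_order(order: np.ndarray) -> np.ndarray:
        vals = []
        for k in removal_counts:
            keep = np.setdiff1d(np.arange(n), order[:k])
            if keep.size == 0:
                vals.append(0.0)
            else:
                vals.append(natural_connectivity(A_full[np.ix_(keep, keep)]))
        return np.array(vals)

    if mode == "degree-descending":
        deg = A_full.sum(axis=1)
        # sort by (-degree, node id) for deterministic tie-breaks
        order = np.array(
            sorted(range(n), key=lambda i: (-deg[i], str(net.nodes[i])))
        )
        curve = curve_for_order(order)
        sd = np.zeros_like(curve)
    else:
        if seed is None:
            raise ValueError("random removal requires a seed")
        rng = np.random.default_rng(seed)
        curves = np.stack(
            [curve_for_order(rng.permutation(n)) for _ in range(n_repeat)]
        )
        curve = curves.mean(axis=0)
        sd = curves.std(axis=0, ddof=0)
    return RobustnessCurve(mode, fractions, curve, sd, seed)


def export_graphml(net: CoNetwork, path) -> None:
    nx.write_graphml(net.to_graph(), path)
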