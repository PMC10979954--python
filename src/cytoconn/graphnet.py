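"""Weighted graph metrics and hub scoring for connectivity matrices.

A connectivity matrix becomes an undirected weighted graph by taking the
absolute correlation as the edge weight (self-loops removed).  The metrics
are the standard weighted forms used for brain networks:

* strength            s_i = sum_j w_ij
* clustering (Onnela) C_i = (1 / k_i (k_i - 1)) * sum_{j,k} (w_ij w_jk w_ki)^{1/3}
* shortest paths      Dijkstra on lengths 1 / w_ij
* char. path length   L_w = mean over ordered pairs of d_ij
* global efficiency   E_w = mean over ordered pairs of 1 / d_ij
* assortativity       weighted degree-degree Pearson correlation over edges
* betweenness         shortest-path betweenness on lengths 1 / w (endpoints excluded)

Hub scoring awards one point per criterion on a group-average graph: top 20%
strength, top 20% betweenness, bottom 20% mean path length, bottom 20%
clustering (scores 0-4).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import ConnectivityMatrix

__all__ = [
    "WeightedGraph",
    "GraphMetrics",
    "to_weighted_graph",
    "strength",
    "clustering",
    "shortest_paths",
    "char_path_length",
    "global_efficiency",
    "assortativity",
    "betweenness",
    "hub_scores",
    "graph_metrics",
]


@dataclass
class WeightedGraph:
    """Symmetric non-negative weight matrix with zero diagonal."""

    weights: np.ndarray
    node_names: list[str]
    n_missing: int = 0    # NaN entries of the source matrix mapped to weight 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_list(self) -> list[tuple[int, int, float]]:
        i, j = np.nonzero(np.triu(self.weights, 1))
        return [(int(a), int(b), float(self.weights[a, b])) for a, b in zip(i, j)]

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        for a, b, w in self.edge_list():
            G.add_edge(a, b, weight=w, length=1.0 / w)
        return G


def to_weighted_graph(matrix: ConnectivityMatrix) -> WeightedGraph:
    """``w = |r|`` off-diagonal, zero diagonal; NaN entries become weight 0."""
    w = np.abs(matrix.r.copy())
    n_missing = int(np.isnan(w).sum())
    w = np.nan_to_num(w, nan=0.0)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w, list(matrix.roi_names), n_missing=n_missing)


def strength(g: WeightedGraph) -> np.ndarray:
    return g.weights.sum(axis=1)


def clustering(g: WeightedGraph, normalize: bool = True) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    With ``normalize`` (default) weights are divided by the maximum weight
    before the geometric-mean triangle term, bounding C_i by 1.
    """
    w = g.weights
    wmax = w.max()
    if normalize and wmax > 0:
        w = w / wmax
    a = np.cbrt(w)
    tri = np.diagonal(a @ a @ a)          # ordered (j, k) pairs, both orders
    k = (g.weights > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    out = np.zeros(g.n_nodes)
    ok = denom > 0
    out[ok] = tri[ok] / denom[ok]
    return out


def shortest_paths(g: WeightedGraph) -> np.ndarray:
    """All-pairs weighted shortest-path matrix on lengths 1/w (inf if disconnected)."""
    w = g.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = dijkstra(csr_matrix(lengths), directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def char_path_length(g: WeightedGraph, d: np.ndarray | None = None) -> float:
    """Mean shortest path over ordered node pairs; inf if disconnected."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("characteristic path length needs >= 2 nodes")
    if d is None:
        d = shortest_paths(g)
    off = d[~np.eye(n, dtype=bool)]
    return float(np.mean(off))


def char_path_length_connected(g: WeightedGraph, d: np.ndarray | None = None) -> float:
    """Fallback for disconnected graphs: mean over finite off-diagonal distances."""
    n = g.n_nodes
    if d is None:
        d = shortest_paths(g)
    off = d[~np.eye(n, dtype=bool)]
    finite = off[np.isfinite(off)]
    return float(np.mean(finite)) if finite.size else float("inf")


def global_efficiency(g: WeightedGraph, d: np.ndarray | None = None) -> float:
    """Mean inverse shortest path over ordered pairs; disconnected pairs add 0."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    if d is None:
        d = shortest_paths(g)
    off = d[~np.eye(n, dtype=bool)]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(off) & (off > 0), 1.0 / off, 0.0)
    return float(np.mean(inv))


def assortativity(g: WeightedGraph) -> float:
    """Weighted degree-degree correlation over the edge set.

    The Pearson correlation of endpoint weighted degrees k_i^w, k_j^w across
    the l edges of the graph (the weighted assortativity of the Brain
    Connectivity Toolbox):

        r_w = [ l^-1 sum k_i k_j - (l^-1 sum (k_i + k_j)/2)^2 ]
              / [ l^-1 sum (k_i^2 + k_j^2)/2 - (l^-1 sum (k_i + k_j)/2)^2 ]

    This form is invariant under uniform weight scaling and reduces to the
    classic (binary) assortativity for 0/1 weights.  Returns NaN (undefined)
    when the denominator vanishes, e.g. for regular graphs where all weighted
    degrees coincide.
    """
    edges = g.edge_list()
    l = len(edges)
    if l < 1:
        raise ValueError("assortativity needs at least one edge")
    kw = strength(g)
    s_prod = s_sum = s_sq = 0.0
    for i, j, _w in edges:
        ki, kj = kw[i], kw[j]
        s_prod += ki * kj
        s_sum += 0.5 * (ki + kj)
        s_sq += 0.5 * (ki ** 2 + kj ** 2)
    num = s_prod / l - (s_sum / l) ** 2
    den = s_sq / l - (s_sum / l) ** 2
    if abs(den) < 1e-15:
        return float("nan")
    return float(num / den)


def betweenness(g: WeightedGraph) -> np.ndarray:
    """Normalised shortest-path betweenness on lengths 1/w, endpoints excluded."""
    G = g.to_networkx()
    bc = nx.betweenness_centrality(G, weight="length", normalized=True,
                                   endpoints=False)
    return np.array([bc[i] for i in range(g.n_nodes)])


def mean_node_distance(g: WeightedGraph, d: np.ndarray | None = None) -> np.ndarray:
    """Per-node mean shortest-path distance to all other nodes."""
    if d is None:
        d = shortest_paths(g)
    n = g.n_nodes
    if n < 2:
        return np.zeros(n)
    mask = ~np.eye(n, dtype=bool)
    return np.array([np.mean(d[i][mask[i]]) for i in range(n)])


def hub_scores(g: WeightedGraph, normalize_clustering: bool = True) -> np.ndarray:
    """0-4 hub score per node on a (group-average) graph.

    One point each for: strength in the top 20%, betweenness in the top 20%,
    mean path length in the bottom 20%, clustering in the bottom 20%.
    Thresholds are the empirical 80th/20th percentiles (linear interpolation);
    values tied with the threshold qualify.
    """
    import warnings as _warnings
    if g.n_nodes < 5:
        _warnings.warn("fewer than 5 nodes: 20% quantile criteria are coarse",
                       RuntimeWarning, stacklevel=2)
    d = shortest_paths(g)
    s = strength(g)
    b = betweenness(g)
    pl = mean_node_distance(g, d)
    c = clustering(g, normalize=normalize_clustering)
    finite_pl = pl[np.isfinite(pl)]
    score = np.zeros(g.n_nodes, dtype=int)
    score += (s >= np.percentile(s, 80)).astype(int)
    score += (b >= np.percentile(b, 80)).astype(int)
    if finite_pl.size:
        score += (pl <= np.percentile(finite_pl, 20)).astype(int)
    score += (c <= np.percentile(c, 20)).astype(int)
    return score


@dataclass
class GraphMetrics:
    """Bundle of per-node and global metrics for one graph."""

    node_table: pd.DataFrame
    char_path: float
    char_path_connected: float
    efficiency: float
    assortativity: float
    mean_clustering: float
    mean_strength: float
    disconnected: bool

    def to_global_dict(self) -> dict:
        return {
            "L_w": self.char_path,
            "L_w_connected": self.char_path_connected,
            "E_w": self.efficiency,
            "r_w": self.assortativity,
            "mean_C": self.mean_clustering,
            "mean_s": self.mean_strength,
            "disconnected": self.disconnected,
        }


def graph_metrics(matrix: ConnectivityMatrix | WeightedGraph,
                  normalize_clustering: bool = True) -> GraphMetrics:
    """Compute the full metric set for one connectivity matrix or graph."""
    g = matrix if isinstance(matrix, WeightedGraph) else to_weighted_graph(matrix)
    d = shortest_paths(g)
    s = strength(g)
    c = clustering(g, normalize=normalize_clustering)
    b = betweenness(g)
    pl = mean_node_distance(g, d)
    lw = char_path_length(g, d)
    node_table = pd.DataFrame({
        "node": g.node_names,
        "strength": s,
        "clustering": c,
        "betweenness": b,
        "mean_path": pl,
        "hub_score": hub_scores(g, normalize_clustering=normalize_clustering)
        if g.n_nodes >= 2 else np.zeros(g.n_nodes, dtype=int),
    })
    return GraphMetrics(
        node_table=node_table,
        char_path=lw,
        char_path_connected=char_path_length_connected(g, d),
        efficiency=global_efficiency(g, d),
        assortativity=assortativity(g) if g.n_edges else float("nan"),
        mean_clustering=float(np.mean(c)),
        mean_strength=float(np.mean(s)),
        disconnected=not np.isfinite(lw),
    )
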