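"""Independent brute-force oracles for weighted graph metrics.

Everything here is deliberately naive — exhaustive path enumeration and
triple loops — so it shares no code path with the package implementation.
Only usable for graphs with a handful of nodes.
"""

import itertools

import numpy as np


def brute_shortest_paths(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on lengths 1/w by enumerating simple paths."""
    n = W.shape[0]
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            others = [x for x in range(n) if x not in (i, j)]
            for k in range(len(others) + 1):
                for mid in itertools.permutations(others, k):
                    path = (i,) + mid + (j,)
                    length = 0.0
                    for a, b in zip(path[:-1], path[1:]):
                        if W[a, b] <= 0:
                            length = np.inf
                            break
                        length += 1.0 / W[a, b]
                    best[i, j] = min(best[i, j], length)
    return best


def brute_clustering(W: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Onnela clustering by explicit ordered-pair triple loop."""
    n = W.shape[0]
    Wn = W / W.max() if normalize and W.max() > 0 else W
    C = np.zeros(n)
    for i in range(n):
        k = int((W[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for l in range(n):
                if j != i and l != i and j != l:
                    total += (Wn[i, j] * Wn[j, l] * Wn[l, i]) ** (1.0 / 3.0)
        C[i] = total / (k * (k - 1))
    return C


def brute_assortativity(W: np.ndarray) -> float:
    """Term-by-term Pearson correlation of endpoint strengths over edges.

    Spelled out as explicit sums (not via np.corrcoef) so it stays an
    independent check of the packaged implementation.
    """
    n = W.shape[0]
    kw = W.sum(axis=1)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if W[i, j] > 0]
    l = len(edges)
    t_prod = sum(kw[i] * kw[j] for i, j in edges) / l
    t_sum = sum(0.5 * (kw[i] + kw[j]) for i, j in edges) / l
    t_sq = sum(0.5 * (kw[i] ** 2 + kw[j] ** 2) for i, j in edges) / l
    den = t_sq - t_sum ** 2
    if abs(den) < 1e-15:
        return float("nan")
    return (t_prod - t_sum ** 2) / den


def brute_betweenness(W: np.ndarray) -> np.ndarray:
    """Normalised betweenness by enumerating all shortest paths explicitly."""
    n = W.shape[0]
    d = brute_shortest_paths(W)
    counts = np.zeros(n)
    n_paths = np.zeros((n, n))
    through = np.zeros((n, n, n))
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(d[s, t]):
                continue
            others = [x for x in range(n) if x not in (s, t)]
            for k in range(len(others) + 1):
                for mid in itertools.permutations(others, k):
                    path = (s,) + mid + (t,)
                    length = 0.0
                    ok = True
                    for a, b in zip(path[:-1], path[1:]):
                        if W[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / W[a, b]
                    if ok and np.isclose(length, d[s, t], rtol=0, atol=1e-12):
                        n_paths[s, t] += 1
                        for v in mid:
                            through[s, t, v] += 1
    for v in range(n):
        total = 0.0
        for s in range(n):
            for t in range(n):
                if s == t or s == v or t == v or n_paths[s, t] == 0:
                    continue
                total += through[s, t, v] / n_paths[s, t]
        counts[v] = total / 2.0              # undirected: each pair counted twice
    norm = (n - 1) * (n - 2) / 2.0
    return counts / norm if norm > 0 else counts


def random_small_graph(rng: np.random.Generator, max_nodes: int = 6,
                       density: float = 0.7) -> np.ndarray:
    """Random symmetric weight matrix on 3..max_nodes nodes."""
    n = int(rng.integers(3, max_nodes + 1))
    U = rng.uniform(0.05, 1.0, size=(n, n))
    keep = rng.random((n, n)) < density
    U = np.triu(U * keep, 1)
    return U + U.T
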