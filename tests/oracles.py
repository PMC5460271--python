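"""Independent brute-force oracles for the graph-metric tests.

These deliberately avoid the package's Floyd–Warshall implementation: paths
are enumerated exhaustively (feasible for n <= 8), so they provide an
independent ground truth for distances, path counts, closeness, betweenness,
CPL and DPL.
"""

from itertools import permutations

import networkx as nx
import numpy as np

TOL = 1e-9


def enumerate_shortest(g: nx.Graph):
    """(d, sigma, interior_counts) by exhaustive simple-path enumeration."""
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    interior = np.zeros(n)
    for si in range(n):
        for ti in range(si + 1, n):
            s, t = nodes[si], nodes[ti]
            best, paths = np.inf, []
            for path in nx.all_simple_paths(g, s, t):
                w = sum(g[u][v]["weight"] for u, v in zip(path[:-1], path[1:]))
                if w < best - TOL:
                    best, paths = w, [path]
                elif abs(w - best) <= TOL:
                    paths.append(path)
            if paths:
                d[si, ti] = d[ti, si] = best
                sigma[si, ti] = sigma[ti, si] = len(paths)
                for path in paths:
                    for u in path[1:-1]:
                        interior[idx[u]] += 1
    return nodes, d, sigma, interior


def closeness_from_distances(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        comp = np.flatnonzero(np.isfinite(d[i]))
        if comp.size >= 2:
            out[i] = (comp.size - 1) / d[i, comp].sum()
    return out


def cpl_from_distances(d: np.ndarray) -> float:
    iu = np.triu_indices(d.shape[0], k=1)
    vals = d[iu]
    return float(vals[np.isfinite(vals)].mean())


def dpl_brute(g: nx.Graph) -> np.ndarray:
    _, d, _, _ = enumerate_shortest(g)
    base = cpl_from_distances(d)
    out = np.empty(g.number_of_nodes())
    for k, x in enumerate(list(g.nodes)):
        h = g.copy()
        h.remove_node(x)
        _, dh, _, _ = enumerate_shortest(h)
        out[k] = cpl_from_distances(dh) - base
    return out


def random_connected_graph(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    """Erdos-Renyi graph with uniform random weights, resampled until connected."""
    while True:
        g = nx.erdos_renyi_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() >= n - 1:
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.2, 2.0))
            return g
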