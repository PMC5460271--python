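"""Weighted-graph metrics for residue interaction networks.

All-pairs shortest paths are computed with a Floyd–Warshall recursion that
also counts distinct shortest paths (ties resolved under an absolute
tolerance, default 1e-9).  On top of the path matrix the module provides:

* closeness ``C(x) = (n-1) / sum_y d(x, y)`` with ``n`` and the sum
  restricted to the node's connected component;
* betweenness as the raw number of shortest paths between all unordered
  node pairs that pass through a node as an interior vertex;
* CPL, the mean shortest-path length over unordered reachable pairs;
* DPL, the change of CPL caused by removing a node (positive when removal
  lengthens paths);
* z-score outlier flags and rank-percentile closeness tiers
  (high = top 20 %, intermediate = 20–60 %, low = rest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PathMatrix",
    "NodeMetrics",
    "shortest_paths",
    "closeness",
    "betweenness",
    "cpl",
    "dpl",
    "zscore_flags",
    "closeness_tiers",
    "network_metrics",
]

TIE_TOL = 1e-9


@dataclass
class PathMatrix:
    """Shortest-path distances ``d``, path counts ``sigma`` and reachability."""

    nodes: list
    d: np.ndarray
    sigma: np.ndarray
    reachable: np.ndarray

    @property
    def n(self) -> int:
        return len(self.nodes)

    def components(self) -> list[np.ndarray]:
        """Connected components as arrays of node indices."""
        n = self.n
        seen = np.zeros(n, dtype=bool)
        comps = []
        for i in range(n):
            if seen[i]:
                continue
            members = np.flatnonzero(self.reachable[i])
            seen[members] = True
            comps.append(members)
        return comps


def _weight_matrix(g: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = list(g.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    for u, v, data in g.edges(data=True):
        wt = float(data.get("weight", 1.0))
        if wt < 0:
            raise ValueError(f"negative edge weight on ({u}, {v})")
        i, j = index[u], index[v]
        if wt < w[i, j]:
            w[i, j] = w[j, i] = wt
    return nodes, w


def shortest_paths(g: nx.Graph, tol: float = TIE_TOL) -> PathMatrix:
    """All-pairs shortest distances and shortest-path counts (Floyd–Warshall).

    ``sigma[i, j]`` is the number of distinct minimum-weight paths between
    ``i`` and ``j``; equal lengths are identified under absolute tolerance
    ``tol``.  Unreachable pairs have ``d = inf`` and ``sigma = 0``.
    """
    nodes, d = _weight_matrix(g)
    n = len(nodes)
    sigma = np.where(np.isfinite(d) & (d > 0), 1.0, 0.0)
    np.fill_diagonal(sigma, 1.0)
    for k in range(n):
        dk = d[:, k][:, None] + d[k, :][None, :]
        sk = sigma[:, k][:, None] * sigma[k, :][None, :]
        with np.errstate(invalid="ignore"):
            shorter = dk < d - tol
            equal = np.abs(dk - d) <= tol
        # paths through k itself as an endpoint are not new paths
        shorter[k, :] = shorter[:, k] = False
        equal[k, :] = equal[:, k] = False
        np.fill_diagonal(shorter, False)
        np.fill_diagonal(equal, False)
        d = np.where(shorter, dk, d)
        sigma = np.where(shorter, sk, np.where(equal, sigma + sk, sigma))
    reachable = np.isfinite(d)
    return PathMatrix(nodes, d, sigma, reachable)


def closeness(p: PathMatrix) -> np.ndarray:
    """Closeness per node, restricted to each node's connected component.

    Isolated nodes get closeness 0 (with a warning).
    """
    out = np.zeros(p.n)
    isolated = False
    for comp in p.components():
        if len(comp) < 2:
            isolated = True
            continue
        sub = p.d[np.ix_(comp, comp)]
        out[comp] = (len(comp) - 1) / sub.sum(axis=1)
    if isolated:
        warnings.warn("isolated node(s): closeness set to 0")
    return out


def betweenness(p: PathMatrix, tol: float = TIE_TOL) -> np.ndarray:
    """Raw shortest-path counts through each node (interior vertex only).

    ``B(x) = sum over unordered pairs {s, t}, s != x != t, of the number of
    shortest s–t paths having x in their interior`` — raw counts, not the
    Brandes-normalised fractions.
    """
    n = p.n
    out = np.zeros(n)
    d, sigma = p.d, p.sigma
    for x in range(n):
        with np.errstate(invalid="ignore"):
            through = np.abs(d[:, x][:, None] + d[x, :][None, :] - d) <= tol
        through &= p.reachable & np.isfinite(d[:, x])[:, None] & np.isfinite(d[x, :])[None, :]
        through[x, :] = through[:, x] = False
        np.fill_diagonal(through, False)
        counts = np.where(through, sigma[:, x][:, None] * sigma[x, :][None, :], 0.0)
        out[x] = counts[np.triu_indices(n, k=1)].sum()
    return out


def cpl(p: PathMatrix) -> float:
    """Mean shortest-path length over unordered reachable pairs."""
    iu = np.triu_indices(p.n, k=1)
    d = p.d[iu]
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError("no reachable pairs: network has no edges")
    return float(d[finite].mean())


def dpl(g: nx.Graph, tol: float = TIE_TOL) -> tuple[np.ndarray, np.ndarray]:
    """Delta path length per node: ``CPL(G - x) - CPL(G)``.

    Pairs disconnected by the removal are dropped from the post-removal
    average; their count per node is returned as the second array.
    """
    nodes = list(g.nodes)
    if len(nodes) < 3:
        raise ValueError("DPL needs at least 3 nodes")
    base = shortest_paths(g, tol=tol)
    base_cpl = cpl(base)
    deltas = np.empty(len(nodes))
    disconnected = np.zeros(len(nodes), dtype=int)
    for k, x in enumerate(nodes):
        h = g.copy()
        h.remove_node(x)
        if h.number_of_nodes() < 2:
            raise ValueError("node removal leaves fewer than 2 nodes")
        sub = shortest_paths(h, tol=tol)
        sub_d = sub.d[np.triu_indices(sub.n, k=1)]
        if np.isfinite(sub_d).any():
            deltas[k] = cpl(sub) - base_cpl
        else:
            deltas[k] = np.nan  # removal disconnects every remaining pair
        keep = [i for i, u in enumerate(base.nodes) if u != x]
        before = base.reachable[np.ix_(keep, keep)]
        disconnected[k] = int((before & ~sub.reachable).sum() // 2)
    return deltas, disconnected


def zscore_flags(values: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Z-scores over the node set and flags where ``z > cutoff``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("z-scores need at least 2 nodes")
    finite = np.isfinite(values)
    sd = values[finite].std()
    if sd == 0:
        warnings.warn("constant metric: all z-scores 0, nothing flagged")
        z = np.where(finite, 0.0, np.nan)
    else:
        z = (values - values[finite].mean()) / sd
    with np.errstate(invalid="ignore"):
        return z, np.where(np.isfinite(z), z > cutoff, False)


def closeness_tiers(values: np.ndarray) -> list[str]:
    """Rank-percentile tiers: high (top 20 %), intermediate (20–60 %), low.

    Ties share the better tier (all-equal input is entirely "high", with a
    warning).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 5:
        raise ValueError("tiers need at least 5 nodes")
    # competition rank, 1 = highest value; ties get the best rank
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(n, dtype=float)
    rank = 1
    for pos, idx in enumerate(order):
        if pos > 0 and values[idx] == values[order[pos - 1]]:
            ranks[idx] = ranks[order[pos - 1]]
        else:
            ranks[idx] = rank
        rank = pos + 2
    if np.unique(values).size == 1:
        warnings.warn("all closeness values equal: every node tiered 'high'")
    frac = ranks / n
    return [
        "high" if f <= 0.2 else ("intermediate" if f <= 0.6 else "low")
        for f in frac
    ]


def network_metrics(
    g: nx.Graph,
    betweenness_z_cutoff: float = 1.5,
    dpl_z_cutoff: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Full per-node metrics table and a network-level summary.

    Returns a DataFrame (node, closeness, betweenness, dpl, z-scores, flags,
    tier) and a dict with CPL and component count.
    """
    p = shortest_paths(g)
    clo = closeness(p)
    btw = betweenness(p)
    network_cpl = cpl(p)
    deltas, disc = dpl(g)
    btw_z, btw_flag = zscore_flags(btw, betweenness_z_cutoff)
    dpl_z, dpl_flag = zscore_flags(deltas, dpl_z_cutoff)
    tiers = closeness_tiers(clo) if p.n >= 5 else ["high"] * p.n
    table = pd.DataFrame(
        {
            "node": [str(u) for u in p.nodes],
            "closeness": clo,
            "betweenness": btw,
            "dpl": deltas,
            "betweenness_z": btw_z,
            "betweenness_flag": btw_flag,
            "dpl_z": dpl_z,
            "dpl_flag": dpl_flag,
            "dpl_disconnected_pairs": disc,
            "closeness_tier": tiers,
        }
    )
    summary = {
        "cpl": network_cpl,
        "n_nodes": p.n,
        "n_edges": g.number_of_edges(),
        "n_components": len(p.components()),
    }
    return table, summary
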