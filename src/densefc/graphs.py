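"""Thresholded binary graphs and subnetwork measures.

A session's weighted adjacency is reduced to a connected binary graph by
taking the maximum spanning tree and then adding the strongest positive
links until the requested proportional density (10/20/30% of possible
edges) is reached.  On that graph two measures are computed per network:
the mean participation coefficient (between-network integration) and the
within-network global efficiency (mean inverse shortest path length over
the network's nodes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import Adjacency

__all__ = [
    "BinaryGraph",
    "mst_threshold",
    "participation",
    "efficiency_within",
    "metric_series",
]

log = logging.getLogger(__name__)


@dataclass
class BinaryGraph:
    """Undirected unweighted graph over atlas nodes."""

    n_nodes: int
    edges: list[tuple[int, int]]
    density: float = 0.0
    provenance: dict = field(default_factory=dict)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def degree(self) -> np.ndarray:
        return self.adjacency().sum(axis=1)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def mst_threshold(adj: Adjacency | np.ndarray, density: float) -> BinaryGraph:
    """Maximum spanning tree plus strongest positive links up to a density.

    Edges are ranked by (weight descending, then smaller node pair) so the
    result is deterministic under ties.  Links beyond the tree are only added
    while positive; if the tree alone already meets or exceeds the requested
    density (or no positive links remain), the realized density is logged.
    """
    w = adj.weights if isinstance(adj, Adjacency) else np.asarray(adj, float)
    n = w.shape[0]
    if w.shape != (n, n) or not np.allclose(w, w.T, equal_nan=True):
        raise ValueError("adjacency must be square and symmetric")
    iu, ju = np.triu_indices(n, k=1)
    weights = w[iu, ju]
    if not np.isfinite(weights).all():
        finite = np.isfinite(weights)
        iu, ju, weights = iu[finite], ju[finite], weights[finite]
    order = np.lexsort((ju, iu, -weights))
    n_pairs = n * (n - 1) // 2
    target = int(np.ceil(density * n_pairs - 1e-12))

    uf = _UnionFind(n)
    tree: list[tuple[int, int]] = []
    extras: list[tuple[int, int]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            tree.append((i, j))
        else:
            extras.append((i, j))
    edges = list(tree)
    in_extra = iter(extras)
    # walk the same ranking again for non-tree edges, adding positive ones
    for i, j in in_extra:
        if len(edges) >= target:
            break
        if w[i, j] > 0:
            edges.append((i, j))
        else:
            break  # ranking is descending; nothing positive remains
    realized = len(edges) / n_pairs
    if realized > density + 1e-12 or len(edges) < target:
        log.info("realized density %.4f for requested %.2f", realized, density)
    return BinaryGraph(
        n_nodes=n,
        edges=sorted(edges),
        density=realized,
        provenance={"requested_density": density, "n_tree_edges": len(tree)},
    )


def participation(graph: BinaryGraph, communities: np.ndarray) -> np.ndarray:
    """Participation coefficient per node: PC_i = 1 - sum_s (k_is / k_i)^2.

    Measures how evenly a node's edges spread over communities; 0 when every
    edge stays inside the node's own community (and, by convention, for an
    isolated node), approaching 1 - 1/m for an even spread over m communities.
    """
    communities = np.asarray(communities)
    if len(communities) != graph.n_nodes:
        raise ValueError("one community label per node required")
    a = graph.adjacency()
    k = a.sum(axis=1).astype(float)
    labels, idx = np.unique(communities, return_inverse=True)
    onehot = np.eye(len(labels))[idx]            # (n, m)
    k_is = a @ onehot                            # edges from node i into community s
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = 1.0 - ((k_is / k[:, None]) ** 2).sum(axis=1)
    pc[k == 0] = 0.0
    return pc


def _bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in np.nonzero(adj[u])[0]:
                if dist[v] == np.inf:
                    dist[v] = d
                    nxt.append(int(v))
        frontier = nxt
    return dist


def efficiency_within(
    graph: BinaryGraph, network_label, communities: np.ndarray
) -> float:
    """Global efficiency of the induced subgraph on one network's nodes.

    Mean of 1/d(i, j) over unordered node pairs of the network, unweighted
    shortest paths within the induced subgraph; disconnected pairs contribute
    0.  Singleton networks are undefined (NaN).
    """
    communities = np.asarray(communities)
    nodes = np.where(communities == network_label)[0]
    if len(nodes) < 2:
        return float("nan")
    sub = graph.adjacency()[np.ix_(nodes, nodes)]
    total = 0.0
    m = len(nodes)
    for s in range(m):
        dist = _bfs_distances(sub, s)
        finite = np.isfinite(dist[s + 1 :])
        total += (1.0 / dist[s + 1 :][finite]).sum()
    return total / (m * (m - 1) / 2)


def metric_series(
    adjacencies: list[Adjacency],
    atlas: pd.DataFrame,
    networks: list[str],
    densities: tuple[float, ...] = (0.10, 0.20, 0.30),
) -> pd.DataFrame:
    """Per-session network metrics over all thresholds (tidy MetricTable).

    One row per session x network x metric x threshold; participation values
    are the mean coefficient over the network's nodes in the whole-brain
    thresholded graph, efficiency is computed on the network's induced
    subgraph of that same graph.
    """
    communities = atlas["network"].to_numpy()
    rows = []
    for adj in adjacencies:
        for density in densities:
            g = mst_threshold(adj, density)
            pc = participation(g, communities)
            for net in networks:
                members = communities == net
                if not members.any():
                    raise ValueError(f"network {net!r} not present in atlas")
                rows.append(
                    {
                        "session_day": adj.session_day,
                        "task": adj.task,
                        "network": net,
                        "metric": "participation",
                        "threshold": density,
                        "value": float(pc[members].mean()),
                    }
                )
                rows.append(
                    {
                        "session_day": adj.session_day,
                        "task": adj.task,
                        "network": net,
                        "metric": "efficiency",
                        "threshold": density,
                        "value": efficiency_within(g, net, communities),
                    }
                )
    return pd.DataFrame(rows)
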