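"""Nodal graph metrics on binary undirected graphs: degree, global
efficiency, local efficiency, and core number.

Efficiency is preferred over characteristic path length and clustering
because it remains well defined on fragmented graphs: an unreachable pair has
infinite distance and simply contributes ``1/inf = 0``.

Definitions (Latora-Marchiori nodal forms):

* ``Eglob(i) = (1/(N-1)) * sum_{j != i} 1/d_ij`` with ``d_ij`` the shortest
  topological distance (edge count); values lie in [0, 1].
* ``Eloc(i)`` is the same average computed inside the subgraph induced by
  ``i``'s direct neighbors (excluding ``i``), i.e.
  ``(1/(k(k-1))) * sum over ordered neighbor pairs of 1/d``; nodes with
  fewer than two neighbors get 0.
* The core number of a node is the largest ``k`` such that the node survives
  iterative deletion of all nodes with degree < k (k-core peeling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .network import BrainGraph

__all__ = [
    "NodeMetricMap",
    "METRIC_NAMES",
    "shortest_path_lengths",
    "distance_matrix",
    "nodal_degree",
    "nodal_global_efficiency",
    "nodal_local_efficiency",
    "kcore_numbers",
    "subject_metric_maps",
]

METRIC_NAMES = ("degree", "eglob", "eloc", "kcore")


@dataclass
class NodeMetricMap:
    """Per-node values of one metric for one subject at one S level."""

    metric: str
    values: np.ndarray
    subject_id: str | None = None
    s_level: float | None = None

    def __post_init__(self):
        if self.metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric!r}")
        self.values = np.asarray(self.values)

    @property
    def n_nodes(self) -> int:
        return self.values.size


def _adjacency(graph) -> sp.csr_matrix:
    if isinstance(graph, BrainGraph):
        return graph.adjacency
    return sp.csr_matrix(graph)


def shortest_path_lengths(graph, source: int) -> np.ndarray:
    """Unit-weight shortest distances from ``source`` to every node.

    Breadth-first search (identical to Dijkstra with unit weights);
    unreachable nodes get ``inf``.
    """
    adj = _adjacency(graph)
    d = shortest_path(adj, method="D", unweighted=True, directed=False, indices=source)
    return np.asarray(d, dtype=float)


def distance_matrix(graph) -> np.ndarray:
    """All-pairs unit-weight shortest distances (N x N, inf if unreachable)."""
    adj = _adjacency(graph)
    return np.asarray(
        shortest_path(adj, method="D", unweighted=True, directed=False), dtype=float
    )


def nodal_degree(graph, **meta) -> NodeMetricMap:
    """Edge count incident to every node (adjacency row sums)."""
    adj = _adjacency(graph)
    return NodeMetricMap("degree", np.asarray(adj.sum(axis=1)).ravel().astype(np.int64), **meta)


def _efficiency_from_distances(d: np.ndarray) -> np.ndarray:
    """Row means of 1/d over off-diagonal entries; 1/inf treated as 0."""
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (d.shape[0] - 1)


def nodal_global_efficiency(graph, distances: np.ndarray | None = None, **meta) -> NodeMetricMap:
    """Mean inverse shortest-path length from each node to all others."""
    adj = _adjacency(graph)
    if adj.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    d = distance_matrix(adj) if distances is None else distances
    return NodeMetricMap("eglob", _efficiency_from_distances(d.copy()), **meta)


def nodal_local_efficiency(graph, **meta) -> NodeMetricMap:
    """Efficiency of each node's neighbor-induced subgraph.

    Distances are computed *inside* the subgraph; neighbors connected only
    through the removed center count as unreachable.
    """
    adj = _adjacency(graph).tocsr()
    n = adj.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    values = np.zeros(n)
    indptr, indices = adj.indptr, adj.indices
    for i in range(n):
        nbrs = indices[indptr[i]:indptr[i + 1]]
        k = nbrs.size
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        d = shortest_path(sub, method="D", unweighted=True, directed=False)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        values[i] = inv.sum() / (k * (k - 1))
    return NodeMetricMap("eloc", values, **meta)


def kcore_numbers(graph, **meta) -> NodeMetricMap:
    """Core number by iterative peeling.

    For k = 1, 2, ... delete all nodes of degree < k (repeatedly, since
    deletions cascade) until the graph collapses; a node's core number is the
    largest k at which it was still present.
    """
    adj = _adjacency(graph).tocsr()
    n = adj.shape[0]
    degree = np.asarray(adj.sum(axis=1)).ravel().astype(np.int64)
    core = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    indptr, indices = adj.indptr, adj.indices
    k = 1
    deg = degree.copy()
    while alive.any():
        # peel everything of degree < k, cascading
        stack = [i for i in np.flatnonzero(alive) if deg[i] < k]
        while stack:
            i = stack.pop()
            if not alive[i]:
                continue
            alive[i] = False
            core[i] = k - 1
            for j in indices[indptr[i]:indptr[i + 1]]:
                if alive[j]:
                    deg[j] -= 1
                    if deg[j] < k:
                        stack.append(j)
        if alive.any():
            k += 1
    return NodeMetricMap("kcore", core, **meta)


def subject_metric_maps(
    graph: BrainGraph,
    subject_id: str | None = None,
    s_level: float | None = None,
) -> dict[str, NodeMetricMap]:
    """All four nodal metrics for one subject graph, voxel-aligned.

    Isolated nodes get degree = kcore = 0 and eglob = eloc = 0, so the maps
    keep the full node set of the mask.
    """
    meta = {"subject_id": subject_id, "s_level": s_level}
    d = distance_matrix(graph)
    return {
        "degree": nodal_degree(graph, **meta),
        "eglob": nodal_global_efficiency(graph, distances=d, **meta),
        "eloc": nodal_local_efficiency(graph, **meta),
        "kcore": kcore_numbers(graph, **meta),
    }
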