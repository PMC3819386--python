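"""Density-matched binary graph construction from voxel correlation matrices.

Subjects differ in how strong their correlations run, so thresholding at a
fixed correlation would give every subject a different connection density.
Instead the network is sized so that ``S = log(N)/log(K)`` — with ``N`` the
node count and ``K`` the mean degree — takes the same target value for every
subject.  ``S`` is the expected path length of an Erdos-Renyi random network
with the same ``N`` and ``K``, i.e. the theoretical lower bound of the path
length at that density.  Fixing ``S`` fixes the mean degree ``K = N**(1/S)``
and hence the edge count ``M = round(N * K / 2)`` exactly, which is what
cross-subject comparability requires.  Conventional values are S = 2.5 and
S = 3.0 (denser and sparser, respectively).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "CorrelationMatrix",
    "BrainGraph",
    "pearson_matrix",
    "target_degree",
    "target_edge_count",
    "threshold_to_density",
    "achieved_S",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix with bookkeeping for degenerate nodes."""

    values: np.ndarray
    n_time: int
    zero_variance_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class BrainGraph:
    """Binary undirected voxel graph with its density-matching audit trail."""

    adjacency: sp.csr_matrix          # symmetric binary, zero diagonal
    s_target: float
    cutoff: float                     # correlation of the weakest kept edge
    node_coordinates: np.ndarray | None = None  # (N, 3) voxel coords, optional

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    @property
    def achieved_s(self) -> float:
        return achieved_S(self)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def edge_list(self) -> np.ndarray:
        """(M, 2) array of edges with i < j, lexicographically sorted."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        edges = np.column_stack([coo.row, coo.col])
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        return edges[order]


def pearson_matrix(series: np.ndarray) -> CorrelationMatrix:
    """Pearson correlations between every pair of node time series.

    Nodes with zero temporal variance are flagged and their correlations set
    to 0 (they are excluded from edge ranking downstream); the diagonal is 1.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a node x time matrix")
    n, t = series.shape
    if t < 3:
        raise ValueError("need at least 3 time points for correlations")
    sd = series.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        warnings.warn(f"{zero.size} zero-variance node(s) flagged", stacklevel=2)
    safe = series.copy()
    safe[zero] = 0.0
    centered = safe - safe.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1))
    denom[denom == 0] = 1.0
    corr = (centered / denom[:, None]) @ (centered / denom[:, None]).T
    np.clip(corr, -1.0, 1.0, out=corr)
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(values=corr, n_time=t, zero_variance_nodes=zero)


def target_degree(n_nodes: int, s: float) -> float:
    """Mean degree ``K = N**(1/S)`` implied by a density-matching target."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if s <= 0:
        raise ValueError("S must be positive")
    return float(n_nodes) ** (1.0 / s)


def target_edge_count(n_nodes: int, s: float) -> int:
    """Edge count ``M = round(N * N**(1/S) / 2)`` (round half away from zero)."""
    return int(math.floor(n_nodes * target_degree(n_nodes, s) / 2.0 + 0.5))


def threshold_to_density(
    corr: CorrelationMatrix,
    s_target: float,
    node_coordinates: np.ndarray | None = None,
) -> BrainGraph:
    """Keep the ``M`` strongest positive correlations as binary edges.

    Unique node pairs are ranked by correlation descending; ties at the M-th
    rank are broken by ascending ``(i, j)`` node index so edge selection is a
    deterministic function of the matrix and ``S``.  Negative or zero
    correlations are never eligible, and zero-variance nodes stay isolated so
    maps remain voxel-aligned.  Because ``M`` depends only on ``(N, S)``, all
    subjects of a cohort get identical edge counts.
    """
    n = corr.n_nodes
    m_edges = target_edge_count(n, s_target)
    iu, ju = np.triu_indices(n, k=1)
    vals = corr.values[iu, ju]
    eligible = vals > 0
    if corr.zero_variance_nodes.size:
        bad = np.zeros(n, dtype=bool)
        bad[corr.zero_variance_nodes] = True
        eligible &= ~(bad[iu] | bad[ju])
    n_eligible = int(eligible.sum())
    if n_eligible < m_edges:
        raise ValueError(
            f"only {n_eligible} positive-correlation pairs available but "
            f"{m_edges} edges required at S={s_target}; increase S (sparser "
            "network) or supply longer/cleaner series"
        )
    iu, ju, vals = iu[eligible], ju[eligible], vals[eligible]
    # descending correlation, ties by ascending (i, j)
    order = np.lexsort((ju, iu, -vals))[:m_edges]
    ei, ej = iu[order], ju[order]
    cutoff = float(vals[order].min())
    adj = sp.coo_matrix(
        (np.ones(2 * m_edges, dtype=np.int8), (np.r_[ei, ej], np.r_[ej, ei])),
        shape=(n, n),
    ).tocsr()
    graph = BrainGraph(
        adjacency=adj,
        s_target=float(s_target),
        cutoff=cutoff,
        node_coordinates=node_coordinates,
    )
    ach = graph.achieved_s
    if abs(ach - s_target) > 0.02 * s_target:
        warnings.warn(
            f"achieved S={ach:.3f} deviates more than 2% from target {s_target}"
            " (rounding at small N)",
            stacklevel=2,
        )
    return graph


def achieved_S(graph: BrainGraph) -> float:
    """``log(N)/log(mean degree)`` actually realized by a graph."""
    kbar = graph.mean_degree
    if kbar <= 1:
        raise ValueError("achieved S undefined for mean degree <= 1")
    return math.log(graph.n_nodes) / math.log(kbar)
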