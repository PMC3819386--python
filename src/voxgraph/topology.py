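"""Cross-subject topology maps: top-fraction masks, overlap maps, group
difference maps, metric-conjunction ROIs, and seed-connectivity QC maps.

The group-level logic is rank-based rather than value-based: for each subject
and metric, the voxels in the top 20% of that subject's map are marked; the
*overlap map* stores, per voxel, the percentage of subjects marking it; the
*difference map* is the signed between-group difference of overlap
percentages, flagged where it exceeds a criterion (default 25 points); ROIs
are contiguous clusters flagged in the same direction across the three
integration metrics (degree, eglob, kcore).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .metrics import NodeMetricMap
from .network import pearson_matrix

__all__ = [
    "OverlapMap",
    "DifferenceMap",
    "ROI",
    "ROISet",
    "top_fraction_mask",
    "overlap_map",
    "threshold_overlap",
    "difference_map",
    "conjunction_rois",
    "roi_mean_metric",
    "seed_connectivity",
]

DEFAULT_TOP_FRACTION = 0.20
DEFAULT_DISPLAY_CUTOFF = 50.0
DEFAULT_DIFFERENCE_CRITERION = 25.0


@dataclass
class OverlapMap:
    """Per-node percentage of subjects whose top-fraction set contains it."""

    values: np.ndarray                # in [0, 100]
    metric: str
    group: str
    s_level: float | None = None
    top_fraction: float = DEFAULT_TOP_FRACTION
    n_subjects: int = 0


@dataclass
class DifferenceMap:
    """Signed overlap difference ``a - b`` with direction flags at criterion."""

    values: np.ndarray                # groupA% - groupB%, per node
    flags_a_gt_b: np.ndarray          # bool, strictly > criterion
    flags_b_gt_a: np.ndarray
    group_a: str
    group_b: str
    metric: str
    criterion: float = DEFAULT_DIFFERENCE_CRITERION
    s_level: float | None = None


@dataclass
class ROI:
    roi_id: int
    direction: str                    # e.g. "young>old"
    nodes: np.ndarray                 # flat node indices
    centroid: np.ndarray              # voxel-coordinate centroid

    @property
    def size(self) -> int:
        return self.nodes.size


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)

    def by_direction(self, direction: str) -> list[ROI]:
        return [r for r in self.rois if r.direction == direction]

    def all_nodes(self, direction: str | None = None) -> np.ndarray:
        rois = self.rois if direction is None else self.by_direction(direction)
        if not rois:
            return np.array([], dtype=np.int64)
        return np.unique(np.concatenate([r.nodes for r in rois]))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def top_fraction_mask(metric_map: NodeMetricMap | np.ndarray, fraction: float = DEFAULT_TOP_FRACTION) -> np.ndarray:
    """Boolean mask of the ``round(fraction * N)`` highest-valued nodes.

    Ties at the cut are broken by ascending node index, so the selection is
    deterministic and permutation-equivariant on distinct values.  An
    all-equal map degenerates to the first ``round(fraction * N)`` indices
    (warned).
    """
    values = metric_map.values if isinstance(metric_map, NodeMetricMap) else np.asarray(metric_map)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = values.size
    k = _round_half_away(fraction * n)
    if np.all(values == values.flat[0]):
        warnings.warn("degenerate all-equal metric map; selecting first indices", stacklevel=2)
    order = np.lexsort((np.arange(n), -np.asarray(values, dtype=float)))
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


def overlap_map(
    subject_masks: list[np.ndarray] | np.ndarray,
    metric: str = "",
    group: str = "",
    s_level: float | None = None,
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> OverlapMap:
    """Percentage of subjects marking each node: ``100 * mean(indicator)``."""
    stack = np.asarray(subject_masks, dtype=bool)
    if stack.ndim != 2 or stack.shape[0] < 1:
        raise ValueError("need a subjects x nodes boolean stack with >= 1 subject")
    return OverlapMap(
        values=100.0 * stack.mean(axis=0),
        metric=metric,
        group=group,
        s_level=s_level,
        top_fraction=top_fraction,
        n_subjects=stack.shape[0],
    )


def threshold_overlap(map_: OverlapMap, cutoff: float = DEFAULT_DISPLAY_CUTOFF) -> np.ndarray:
    """Display thresholding: zero values below ``cutoff``, keep the rest."""
    if not 0 <= cutoff <= 100:
        raise ValueError("cutoff must be in [0, 100]")
    out = map_.values.copy()
    out[out < cutoff] = 0.0
    return out


def difference_map(
    a: OverlapMap, b: OverlapMap, criterion: float = DEFAULT_DIFFERENCE_CRITERION
) -> DifferenceMap:
    """Signed overlap difference with strict ``> criterion`` direction flags."""
    if a.metric != b.metric or a.s_level != b.s_level:
        raise ValueError("difference maps require the same metric and S level")
    if a.values.shape != b.values.shape:
        raise ValueError("overlap maps are not node-aligned")
    delta = a.values - b.values
    return DifferenceMap(
        values=delta,
        flags_a_gt_b=delta > criterion,
        flags_b_gt_a=-delta > criterion,
        group_a=a.group,
        group_b=b.group,
        metric=a.metric,
        criterion=criterion,
        s_level=a.s_level,
    )


#: 26-connectivity structuring element for 3D cluster labeling
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def conjunction_rois(
    diffs: list[DifferenceMap],
    node_coordinates: np.ndarray,
    grid_dims: tuple[int, int, int] | None = None,
    min_size: int = 2,
) -> ROISet:
    """ROIs from the metric conjunction of difference maps.

    A node qualifies when it is flagged in the *same* direction in every
    supplied difference map (conventionally degree, eglob and kcore — the
    integration metrics — at one S level).  Qualifying nodes are grouped into
    spatially contiguous clusters via 26-connectivity; clusters smaller than
    ``min_size`` voxels are dropped.  An empty conjunction yields an empty
    ROISet with a warning.
    """
    if not diffs:
        raise ValueError("need at least one difference map")
    n = diffs[0].values.size
    if any(d.values.size != n for d in diffs):
        raise ValueError("difference maps are not node-aligned")
    node_coordinates = np.asarray(node_coordinates, dtype=int)
    if node_coordinates.shape != (n, 3):
        raise ValueError("node_coordinates must be (N, 3) voxel coordinates")
    if grid_dims is None:
        grid_dims = tuple(node_coordinates.max(axis=0) + 1)

    dir_a = f"{diffs[0].group_a}>{diffs[0].group_b}"
    dir_b = f"{diffs[0].group_b}>{diffs[0].group_a}"
    conj_a = np.logical_and.reduce([d.flags_a_gt_b for d in diffs])
    conj_b = np.logical_and.reduce([d.flags_b_gt_a for d in diffs])

    rois: list[ROI] = []
    next_id = 1
    for direction, conj in ((dir_a, conj_a), (dir_b, conj_b)):
        vol = np.zeros(grid_dims, dtype=bool)
        coords = node_coordinates[conj]
        vol[coords[:, 0], coords[:, 1], coords[:, 2]] = True
        labeled, n_clusters = ndimage.label(vol, structure=_STRUCT_26)
        node_labels = labeled[
            node_coordinates[:, 0], node_coordinates[:, 1], node_coordinates[:, 2]
        ]
        for lab in range(1, n_clusters + 1):
            nodes = np.flatnonzero(node_labels == lab)
            if nodes.size < min_size:
                continue
            rois.append(
                ROI(
                    roi_id=next_id,
                    direction=direction,
                    nodes=nodes,
                    centroid=node_coordinates[nodes].mean(axis=0),
                )
            )
            next_id += 1
    if not rois:
        warnings.warn("conjunction of difference maps is empty", stacklevel=2)
    return ROISet(
        rois=rois,
        provenance={
            "metrics": [d.metric for d in diffs],
            "s_level": diffs[0].s_level,
            "criterion": diffs[0].criterion,
            "min_size": min_size,
            "connectivity": 26,
        },
    )


def roi_mean_metric(metric_map: NodeMetricMap | np.ndarray, roi: ROI | np.ndarray) -> float:
    """Arithmetic mean of a nodal metric over an ROI's nodes."""
    values = metric_map.values if isinstance(metric_map, NodeMetricMap) else np.asarray(metric_map)
    nodes = roi.nodes if isinstance(roi, ROI) else np.asarray(roi)
    if nodes.size == 0:
        raise ValueError("ROI is empty")
    return float(np.asarray(values, dtype=float)[nodes].mean())


#: cap applied to |r| before the Fisher transform (degenerate r = +-1)
_SEED_R_CAP = 1.0 - 1e-7


def seed_connectivity(
    series: np.ndarray,
    seed_nodes: np.ndarray,
    z_cutoff: float = 2.33,
) -> dict:
    """Seed-based connectivity z-map for QC.

    Correlates the mean time series of ``seed_nodes`` with every node,
    applies the Fisher transform scaled by ``sqrt(T - 3)`` (normal
    approximation), and zeroes nodes below ``z_cutoff``.  Degenerate
    correlations (|r| = 1, e.g. a single-node seed with itself) are capped at
    ``|r| = 1 - 1e-7`` before the transform; seed-internal nodes are reported
    but flagged.
    """
    series = np.asarray(series, dtype=float)
    t = series.shape[1]
    if t < 10:
        raise ValueError("need at least 10 time points")
    seed_nodes = np.asarray(seed_nodes, dtype=int)
    if seed_nodes.size == 0:
        raise ValueError("seed is empty")
    seed_ts = series[seed_nodes].mean(axis=0)
    stacked = np.vstack([seed_ts[None, :], series])
    corr = pearson_matrix(stacked)
    r = corr.values[0, 1:]
    r = np.clip(r, -_SEED_R_CAP, _SEED_R_CAP)
    z = np.arctanh(r) * math.sqrt(t - 3)
    zmap = np.where(np.abs(z) >= z_cutoff, z, 0.0)
    in_seed = np.zeros(series.shape[0], dtype=bool)
    in_seed[seed_nodes] = True
    return {
        "z": zmap,
        "r": r,
        "in_seed": in_seed,
        "z_cutoff": z_cutoff,
        "z_cap": math.atanh(_SEED_R_CAP) * math.sqrt(t - 3),
    }
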