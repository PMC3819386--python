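"""Synthetic multi-subject cohort generator.

Emulates a two-group (young / old) resting-style fMRI cohort at the voxel
scale: each subject carries three runs of node x time BOLD-like series on a 3D
voxel grid, a motion covariate, nuisance components (global signal,
motion-coupled artifact), and scored behavior (SWLS, switch costs, spatial
working memory).

Signal model
------------
Voxel time series follow a Gaussian factor model, white in time::

    x_i(t) = sum_c  lambda_{i,c} f_c(t)  +  g_amp * g(t)
             + m_amp_s * m(t) + sigma_i e_i(t)

where ``f_c`` are unit-variance community factors (one per planted module),
``g`` a global factor shared by every in-mask voxel, ``m`` a motion-coupled
artifact whose amplitude scales with the subject's motion covariate, and
``e_i`` voxel-specific white noise.  Residual variances are chosen so each
voxel has unit variance; a loading configuration whose squared loadings
exceed 1 makes the implied covariance non-PSD and raises
:class:`ParameterizationError`.

Within a community with target correlation ``rho`` every member voxel loads
``sqrt(rho)`` on its factor, so pairwise correlation equals ``rho`` (after the
shared nuisance terms are regressed out).  Group effects are planted by giving
the groups different ``rho`` targets and by adding cross-community loadings to
designated hub voxels in the old group.  Per-subject standard-normal latents
jitter the planted parameters and drive the behavior couplings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehaviorRecord, compute_switch_costs, score_swls, wm_composite_scores

__all__ = [
    "ParameterizationError",
    "CommunityLayout",
    "EffectSpec",
    "CohortSpec",
    "SubjectRecord",
    "default_layout",
    "generate_cohort",
    "implied_covariance",
    "behavior_table",
]

YOUNG = "young"
OLD = "old"


class ParameterizationError(ValueError):
    """Raised when the requested effect sizes imply a non-PSD covariance."""


# --------------------------------------------------------------------------- #
# layout


@dataclass
class CommunityLayout:
    """Assignment of grid voxels to planted communities.

    ``labels`` is a flat int array over the grid in x-fastest raster order
    (0 = background, ``k`` = community ``names[k-1]``).  ``hub_nodes`` lists,
    per community, flat node indices designated as hubs (eligible for
    cross-community coupling boosts).
    """

    grid_dims: tuple[int, int, int]
    labels: np.ndarray
    names: tuple[str, ...]
    hub_nodes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)
        n_grid = int(np.prod(self.grid_dims))
        if self.labels.shape != (n_grid,):
            raise ValueError("labels must be a flat array over the full grid")
        if self.labels.min() < 0 or self.labels.max() > len(self.names):
            raise ValueError("label ids must lie in [0, len(names)]")
        for name, nodes in self.hub_nodes.items():
            nodes = np.asarray(nodes, dtype=np.int64)
            comm = self.community_nodes(name)
            if not np.isin(nodes, comm).all():
                raise ValueError(f"hub nodes of {name!r} not a subset of the community")
            self.hub_nodes[name] = nodes

    @property
    def n_nodes(self) -> int:
        return int(self.labels.size)

    def community_nodes(self, name: str) -> np.ndarray:
        k = self.names.index(name) + 1
        return np.flatnonzero(self.labels == k)

    def background_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)


def _block(grid_dims, xs, ys, zs) -> np.ndarray:
    """Flat x-fastest indices of the block ``[xs) x [ys) x [zs)``."""
    nx, ny, nz = grid_dims
    x, y, z = np.meshgrid(
        np.arange(*xs), np.arange(*ys), np.arange(*zs), indexing="ij"
    )
    return (x + nx * (y + ny * z)).ravel()


def default_layout(grid_dims: tuple[int, int, int] = (12, 12, 12)) -> CommunityLayout:
    """Planted community layout used throughout the package.

    Requires a grid of at least 11 x 11 x 10 voxels.  Communities:

    * ``dmn`` — 4x4x4 cortical module (64 voxels); integration is planted to
      drop in the old group.
    * ``fp`` — 4x4x4 cortical module (64 voxels); stable across groups, and
      the target of the old-group hub coupling boost.
    * ``ctx1``..``ctx6`` — six 5x4x2 filler cortical modules (40 voxels each)
      with intermediate coupling; they populate the upper tail of the nodal
      metric distributions so the top-20% cut is competitive.
    * ``sal`` — 2x2x2 subcortical hub block (8 voxels, all hubs); weakly
      integrated in the young group, boosted in the old group.
    """
    if any(d < m for d, m in zip(grid_dims, (11, 11, 10))):
        raise ValueError("default_layout needs a grid of at least 11 x 11 x 10")
    names = ("dmn", "fp", "ctx1", "ctx2", "ctx3", "ctx4", "ctx5", "ctx6", "sal")
    blocks = {
        "dmn": _block(grid_dims, (1, 5), (1, 5), (1, 5)),
        "fp": _block(grid_dims, (7, 11), (1, 5), (1, 5)),
        "ctx1": _block(grid_dims, (0, 5), (7, 11), (0, 2)),
        "ctx2": _block(grid_dims, (6, 11), (7, 11), (0, 2)),
        "ctx3": _block(grid_dims, (0, 5), (7, 11), (3, 5)),
        "ctx4": _block(grid_dims, (6, 11), (7, 11), (3, 5)),
        "ctx5": _block(grid_dims, (0, 5), (7, 11), (6, 8)),
        "ctx6": _block(grid_dims, (6, 11), (7, 11), (6, 8)),
        "sal": _block(grid_dims, (5, 7), (5, 7), (8, 10)),
    }
    labels = np.zeros(int(np.prod(grid_dims)), dtype=np.int32)
    for k, name in enumerate(names, start=1):
        if labels[blocks[name]].any():
            raise ValueError("community blocks overlap")
        labels[blocks[name]] = k
    return CommunityLayout(
        grid_dims=tuple(grid_dims),
        labels=labels,
        names=names,
        hub_nodes={"sal": blocks["sal"].copy()},
    )


# --------------------------------------------------------------------------- #
# effects


def _default_within(young: bool) -> dict[str, float]:
    base = {"dmn": 0.55, "fp": 0.50, "sal": 0.50}
    base.update({f"ctx{i}": 0.45 for i in range(1, 7)})
    if not young:
        base["dmn"] = 0.05  # planted near-complete loss of module integration
    return base


@dataclass
class EffectSpec:
    """Planted group effects and behavior couplings.

    ``within_corr_*`` give the target within-community correlation per
    community and group.  ``cross_hub_boost_old`` is the loading of old-group
    hub voxels on the ``hub_boost_target`` community factor (0 disables the
    boost); boosted hubs keep ``hub_own_loading_old`` on their own factor.
    ``behavior_couplings`` maps a behavior score to
    ``(community, metric, target correlation)`` — the score is coupled with
    the subject latent that drives that community's planted parameter, with
    the given sign and magnitude.
    """

    within_corr_young: dict[str, float] = field(default_factory=lambda: _default_within(True))
    within_corr_old: dict[str, float] = field(default_factory=lambda: _default_within(False))
    cross_hub_boost_old: float = 0.75
    hub_boost_target: str = "fp"
    hub_own_loading_old: float = 0.40
    behavior_couplings: dict[str, tuple[str, str, float]] = field(
        default_factory=lambda: {
            "swls_total": ("sal", "eglob", 0.5),
            "single_task_rt": ("dmn", "eloc", -0.4),
        }
    )

    def validate(self, layout: CommunityLayout) -> None:
        for table in (self.within_corr_young, self.within_corr_old):
            for name, rho in table.items():
                if name not in layout.names:
                    raise ValueError(f"unknown community {name!r} in effect spec")
                if not (-1.0 < rho < 1.0):
                    raise ValueError(f"within-community correlation {rho} outside (-1, 1)")
        if self.cross_hub_boost_old and self.hub_boost_target not in layout.names:
            raise ValueError(f"unknown hub boost target {self.hub_boost_target!r}")


# --------------------------------------------------------------------------- #
# cohort spec


@dataclass
class CohortSpec:
    """Full description of a simulated cohort.

    Defaults mirror the acquisition emulated throughout the package: three
    runs of 150/220/180 time points at TR = 1.5 s on a 12x12x12 grid.
    """

    n_young: int = 15
    n_old: int = 15
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    run_lengths: tuple[int, ...] = (150, 220, 180)
    tr_seconds: float = 1.5
    layout: CommunityLayout | None = None
    effects: EffectSpec = field(default_factory=EffectSpec)
    global_amp: float = 0.25
    motion_coupling: float = 0.3
    #: lognormal (mu, sigma) of mean relative displacement, mm, per group
    motion_lognorm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {YOUNG: (math.log(0.10), 0.30), OLD: (math.log(0.18), 0.35)}
    )
    rho_jitter: float = 0.03
    hub_boost_jitter: float = 0.06
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_young <= 0 or self.n_old <= 0:
            raise ValueError("group sizes must be positive")
        if not self.run_lengths or any(t <= 0 for t in self.run_lengths):
            raise ValueError("run_lengths must be non-empty positive counts")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.layout is None:
            self.layout = default_layout(self.grid_dims)
        if tuple(self.layout.grid_dims) != tuple(self.grid_dims):
            raise ValueError("layout grid does not match grid_dims")
        self.effects.validate(self.layout)

    @property
    def n_nodes(self) -> int:
        return self.layout.n_nodes

    @property
    def total_time(self) -> int:
        return int(sum(self.run_lengths))


@dataclass
class SubjectRecord:
    """One simulated participant."""

    subject_id: str
    group: str
    runs: list[np.ndarray]            # node x time, one per run
    motion_series: list[np.ndarray]   # time x 6 motion regressors, one per run
    motion: float                     # mean relative displacement, mm
    behavior: BehaviorRecord
    latents: dict[str, float]
    tr: float
    sex: str = "F"

    @property
    def n_nodes(self) -> int:
        return self.runs[0].shape[0]


# --------------------------------------------------------------------------- #
# generation internals


def _subject_loadings(spec: CohortSpec, group: str, latents: dict[str, float]):
    """Per-voxel factor loading matrix (n_nodes x n_factors) for one subject.

    Factor order: one factor per community (layout order).  Returns
    ``(loadings, hub_target_col)``.
    """
    layout = spec.layout
    eff = spec.effects
    table = eff.within_corr_young if group == YOUNG else eff.within_corr_old
    n_comm = len(layout.names)
    loadings = np.zeros((layout.n_nodes, n_comm))
    for k, name in enumerate(layout.names):
        rho = table.get(name, 0.0)
        rho = float(np.clip(rho + spec.rho_jitter * latents[name], 0.0, 0.95))
        loadings[layout.community_nodes(name), k] = math.sqrt(rho)
    if group == OLD and eff.cross_hub_boost_old:
        target_col = layout.names.index(eff.hub_boost_target)
        # jittered boost, clipped so hub voxel variance stays below 1
        boost = float(
            np.clip(eff.cross_hub_boost_old + spec.hub_boost_jitter * latents["sal"], 0.0, 0.85)
        )
        for name, hubs in layout.hub_nodes.items():
            own_col = layout.names.index(name)
            loadings[hubs, own_col] = eff.hub_own_loading_old
            loadings[hubs, target_col] = boost
    return loadings


def _residual_sd(spec: CohortSpec, loadings: np.ndarray, motion_amp: float) -> np.ndarray:
    shared = spec.global_amp**2 + motion_amp**2
    var = 1.0 - (loadings**2).sum(axis=1) - shared
    if (var <= 0).any():
        raise ParameterizationError(
            "implied covariance is not positive semi-definite: squared factor "
            "loadings plus nuisance amplitudes exceed unit variance for "
            f"{int((var <= 0).sum())} voxel(s); reduce within-community "
            "correlations, cross_hub_boost_old, or nuisance amplitudes"
        )
    return np.sqrt(var)


def _ar1_filter(x: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0.0:
        return x
    from scipy.signal import lfilter

    return lfilter([math.sqrt(1 - phi**2)], [1.0, -phi], x, axis=-1)


def _motion_regressors(rng: np.random.Generator, t: int) -> np.ndarray:
    """Six slow drifting series mimicking rigid-body motion estimates."""
    steps = rng.normal(size=(t, 6))
    walk = np.cumsum(steps, axis=0)
    walk -= walk.mean(axis=0)
    walk /= walk.std(axis=0) + 1e-12
    return walk


def _simulate_runs(spec, loadings, resid_sd, motion_amp, rng):
    runs, motion_series = [], []
    n_factors = loadings.shape[1]
    for t in spec.run_lengths:
        factors = _ar1_filter(rng.normal(size=(n_factors, t)), spec.ar1)
        g = _ar1_filter(rng.normal(size=t), spec.ar1)
        motion = _motion_regressors(rng, t)
        noise = rng.normal(size=(spec.n_nodes, t))
        x = loadings @ factors
        x += spec.global_amp * g
        x += motion_amp * motion[:, 0]
        x += resid_sd[:, None] * noise
        runs.append(x)
        motion_series.append(motion)
    return runs, motion_series


def _behavior_for_subject(spec, group, latents, rng) -> BehaviorRecord:
    eff = spec.effects
    rec = BehaviorRecord()

    def coupled_z(score_name: str) -> float:
        if score_name in eff.behavior_couplings:
            comm, _metric, r = eff.behavior_couplings[score_name]
            return r * latents[comm] + math.sqrt(max(0.0, 1 - r**2)) * rng.normal()
        return float(rng.normal())

    # SWLS: mean 26.2, SD 5.5 on the 5-35 scale (typical older-adult sample)
    swls_z = coupled_z("swls_total")
    target = float(np.clip(26.2 + 5.5 * swls_z, 5, 35))
    items = np.clip(np.rint(target / 5 + rng.normal(0, 0.6, 5)), 1, 7).astype(int)
    rec.swls_items = tuple(int(i) for i in items)
    rec.swls_total = score_swls(rec.swls_items)

    # task switching: trial-level RTs around subject means
    base = 600.0 if group == YOUNG else 800.0
    single_mean = base + 90.0 * coupled_z("single_task_rt")
    local_true = (150.0 if group == YOUNG else 250.0) + 30.0 * rng.normal()
    nonswitch_mean = single_mean + 80.0
    trials = pd.DataFrame(
        {
            "condition": ["single-block"] * 96
            + ["mixed-nonswitch"] * 60
            + ["mixed-switch"] * 60,
            "rt_ms": np.clip(
                np.concatenate(
                    [
                        rng.normal(single_mean, 100, 96),
                        rng.normal(nonswitch_mean, 110, 60),
                        rng.normal(nonswitch_mean + local_true, 120, 60),
                    ]
                ),
                150,
                None,
            ),
        }
    )
    local, global_ = compute_switch_costs(trials)
    rec.single_task_rt = float(trials.loc[trials.condition == "single-block", "rt_ms"].mean())
    rec.nonswitch_rt = float(trials.loc[trials.condition == "mixed-nonswitch", "rt_ms"].mean())
    rec.switch_rt = float(trials.loc[trials.condition == "mixed-switch", "rt_ms"].mean())
    rec.mixed_block_rt = float(
        trials.loc[trials.condition != "single-block", "rt_ms"].mean()
    )
    rec.local_cost, rec.global_cost = local, global_

    # spatial working memory: RT grows and accuracy falls with set size
    wm_z = coupled_z("wm_composite")
    set_rt = base + 60 * np.arange(1, 4) - 60 * wm_z + rng.normal(0, 25, 3)
    set_acc = np.clip(0.97 - 0.04 * np.arange(0, 3) + 0.04 * wm_z + rng.normal(0, 0.02, 3), 0, 1)
    rec.spwm_rt = float(set_rt.mean())
    rec.spwm_accuracy = float(set_acc.mean())
    rec.metadata["wm_standardization"] = "cohort z(acc) - z(RT), averaged, re-standardized"
    return rec


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Simulate the full cohort described by ``spec``.

    Deterministic for a fixed ``spec.seed``: every random stream is derived
    from a single :class:`numpy.random.SeedSequence`.
    """
    n_total = spec.n_young + spec.n_old
    children = np.random.SeedSequence(spec.seed).spawn(n_total)
    records: list[SubjectRecord] = []
    groups = [YOUNG] * spec.n_young + [OLD] * spec.n_old
    for idx, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        sex = "F" if rng.random() < 0.5 else "M"
        latents = {name: float(rng.normal()) for name in spec.layout.names}
        mu, sigma = spec.motion_lognorm[group]
        motion = float(np.exp(rng.normal(mu, sigma)))
        motion_amp = spec.motion_coupling * motion
        loadings = _subject_loadings(spec, group, latents)
        resid_sd = _residual_sd(spec, loadings, motion_amp)
        runs, motion_series = _simulate_runs(spec, loadings, resid_sd, motion_amp, rng)
        behavior = _behavior_for_subject(spec, group, latents, rng)
        records.append(
            SubjectRecord(
                subject_id=f"sub-{idx + 1:03d}",
                group=group,
                runs=runs,
                motion_series=motion_series,
                motion=motion,
                behavior=behavior,
                latents=latents,
                tr=spec.tr_seconds,
                sex=sex,
            )
        )
    # cohort-standardized WM composite
    rt = np.array([r.behavior.spwm_rt for r in records])
    acc = np.array([r.behavior.spwm_accuracy for r in records])
    for rec, comp in zip(records, wm_composite_scores(rt, acc)):
        rec.behavior.wm_composite = float(comp)
    return records


def implied_covariance(spec: CohortSpec, group: str, latents: dict[str, float] | None = None,
                       motion: float | None = None) -> np.ndarray:
    """Model voxel covariance ``Lambda Lambda' + shared nuisance + D``.

    Intended for audits on small grids (the matrix is dense ``N x N``).
    """
    if latents is None:
        latents = {name: 0.0 for name in spec.layout.names}
    if motion is None:
        motion = math.exp(spec.motion_lognorm[group][0])
    loadings = _subject_loadings(spec, group, latents)
    motion_amp = spec.motion_coupling * motion
    resid_sd = _residual_sd(spec, loadings, motion_amp)
    cov = loadings @ loadings.T
    cov += spec.global_amp**2 + motion_amp**2
    cov[np.diag_indices_from(cov)] += resid_sd**2
    return cov


def behavior_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tidy per-subject behavior/demographics table."""
    rows = []
    for rec in records:
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "sex": rec.sex,
            "motion_mm": rec.motion,
        }
        row.update(rec.behavior.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
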