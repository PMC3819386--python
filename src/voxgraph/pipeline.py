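"""End-to-end pipeline: simulate -> preprocess -> network -> metrics ->
groupmaps -> stats -> report.

Two layers:

* pure in-memory analysis functions (:func:`preprocess_cohort`,
  :func:`build_graphs`, :func:`compute_metric_maps`, :func:`group_topology_maps`,
  :func:`stats_battery`) used directly by tests and scripts;
* cached disk stages (:func:`run_pipeline`) — each stage writes its outputs
  plus a ``.stage.json`` sidecar recording a hash of the configuration slice
  it depends on and of its upstream stage, so re-running with an unchanged
  config re-executes nothing, and changing e.g. only the S levels re-runs
  the network stage onward only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorRecord
from .config import PipelineConfig
from .io import ProvenanceLog, config_hash, write_metric_nifti, write_tsv
from .metrics import METRIC_NAMES, subject_metric_maps
from .network import BrainGraph, pearson_matrix, threshold_to_density
from .preprocess import CleanSeries, GrayMatterMask, preprocess_subject
from .simulate import (
    OLD,
    YOUNG,
    CohortSpec,
    SubjectRecord,
    behavior_table,
    generate_cohort,
)
from .stats import (
    RegressionSpec,
    RoiMetricTable,
    build_interaction,
    dual_threshold_significance,
    hierarchical_regression,
    manova_pillai,
    pearson_correlation,
    rm_group_by_roi_interaction,
    univariate_anova,
)
from .topology import (
    conjunction_rois,
    difference_map,
    overlap_map,
    roi_mean_metric,
    top_fraction_mask,
)

__all__ = [
    "STAGES",
    "cohort_spec_from_config",
    "preprocess_cohort",
    "build_graphs",
    "compute_metric_maps",
    "group_topology_maps",
    "roi_metric_table",
    "stats_battery",
    "analyze_cohort",
    "CohortAnalysis",
    "run_pipeline",
]

STAGES = ("simulate", "preprocess", "network", "metrics", "groupmaps", "stats", "report")

INTEGRATION_METRICS = ("degree", "eglob", "kcore")  # conjunction-ROI metrics


# --------------------------------------------------------------------------- #
# in-memory analysis


def cohort_spec_from_config(cfg: PipelineConfig) -> CohortSpec:
    return CohortSpec(
        n_young=cfg.n_young,
        n_old=cfg.n_old,
        grid_dims=cfg.grid_dims,
        run_lengths=cfg.run_lengths,
        tr_seconds=cfg.tr_seconds,
        seed=cfg.seed,
    )


def preprocess_cohort(records: list[SubjectRecord], cfg: PipelineConfig) -> list[CleanSeries]:
    return [
        preprocess_subject(
            rec.runs,
            motion_series=rec.motion_series,
            tr_seconds=cfg.tr_seconds,
            lo_hz=cfg.lo_hz,
            hi_hz=cfg.hi_hz,
        )
        for rec in records
    ]


def build_graphs(
    clean: list[CleanSeries],
    s_levels,
    node_coordinates: np.ndarray | None = None,
) -> dict[float, list[BrainGraph]]:
    """Per-subject density-matched graphs at every S level."""
    graphs: dict[float, list[BrainGraph]] = {float(s): [] for s in s_levels}
    for series in clean:
        corr = pearson_matrix(series.data)
        for s in s_levels:
            graphs[float(s)].append(
                threshold_to_density(corr, float(s), node_coordinates=node_coordinates)
            )
    return graphs


def compute_metric_maps(
    graphs: dict[float, list[BrainGraph]],
    subject_ids: list[str] | None = None,
) -> dict[float, dict[str, np.ndarray]]:
    """Nodal metric maps, stacked subjects x nodes per metric and S."""
    out: dict[float, dict[str, np.ndarray]] = {}
    for s, glist in graphs.items():
        per_metric = {m: [] for m in METRIC_NAMES}
        for i, g in enumerate(glist):
            sid = subject_ids[i] if subject_ids else None
            maps = subject_metric_maps(g, subject_id=sid, s_level=s)
            for m in METRIC_NAMES:
                per_metric[m].append(maps[m].values)
        out[s] = {m: np.vstack(v) for m, v in per_metric.items()}
    return out


def group_topology_maps(
    metric_maps: dict[float, dict[str, np.ndarray]],
    groups: np.ndarray,
    node_coordinates: np.ndarray,
    grid_dims,
    cfg: PipelineConfig,
):
    """Overlap maps, difference maps, and conjunction ROIs at every S."""
    groups = np.asarray(groups)
    overlaps: dict[float, dict[str, dict[str, object]]] = {}
    diffs: dict[float, dict[str, object]] = {}
    rois: dict[float, object] = {}
    for s, per_metric in metric_maps.items():
        overlaps[s] = {}
        diffs[s] = {}
        for metric, stack in per_metric.items():
            masks = np.vstack(
                [top_fraction_mask(row, cfg.top_fraction) for row in stack]
            )
            o_young = overlap_map(masks[groups == YOUNG], metric, YOUNG, s, cfg.top_fraction)
            o_old = overlap_map(masks[groups == OLD], metric, OLD, s, cfg.top_fraction)
            overlaps[s][metric] = {YOUNG: o_young, OLD: o_old}
            diffs[s][metric] = difference_map(o_young, o_old, cfg.difference_criterion)
        rois[s] = conjunction_rois(
            [diffs[s][m] for m in INTEGRATION_METRICS],
            node_coordinates,
            grid_dims=tuple(grid_dims),
            min_size=cfg.roi_min_size,
        )
    return overlaps, diffs, rois


def roi_metric_table(
    stack: np.ndarray,
    roi_nodes: list[np.ndarray],
    groups: np.ndarray,
    roi_names: list[str],
    metric: str,
    s_level: float,
) -> RoiMetricTable:
    values = np.column_stack(
        [stack[:, nodes].mean(axis=1) for nodes in roi_nodes]
    )
    return RoiMetricTable(
        values=values,
        groups=np.asarray(groups),
        roi_names=roi_names,
        metric=metric,
        s_level=s_level,
    )


def stats_battery(
    metric_maps: dict[float, dict[str, np.ndarray]],
    rois: dict[float, object],
    behavior: pd.DataFrame,
    cfg: PipelineConfig,
) -> dict:
    """The full inference battery on conjunction-ROI metric means.

    ROIs come from the conjunction at the first (densest) S level and are
    then evaluated at every S level: MANOVA per contrast direction,
    univariate ANOVA per ROI, the group x ROI repeated-measures interaction,
    a hierarchical regression predicting single-task RT from the mean local
    efficiency of the young>old ROIs, and SWLS - global-efficiency
    correlations in the old>young ROIs (old group only).  Effects are
    admitted only when significant with a consistent sign at every S level
    (the dual-threshold rule).
    """
    s_ref = float(cfg.s_levels[0])
    roi_set = rois[s_ref]
    groups = behavior["group"].to_numpy()
    rows: list[dict] = []
    regression_steps: dict = {}
    dual: dict[str, dict] = {}

    directions = sorted({r.direction for r in roi_set})
    for s in (float(x) for x in cfg.s_levels):
        for metric in ("eglob", "eloc"):
            stack = metric_maps[s][metric]
            for direction in directions:
                sub = roi_set.by_direction(direction)
                table = roi_metric_table(
                    stack,
                    [r.nodes for r in sub],
                    groups,
                    [f"roi{r.roi_id}" for r in sub],
                    metric,
                    s,
                )
                if table.n_rois < table.n_subjects - 1:
                    res = manova_pillai(table)
                    rows.append(
                        _row("manova", s, metric, direction, res.name, res.value,
                             res.df, res.p, res.effect_size)
                    )
                for r in sub:
                    res = univariate_anova(stack[:, r.nodes].mean(axis=1), groups)
                    rows.append(
                        _row("anova", s, metric, f"{direction}:roi{r.roi_id}",
                             res.name, res.value, res.df, res.p, res.effect_size)
                    )
            if len(roi_set) >= 2:
                table_all = roi_metric_table(
                    stack,
                    [r.nodes for r in roi_set],
                    groups,
                    [f"roi{r.roi_id}" for r in roi_set],
                    metric,
                    s,
                )
                res = rm_group_by_roi_interaction(table_all)
                rows.append(
                    _row("rm_interaction", s, metric, "all", res.name, res.value,
                         res.df, res.p, res.effect_size)
                )

    # hierarchical regression: single-task RT ~ group + sex, + eloc(young>old ROIs)
    yo_nodes = roi_set.all_nodes(f"{YOUNG}>{OLD}")
    beta_results = {}
    # four predictors + intercept: require a couple of residual df
    if yo_nodes.size and len(behavior) >= 8:
        for s in (float(x) for x in cfg.s_levels):
            df = behavior.copy()
            df["roi_eloc"] = metric_maps[s]["eloc"][:, yo_nodes].mean(axis=1)
            df["sex_code"] = (df["sex"] == "M").astype(float) - 0.5
            df = build_interaction(df, "group", "roi_eloc", name="group_x_metric")
            spec = RegressionSpec(
                dependent="single_task_rt",
                blocks=[["group_code", "sex_code"], ["roi_eloc_c"], ["group_x_metric"]],
            )
            steps = hierarchical_regression(df, spec)
            regression_steps[s] = steps
            coef = steps[1]["coefficients"]["roi_eloc_c"]
            beta_results[s] = coef
            rows.append(
                _row("regression", s, "eloc", f"{YOUNG}>{OLD}", "beta_metric",
                     coef["beta"], (float(steps[1]["df_resid"]),), coef["p"], coef["beta"])
            )
        from .stats import StatResult

        pair = [
            StatResult("beta", beta_results[s]["beta"], None, beta_results[s]["p"],
                       effect_size=beta_results[s]["beta"])
            for s in (float(x) for x in cfg.s_levels[:2])
        ]
        if len(pair) == 2:
            dual["regression_beta"] = {
                "passes": bool(dual_threshold_significance(pair[0], pair[1], cfg.alpha)),
                "values": {str(s): beta_results[s] for s in beta_results},
            }

    # SWLS correlations with Eglob in old>young ROIs, old group only
    oy_nodes = roi_set.all_nodes(f"{OLD}>{YOUNG}")
    if oy_nodes.size and int((groups == OLD).sum()) >= 4:
        old_sel = groups == OLD
        swls = behavior.loc[old_sel, "swls_total"].to_numpy(float)
        corr_results = {}
        for s in (float(x) for x in cfg.s_levels):
            eglob_roi = metric_maps[s]["eglob"][np.asarray(old_sel), :][:, oy_nodes].mean(axis=1)
            res = pearson_correlation(eglob_roi, swls)
            corr_results[s] = res
            rows.append(
                _row("swls_correlation", s, "eglob", f"{OLD}>{YOUNG}", res.name,
                     res.value, res.df, res.p, res.effect_size)
            )
        pair = [corr_results[float(s)] for s in cfg.s_levels[:2]]
        if len(pair) == 2:
            dual["swls_correlation"] = {
                "passes": bool(dual_threshold_significance(pair[0], pair[1], cfg.alpha)),
                "values": {str(s): corr_results[float(s)].value for s in cfg.s_levels[:2]},
            }

    results = pd.DataFrame(
        rows,
        columns=["analysis", "s", "metric", "contrast", "statistic",
                 "value", "df1", "df2", "p", "effect_size"],
    )
    return {"results": results, "regression": regression_steps, "dual_threshold": dual}


def _row(analysis, s, metric, contrast, statistic, value, df, p, effect):
    df1 = df[0] if df else np.nan
    df2 = df[1] if df and len(df) > 1 else np.nan
    return {
        "analysis": analysis,
        "s": s,
        "metric": metric,
        "contrast": contrast,
        "statistic": statistic,
        "value": float(value),
        "df1": float(df1),
        "df2": float(df2),
        "p": float(p),
        "effect_size": float(effect) if effect is not None else np.nan,
    }


@dataclass
class CohortAnalysis:
    """Everything the in-memory pipeline computes for one cohort."""

    records: list[SubjectRecord]
    behavior: pd.DataFrame
    mask: GrayMatterMask
    clean: list[CleanSeries]
    graphs: dict[float, list[BrainGraph]]
    metric_maps: dict[float, dict[str, np.ndarray]]
    overlaps: dict = field(default_factory=dict)
    diffs: dict = field(default_factory=dict)
    rois: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)


def analyze_cohort(records: list[SubjectRecord], cfg: PipelineConfig) -> CohortAnalysis:
    """Run the whole analysis in memory on an existing cohort."""
    mask = GrayMatterMask.full(cfg.grid_dims)
    coords = mask.coordinates()
    clean = preprocess_cohort(records, cfg)
    graphs = build_graphs(clean, cfg.s_levels, node_coordinates=coords)
    maps = compute_metric_maps(graphs, [r.subject_id for r in records])
    groups = np.array([r.group for r in records])
    overlaps, diffs, rois = group_topology_maps(maps, groups, coords, cfg.grid_dims, cfg)
    behavior = behavior_table(records)
    stats = stats_battery(maps, rois, behavior, cfg)
    return CohortAnalysis(
        records=records,
        behavior=behavior,
        mask=mask,
        clean=clean,
        graphs=graphs,
        metric_maps=maps,
        overlaps=overlaps,
        diffs=diffs,
        rois=rois,
        stats=stats,
    )


# --------------------------------------------------------------------------- #
# disk stages with caching


def _stage_dir(cfg, stage) -> Path:
    return Path(cfg.out_dir) / stage


def _stage_config(cfg: PipelineConfig, stage: str) -> dict:
    keys = {
        "simulate": ["n_young", "n_old", "grid_dims", "run_lengths", "tr_seconds", "seed"],
        "preprocess": ["lo_hz", "hi_hz", "tr_seconds"],
        "network": ["s_levels"],
        "metrics": [],
        "groupmaps": ["top_fraction", "display_cutoff", "difference_criterion", "roi_min_size"],
        "stats": ["alpha", "s_levels"],
        "report": [],
    }[stage]
    return {k: getattr(cfg, k) for k in keys}


def _read_sidecar(path: Path) -> str | None:
    f = path / ".stage.json"
    if f.exists():
        return json.loads(f.read_text()).get("hash")
    return None


def _write_sidecar(path: Path, h: str):
    (path / ".stage.json").write_text(json.dumps({"hash": h}, sort_keys=True))


def run_pipeline(cfg: PipelineConfig, stages=None, force: bool = False) -> dict:
    """Execute (or resume) the pipeline; returns per-stage status.

    A stage is skipped when its sidecar hash — covering its configuration
    slice and the upstream stage hash — is unchanged.  Identical config and
    seed therefore reproduce identical outputs without recomputation.
    """
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = ProvenanceLog(out / "provenance.jsonl")
    status: dict[str, str] = {}
    upstream = ""
    for stage in STAGES:
        h = config_hash({"cfg": _stage_config(cfg, stage), "upstream": upstream})
        sdir = _stage_dir(cfg, stage)
        if stage not in stages:
            upstream = _read_sidecar(sdir) or h
            continue
        if not force and _read_sidecar(sdir) == h:
            status[stage] = "cached"
            upstream = h
            continue
        sdir.mkdir(parents=True, exist_ok=True)
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as exc:  # halt with stage name per contract
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        _write_sidecar(sdir, h)
        log.record(stage, h, cfg.seed)
        status[stage] = "ran"
        upstream = h
    return status


def _stage_simulate(cfg: PipelineConfig):
    spec = cohort_spec_from_config(cfg)
    records = generate_cohort(spec)
    sdir = _stage_dir(cfg, "simulate")
    for rec in records:
        np.savez_compressed(
            sdir / f"{rec.subject_id}.npz",
            **{f"run_{i}": r for i, r in enumerate(rec.runs)},
            **{f"motion_{i}": m for i, m in enumerate(rec.motion_series)},
            motion=np.array(rec.motion),
        )
    write_tsv(behavior_table(records), sdir / "behavior.tsv")
    np.savez_compressed(
        sdir / "layout.npz",
        labels=spec.layout.labels,
        grid_dims=np.array(spec.layout.grid_dims),
        names=np.array(spec.layout.names),
        **{f"hub_{k}": v for k, v in spec.layout.hub_nodes.items()},
    )


def _load_cohort(cfg: PipelineConfig):
    sdir = _stage_dir(cfg, "simulate")
    behavior = pd.read_csv(sdir / "behavior.tsv", sep="\t")
    records = []
    n_runs = len(cfg.run_lengths)
    for _, row in behavior.iterrows():
        with np.load(sdir / f"{row.subject_id}.npz") as z:
            runs = [z[f"run_{i}"] for i in range(n_runs)]
            motion_series = [z[f"motion_{i}"] for i in range(n_runs)]
            motion = float(z["motion"])
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                group=row.group,
                runs=runs,
                motion_series=motion_series,
                motion=motion,
                behavior=BehaviorRecord(),
                latents={},
                tr=cfg.tr_seconds,
                sex=row.sex,
            )
        )
    return records, behavior


def _stage_preprocess(cfg: PipelineConfig):
    records, _ = _load_cohort(cfg)
    sdir = _stage_dir(cfg, "preprocess")
    for rec in records:
        clean = preprocess_subject(
            rec.runs, rec.motion_series, cfg.tr_seconds, cfg.lo_hz, cfg.hi_hz
        )
        np.savez_compressed(
            sdir / f"{rec.subject_id}_clean.npz",
            data=clean.data,
            boundaries=np.array(clean.run_boundaries),
        )


def _subject_ids(cfg):
    behavior = pd.read_csv(_stage_dir(cfg, "simulate") / "behavior.tsv", sep="\t")
    return behavior["subject_id"].tolist(), behavior


def _stage_network(cfg: PipelineConfig):
    ids, _ = _subject_ids(cfg)
    pdir = _stage_dir(cfg, "preprocess")
    sdir = _stage_dir(cfg, "network")
    coords = GrayMatterMask.full(cfg.grid_dims).coordinates()
    for sid in ids:
        with np.load(pdir / f"{sid}_clean.npz") as z:
            data = z["data"]
        corr = pearson_matrix(data)
        for s in cfg.s_levels:
            g = threshold_to_density(corr, float(s), node_coordinates=coords)
            edges = g.edge_list()
            np.savez_compressed(sdir / f"{sid}_S{s:g}_edges.npz", edges=edges)
            meta = {
                "n_nodes": g.n_nodes,
                "s_target": g.s_target,
                "n_edges": g.n_edges,
                "cutoff": g.cutoff,
                "achieved_s": g.achieved_s,
                "mean_degree": g.mean_degree,
            }
            (sdir / f"{sid}_S{s:g}_meta.json").write_text(
                json.dumps(meta, sort_keys=True)
            )


def _load_graph(cfg, sid, s) -> BrainGraph:
    import scipy.sparse as sp

    sdir = _stage_dir(cfg, "network")
    with np.load(sdir / f"{sid}_S{s:g}_edges.npz") as z:
        edges = z["edges"]
    meta = json.loads((sdir / f"{sid}_S{s:g}_meta.json").read_text())
    n = meta["n_nodes"]
    adj = sp.coo_matrix(
        (
            np.ones(2 * len(edges), dtype=np.int8),
            (
                np.r_[edges[:, 0], edges[:, 1]],
                np.r_[edges[:, 1], edges[:, 0]],
            ),
        ),
        shape=(n, n),
    ).tocsr()
    coords = GrayMatterMask.full(cfg.grid_dims).coordinates()
    return BrainGraph(
        adjacency=adj,
        s_target=meta["s_target"],
        cutoff=meta["cutoff"],
        node_coordinates=coords,
    )


def _stage_metrics(cfg: PipelineConfig):
    ids, _ = _subject_ids(cfg)
    sdir = _stage_dir(cfg, "metrics")
    for sid in ids:
        for s in cfg.s_levels:
            g = _load_graph(cfg, sid, float(s))
            maps = subject_metric_maps(g, subject_id=sid, s_level=float(s))
            np.savez_compressed(
                sdir / f"{sid}_S{s:g}_metrics.npz",
                **{m: maps[m].values for m in METRIC_NAMES},
            )


def _load_metric_maps(cfg) -> dict[float, dict[str, np.ndarray]]:
    ids, _ = _subject_ids(cfg)
    sdir = _stage_dir(cfg, "metrics")
    out = {}
    for s in cfg.s_levels:
        per_metric = {m: [] for m in METRIC_NAMES}
        for sid in ids:
            with np.load(sdir / f"{sid}_S{s:g}_metrics.npz") as z:
                for m in METRIC_NAMES:
                    per_metric[m].append(z[m])
        out[float(s)] = {m: np.vstack(v) for m, v in per_metric.items()}
    return out


def _stage_groupmaps(cfg: PipelineConfig):
    ids, behavior = _subject_ids(cfg)
    maps = _load_metric_maps(cfg)
    mask = GrayMatterMask.full(cfg.grid_dims)
    coords = mask.coordinates()
    groups = behavior["group"].to_numpy()
    overlaps, diffs, rois = group_topology_maps(maps, groups, coords, cfg.grid_dims, cfg)
    sdir = _stage_dir(cfg, "groupmaps")
    for s in maps:
        arrays = {}
        for metric in maps[s]:
            for grp, om in overlaps[s][metric].items():
                arrays[f"overlap_{metric}_{grp}"] = om.values
                write_metric_nifti(
                    sdir / f"overlap_{metric}_{grp}_S{s:g}.nii.gz", om.values, mask
                )
            arrays[f"diff_{metric}"] = diffs[s][metric].values
        np.savez_compressed(sdir / f"maps_S{s:g}.npz", **arrays)
        roi_rows = [
            {
                "roi_id": r.roi_id,
                "direction": r.direction,
                "size": r.size,
                "centroid_x": r.centroid[0],
                "centroid_y": r.centroid[1],
                "centroid_z": r.centroid[2],
                "nodes": ";".join(map(str, r.nodes.tolist())),
            }
            for r in rois[s]
        ]
        write_tsv(
            pd.DataFrame(
                roi_rows,
                columns=["roi_id", "direction", "size", "centroid_x",
                         "centroid_y", "centroid_z", "nodes"],
            ),
            sdir / f"rois_S{s:g}.tsv",
        )
        label_vol = np.zeros(mask.n_nodes)
        for r in rois[s]:
            label_vol[r.nodes] = r.roi_id
        write_metric_nifti(sdir / f"rois_S{s:g}.nii.gz", label_vol, mask)


def _load_rois(cfg):
    from .topology import ROI, ROISet

    sdir = _stage_dir(cfg, "groupmaps")
    rois = {}
    for s in cfg.s_levels:
        df = pd.read_csv(sdir / f"rois_S{s:g}.tsv", sep="\t")
        items = [
            ROI(
                roi_id=int(row.roi_id),
                direction=row.direction,
                nodes=np.array([int(x) for x in str(row.nodes).split(";")]),
                centroid=np.array([row.centroid_x, row.centroid_y, row.centroid_z]),
            )
            for _, row in df.iterrows()
        ]
        rois[float(s)] = ROISet(rois=items)
    return rois


def _stage_stats(cfg: PipelineConfig):
    _, behavior = _subject_ids(cfg)
    maps = _load_metric_maps(cfg)
    rois = _load_rois(cfg)
    out = stats_battery(maps, rois, behavior, cfg)
    sdir = _stage_dir(cfg, "stats")
    write_tsv(out["results"], sdir / "results.tsv")
    (sdir / "dual_threshold.json").write_text(
        json.dumps(out["dual_threshold"], sort_keys=True, indent=2, default=str)
    )
    (sdir / "regression.json").write_text(
        json.dumps(out["regression"], sort_keys=True, indent=2, default=str)
    )


def _stage_report(cfg: PipelineConfig):
    stats_dir = _stage_dir(cfg, "stats")
    if not (stats_dir / "results.tsv").exists():
        raise FileNotFoundError("stats stage outputs missing; run 'stats' first")
    results = pd.read_csv(stats_dir / "results.tsv", sep="\t")
    _, behavior = _subject_ids(cfg)
    maps = _load_metric_maps(cfg)
    rois = _load_rois(cfg)
    sdir = _stage_dir(cfg, "report")
    sdir.mkdir(parents=True, exist_ok=True)

    anova = results[results["analysis"] == "anova"].copy()
    write_tsv(anova, sdir / "roi_anova_table.tsv")

    # efficiency-by-group bar data
    s_ref = float(cfg.s_levels[0])
    groups = behavior["group"].to_numpy()
    bar_rows = []
    for s in (float(x) for x in cfg.s_levels):
        for metric in ("eglob", "eloc"):
            stack = maps[s][metric]
            for r in rois[s_ref]:
                vals = stack[:, r.nodes].mean(axis=1)
                for grp in np.unique(groups):
                    sel = groups == grp
                    bar_rows.append(
                        {
                            "s": s,
                            "metric": metric,
                            "roi_id": r.roi_id,
                            "direction": r.direction,
                            "group": grp,
                            "mean": vals[sel].mean(),
                            "sem": vals[sel].std(ddof=1) / np.sqrt(sel.sum()),
                        }
                    )
    bar = pd.DataFrame(bar_rows)
    write_tsv(bar, sdir / "efficiency_by_group.tsv")

    # SWLS scatter data (old group, old>young ROIs)
    oy = rois[s_ref].all_nodes(f"{OLD}>{YOUNG}")
    if oy.size:
        old_sel = groups == OLD
        scatter_rows = []
        for s in (float(x) for x in cfg.s_levels):
            eglob_roi = maps[s]["eglob"][old_sel][:, oy].mean(axis=1)
            for sid, eg, sw in zip(
                behavior.loc[old_sel, "subject_id"],
                eglob_roi,
                behavior.loc[old_sel, "swls_total"],
            ):
                scatter_rows.append(
                    {"s": s, "subject_id": sid, "roi_eglob": eg, "swls_total": sw}
                )
        write_tsv(pd.DataFrame(scatter_rows), sdir / "swls_scatter.tsv")

    _report_figures(sdir, bar)


def _report_figures(sdir: Path, bar: pd.DataFrame):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if bar.empty:
        return
    fig, ax = plt.subplots(figsize=(8, 4))
    sub = bar[(bar["metric"] == "eglob") & (bar["s"] == bar["s"].min())]
    width = 0.35
    rois_ids = sorted(sub["roi_id"].unique())
    for k, grp in enumerate(sorted(sub["group"].unique())):
        sel = sub[sub["group"] == grp].set_index("roi_id").loc[rois_ids]
        ax.bar(
            np.arange(len(rois_ids)) + k * width,
            sel["mean"],
            width,
            yerr=sel["sem"],
            label=grp,
        )
    ax.set_xticks(np.arange(len(rois_ids)) + width / 2)
    ax.set_xticklabels([f"ROI {r}" for r in rois_ids])
    ax.set_ylabel("mean nodal Eglob")
    ax.legend()
    fig.tight_layout()
    fig.savefig(sdir / "efficiency_by_group.png", dpi=100)
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "network": _stage_network,
    "metrics": _stage_metrics,
    "groupmaps": _stage_groupmaps,
    "stats": _stage_stats,
    "report": _stage_report,
}
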