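# voxgraph

Voxel-wise functional brain-network analysis: density-matched binary graph
construction, nodal integration/segregation metrics, cross-subject topology
maps, and brain–behavior statistics — with a synthetic multi-subject cohort
generator that makes the whole pipeline testable end to end.

## The problem

Resting-style fMRI connectivity can be modeled as a graph in which every
gray-matter **voxel** is a node and edges link voxels whose BOLD time series
are strongly correlated. Comparing such graphs across people is only
meaningful if the networks have the same connection density, because almost
every graph metric depends on density. The analysis implemented here fixes
density through the constant

```
S = log(N) / log(K)
```

where *N* is the node count and *K* the mean degree. *S* is the expected path
length of an Erdős–Rényi random network with the same *N* and *K* — the
theoretical lower bound of the path length at that density. Holding *S* fixed
(conventionally **S = 2.5** and **S = 3.0**) fixes `K = N^(1/S)` and hence the
edge count `M = round(N·K/2)` identically for every subject: each subject's
Pearson correlation matrix is thresholded to keep exactly its *M* strongest
positive correlations.

From each binary graph four nodal metrics are computed:

- **degree** `K(i)` — number of incident edges;
- **global efficiency** `Eglob(i) = (1/(N−1)) Σ_{j≠i} 1/d_ij`, with `d_ij`
  the shortest topological distance and `1/∞ = 0` for unreachable pairs;
- **local efficiency** `Eloc(i)` — the same average inside the subgraph
  induced by *i*'s direct neighbors (excluding *i*);
- **core number** — the largest *k* such that the node survives iterative
  removal of all nodes of degree < *k*.

Group topology is summarized rank-wise: per subject, the voxels in the **top
20%** of each metric map are marked; the **overlap map** gives the percentage
of subjects marking each voxel (a voxel marked by 6 of 10 subjects scores
60); maps are displayed at ≥ 50% overlap; the **difference map** between two
groups is flagged where it exceeds **25 points**; contiguous clusters flagged
in the same direction across the three integration metrics (degree, Eglob,
core) form conjunction **ROIs**. ROI-level metric means then feed MANOVAs
(Pillai's trace), univariate ANOVAs with η², a group × ROI repeated-measures
interaction, hierarchical regressions against behavior, correlations with
life-satisfaction (SWLS) scores, and a dual-threshold rule that admits an
effect only if it is significant with a consistent sign at both S levels.

Because no public voxel-level dataset accompanies this design, the package
ships a **synthetic cohort generator** (`voxgraph.simulate`): a Gaussian
factor model plants modular correlation structure (DMN-like, fronto-parietal
and filler cortical modules, plus a small subcortical hub block), group
differences (loss of cortical-module integration and boosted subcortical-hub
coupling in the "old" group), nuisance components (global signal,
motion-coupled artifact), and behavior coupled to the planted latents.

## Worked example

```python
from voxgraph import CohortSpec, PipelineConfig, generate_cohort
from voxgraph.pipeline import analyze_cohort

spec = CohortSpec(n_young=15, n_old=15, seed=1)   # 12x12x12 grid, runs 150/220/180, TR 1.5 s
ana = analyze_cohort(generate_cohort(spec), PipelineConfig(seed=1))

g = ana.graphs[2.5][0]
print(f"subject 1: N={g.n_nodes} nodes, M={g.n_edges} edges, "
      f"mean degree K={g.mean_degree:.2f}, achieved S={g.achieved_s:.4f}, "
      f"correlation cutoff r={g.cutoff:.3f}")
for roi in ana.rois[2.5]:
    print(f"ROI {roi.roi_id}: {roi.direction:<10} {roi.size:3d} voxels, "
          f"centroid {tuple(float(round(c, 1)) for c in roi.centroid)}")
res = ana.stats["results"]
manova = res[(res.analysis == "manova") & (res.s == 2.5) & (res.metric == "eglob")]
for _, row in manova.iterrows():
    print(f"MANOVA eglob {row.contrast:<10} V={row.value:.3f} "
          f"F({row.df1:.0f},{row.df2:.0f}) p={row.p:.2g} eta_p2={row.effect_size:.3f}")
```

prints (in a few minutes on one CPU):

```
subject 1: N=1728 nodes, M=17042 edges, mean degree K=19.72, achieved S=2.5000, correlation cutoff r=0.236
ROI 1: young>old   64 voxels, centroid (2.5, 2.5, 2.5)
ROI 2: old>young    8 voxels, centroid (5.5, 5.5, 8.5)
MANOVA eglob old>young  V=0.862 F(1,28) p=1.4e-13 eta_p2=0.862
MANOVA eglob young>old  V=0.838 F(1,28) p=1.3e-12 eta_p2=0.838
```

Reading this: every subject's graph has exactly 17,042 edges (density
matching is exact), and the achieved `log(N)/log(K)` reproduces the S = 2.5
target. The conjunction ROIs recover precisely the two planted effects — the
64-voxel cortical module whose integration was reduced in the old group
(`young>old`) and the 8-voxel subcortical hub block whose cross-community
coupling was boosted (`old>young`); the centroids sit at the planted block
centers. The ROI-level MANOVAs confirm both group differences in global
efficiency.

The same analysis is available as a resumable, cached command-line pipeline:

```bash
voxgraph init-config cfg.yaml
voxgraph run --config cfg.yaml --out-dir out --seed 1
```

with stage subcommands `simulate`, `preprocess`, `network`, `metrics`,
`groupmaps`, `stats` and `report` (outputs: NIfTI maps, TSV tables, PNG
figures, and a JSON-lines provenance log).

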