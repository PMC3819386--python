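# Methods

This note documents the models, defaults, and numerical choices behind
`voxgraph`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort model

Each subject's voxel time series follow a Gaussian factor model, white in
time:

```
x_i(t) = Σ_c λ_{i,c} f_c(t) + a_g g(t) + a_m m(t) + σ_i ε_i(t)
```

with unit-variance community factors `f_c`, a global factor `g` shared by
all in-mask voxels, a motion-coupled artifact `m` whose amplitude scales
with the subject's motion covariate, and voxel-specific white noise. Every
voxel has unit total variance; residual variances are solved from the
loadings, and a configuration whose squared loadings exceed 1 raises an
explicit parameterization error (equivalently, the implied covariance
`ΛΛᵀ + shared nuisance + D` would not be PSD; `implied_covariance` exposes
the matrix for audits). A voxel in community *c* with target within-module
correlation ρ loads `√ρ` on `f_c`, so any two same-module voxels correlate
at ρ once the shared nuisance terms are removed. White-in-time factors were
chosen deliberately: temporal filtering then preserves the correlation
structure exactly (an optional AR(1) smoothing stage exists but is off by
default).

### Default layout and planted effects (12×12×12 grid, 1,728 voxels)

| community | size | ρ young | ρ old | role |
|---|---|---|---|---|
| `dmn` | 64 (4³ block) | 0.55 | 0.05 | planted loss of integration in old |
| `fp` | 64 (4³ block) | 0.50 | 0.50 | stable module; hub-boost target |
| `ctx1`–`ctx6` | 6 × 40 | 0.45 | 0.45 | filler modules |
| `sal` | 8 (2³ block, all hubs) | 0.50 | — | hub block; in old, own loading 0.40 plus loading 0.75 on the `fp` factor |

Acquisition defaults mirror the emulated protocol: three runs of
150/220/180 time points at TR = 1.5 s (550 total). Nuisance defaults:
global amplitude 0.25; motion covariate drawn from group-specific
lognormals (medians ≈ 0.10 mm young, 0.18 mm old) and injected with
coupling 0.3·motion. Per-subject standard-normal latents jitter the planted
parameters (ρ jitter 0.03, hub-boost jitter 0.06) and drive the behavior
couplings.

The sizes and coupling strengths were chosen once so that the density-matched
graphs separate into well-spaced degree classes: the top-20% cut at S = 2.5
(≈ 346 of 1,728 voxels) falls inside the filler class, the planted modules
sit far above or below it in the relevant group, and each planted voxel
shows a between-group overlap gap far beyond the 25-point criterion in all
three integration metrics. The old-group module loss is near-complete
(ρ = 0.05) because a binary, density-matched graph is insensitive to
correlation changes that stay above the edge cutoff: a module at ρ = 0.3
keeps all its within-module edges and therefore its degree, core number and
— because shared factors concentrate each module's spurious edges on common
targets, compressing the efficiency range — most of its global efficiency.
Only decoupling that pushes pairs below the cutoff changes the graph.

### Behavior

SWLS totals are built from five 1–7 items (population mean 26.2, SD 5.5);
task-switching and spatial working-memory measures are generated at the
trial level and scored by the same functions users apply to real tables
(`score_swls`, `compute_switch_costs`, `spatial_wm_composite`). The working
memory composite — the instrument names no formula, so the package defines
one — is the average of z-scored accuracy and negated z-scored mean RT,
re-standardized over the cohort (mean 0, SD 1 by construction) and recorded
in the output metadata. Behavior couplings act on the subject *latents*
(e.g., SWLS at r = 0.5 with the hub-boost latent; single-task RT at −0.4
with the module-integration latent). Note a consequence of edge saturation:
at the default effect sizes the latent barely moves the *measured* ROI
metrics, so brain–behavior couplings are recoverable from the latents (and
from the dedicated generate-and-refit simulations) but are not expected to
reach significance through the measured graphs at n = 30 — the pipeline's
dual-threshold rule correctly reports them as not admitted.

## Preprocessing

Fixed order, recorded in provenance: (1) per-run OLS nuisance regression
(intercept, in-mask global mean, six motion parameters, plus any labeled
extras such as WM/CSF/visual-ROI means; collinear columns are dropped with a
warning), (2) ideal FFT-domain band-pass keeping 0.008 < f < 0.08 Hz (the
DC bin always falls outside the band, so means are removed; no other
detrending), (3) per-run, per-node z-scoring and concatenation with run
boundaries kept. Whether regression should precede filtering is a genuinely
open ordering question; it is fixed as above and logged. Gray-matter masks
keep the top 80% of a tissue-prior volume (linear-interpolation percentile;
ties at the threshold included); node order is the x-fastest raster of
in-mask voxels, and masking/unmasking round-trips exactly. A per-voxel
periodogram QC (`voxelwise_psd`) reports band power (defaults 0–0.016 and
0.019–0.03 Hz).

## Network construction

Density is matched by **edge count**, not by iterating a correlation
cutoff: `M = round(N·N^{1/S}/2)` (round half away from zero) guarantees
identical mean degree across subjects exactly, which is the point of the S
threshold; the realized cutoff correlation is reported for audit. Only
strictly positive correlations are edge-eligible (after global-signal
regression, negative edges are conventionally excluded); zero-variance
nodes are flagged, excluded from ranking, and remain as isolated nodes so
maps stay voxel-aligned. Ties at the M-th rank break by ascending (i, j)
index, making edge selection a deterministic function of the matrix and S.
Decreasing S (denser graph) therefore only ever adds edges.

## Nodal metrics

Distances are unit-weight shortest paths computed by BFS (scipy's sparse
Dijkstra with unit weights — identical by contract). The nodal global
efficiency uses the Latora–Marchiori `1/(N−1)` normalization; the local
efficiency averages `1/d` over ordered neighbor pairs with distances
computed *inside* the neighbor subgraph, and nodes with fewer than two
neighbors score 0. Unreachable pairs contribute 0 to both efficiencies —
the reason efficiency is preferred over characteristic path length on
possibly fragmented graphs. Core numbers come from standard k-core peeling
(cascading deletion of nodes below degree k until the graph collapses).
All four metrics are cross-checked in the test suite against independent
brute-force oracles (Floyd–Warshall distances; per-k maximal-subgraph
membership) and against networkx.

## Group topology maps

Top-fraction masks take `round(0.20·N)` nodes (half away from zero —
documented because synthetic N is arbitrary), ties broken by node index;
an all-equal map warns and degenerates to the first indices. Overlap maps
are exact percentages on the `100/n` lattice; display thresholding keeps
values ≥ 50. Difference flags are strict (> 25 points). Conjunction ROIs
require same-direction flags in degree ∧ Eglob ∧ core, are clustered with
26-connectivity, and drop clusters below 2 voxels — the clustering rule and
minimum extent are explicit package choices, since only the ROI *outcome*
is conventionally reported. The 25-point criterion is applied to raw (not
display-thresholded) overlap maps. Seed-connectivity QC maps use the Fisher
z normal approximation `z = atanh(r)·√(T−3)` with |r| capped at 1−1e−7
(cap value reported) and a default display threshold of Z > 2.33; this is a
QC surrogate, not a registered group GLM.

## Inferential statistics

All tests are two-tailed. For two groups Pillai's trace is computed from
the between/within SSCP eigenproblem and converted exactly:
`F = (V/(1−V))·(N−g−p+1)/p` on `(p, N−g−p+1)` df, with partial η² = V. The
repeated-measures group × ROI interaction uses the standard mixed-model
error term, df `((R−1), (R−1)(N−2))`, no sphericity correction (verified
against pingouin for balanced and unbalanced groups). "Step-wise"
regression means hierarchical forced entry in a stated block order
(demographics; mean-centered metric; group × metric interaction), not
automatic selection; groups are contrast-coded ±0.5, all variables are
z-scored so coefficients are standardized βs, and ΔR² per block carries an
F-change test. The dual-threshold rule admits an effect only if p < α at
both S levels with agreeing signs (sign conflicts warn and fail). No
multiple-comparison correction is applied beyond that rule; a
Benjamini–Hochberg helper exists but is off by default. MANOVA, the mixed
ANOVA and the hierarchical regression are implemented directly (numpy/scipy)
so that statsmodels and pingouin can serve as independent cross-checks in
the tests rather than as the implementation.

## Pipeline, seeds, determinism

All randomness flows from the single configuration seed through
`numpy.random.SeedSequence` spawning (one child per subject / simulation
block); no stage touches global RNG state. Disk stages cache on a hash of
their configuration slice chained with the upstream stage hash, so an
unchanged config re-executes nothing and changing only the S list re-runs
the network stage onward. Result tables are written with fixed float
formatting; identical config + seed reproduces byte-identical tables.
Voxel coordinates are 0-based internally; NIfTI affines are preserved on
round trip.

## Problem sizes used by the test suite

Unit tests use graphs of N ≤ 200 and small custom layouts; the end-to-end
plant-and-recover analysis uses the default 12³ grid with 15+15 subjects
and 550 time points at both S levels; calibration uses 500 permutation
replicates per test and effect recovery 200–500 replicates. Full-scale
grids (~30k nodes, K ≈ 60) are supported by the same code paths — all-pairs
BFS is O(N·E) — but are not exercised by the suite.

## Known limitations

- No hemodynamic model, task-evoked block structure, spatial noise
  autocorrelation, or realignment-style motion simulation; the motion
  covariate is a scalar amplitude on a shared artifact regressor.
- Binary density-matched graphs saturate: correlation differences that do
  not cross the edge cutoff are invisible to every downstream metric (see
  the generator section); passing plant-and-recover tests therefore shows
  the pipeline detects *edge-crossing* effects, not arbitrarily small ones.
- The Eloc/Eglob compression induced by shared factors means efficiency
  maps discriminate classes less sharply than degree or core maps — visible
  in real voxel-wise analyses too, where efficiency maps are smoother.
- Statistics assume complete cases and exactly two groups; the
  repeated-measures F for unbalanced groups uses cell-mean weighting
  (matches pingouin), documented as an assumption rather than a derivation.
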