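"""Functional preprocessing: nuisance regression, band-pass filtering,
run normalization/concatenation, gray-matter masking, and PSD-based QC.

The fixed stage order is regression -> band-pass -> per-run normalization ->
concatenation; :func:`preprocess_subject` enforces and records it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram

__all__ = [
    "NuisanceDesign",
    "GrayMatterMask",
    "CleanSeries",
    "regress_nuisance",
    "bandpass",
    "normalize_and_concatenate",
    "apply_mask",
    "unmask",
    "voxelwise_psd",
    "build_nuisance_design",
    "preprocess_subject",
]

DEFAULT_LO_HZ = 0.008
DEFAULT_HI_HZ = 0.08


# --------------------------------------------------------------------------- #
# domain types


@dataclass
class NuisanceDesign:
    """Time x p nuisance regressor matrix with labeled columns.

    Conventional columns: intercept, global (in-mask mean), white-matter and
    CSF means, a visual-cortex ROI mean, and six motion parameters.  Any
    labeled set is accepted; an intercept column is required.
    """

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("design matrix shape does not match labels")
        if "intercept" not in self.labels:
            raise ValueError("nuisance design must include an 'intercept' column")
        norms = np.abs(self.matrix).max(axis=0)
        dead = [
            lab
            for lab, n in zip(self.labels, norms)
            if n == 0 and lab != "intercept"
        ]
        if dead:
            raise ValueError(f"all-zero nuisance column(s): {dead}")

    @property
    def n_time(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GrayMatterMask:
    """Binary 3D mask with a documented voxel <-> node index map.

    Node k corresponds to the k-th in-mask voxel in x-fastest raster order
    (flat index ``x + nx*(y + ny*z)``), so metric maps stay voxel-aligned
    across subjects.
    """

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3D volume")
        if self.n_nodes < 2:
            raise ValueError("mask must contain at least 2 voxels")

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_nodes(self) -> int:
        return int(self.data.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        """Flat (x-fastest) grid indices of mask voxels, in node order."""
        return np.flatnonzero(self.data.ravel(order="F"))

    def coordinates(self) -> np.ndarray:
        """(n_nodes, 3) integer voxel coordinates in node order."""
        nx, ny, _ = self.shape
        flat = self.flat_indices
        x = flat % nx
        y = (flat // nx) % ny
        z = flat // (nx * ny)
        return np.stack([x, y, z], axis=1)

    @classmethod
    def from_tissue_prior(cls, volume: np.ndarray, top_fraction: float = 0.80):
        """Keep the top ``top_fraction`` of intensity values of a tissue prior.

        The cut is the ``100*(1-top_fraction)`` linear-interpolation
        percentile; ties at the threshold are included.
        """
        volume = np.asarray(volume, dtype=float)
        if not 0 < top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        cut = np.percentile(volume, 100 * (1 - top_fraction))
        return cls(volume >= cut)

    @classmethod
    def full(cls, shape):
        return cls(np.ones(shape, dtype=bool))


@dataclass
class CleanSeries:
    """Nuisance-cleaned, filtered, concatenated node x time matrix."""

    data: np.ndarray
    run_boundaries: list[int]  # cumulative end index of each run
    tr: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]


# --------------------------------------------------------------------------- #
# operations


def regress_nuisance(series: np.ndarray, design: NuisanceDesign) -> np.ndarray:
    """OLS-residualize every node series against the nuisance design.

    Collinear design columns are dropped with a warning; if the design is
    still rank-deficient an error lists the offending columns.  Residuals are
    orthogonal to every retained design column.
    """
    series = np.asarray(series, dtype=float)
    x = design.matrix
    if x.shape[0] != series.shape[1]:
        raise ValueError(
            f"design has {x.shape[0]} rows but series has {series.shape[1]} time points"
        )
    keep, dropped = _independent_columns(x)
    if dropped:
        warnings.warn(
            f"dropping collinear nuisance column(s): {[design.labels[i] for i in dropped]}",
            stacklevel=2,
        )
    xk = x[:, keep]
    if np.linalg.matrix_rank(xk) < xk.shape[1]:
        raise ValueError(
            "nuisance design rank-deficient after dropping collinear columns: "
            f"{[design.labels[i] for i in keep]}"
        )
    beta, *_ = np.linalg.lstsq(xk, series.T, rcond=None)
    return series - (xk @ beta).T


def _independent_columns(x: np.ndarray, tol: float = 1e-10):
    """Greedy rank-revealing pass: indices to keep, indices dropped."""
    keep: list[int] = []
    dropped: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(j)
    return keep, dropped


def bandpass(series: np.ndarray, lo_hz: float, hi_hz: float, tr_seconds: float) -> np.ndarray:
    """Ideal FFT-domain band-pass: keep bins with ``lo_hz < f < hi_hz``.

    The DC bin is outside any band with ``lo_hz >= 0``, so constant series
    map to (numerically) zero.  Output is real.
    """
    series = np.asarray(series, dtype=float)
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 <= lo_hz < hi_hz):
        raise ValueError("need 0 <= lo_hz < hi_hz")
    if hi_hz >= nyquist:
        raise ValueError(f"hi_hz={hi_hz} must be below the Nyquist frequency {nyquist}")
    t = series.shape[-1]
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    spec = np.fft.rfft(series, axis=-1)
    spec[..., ~((freqs > lo_hz) & (freqs < hi_hz))] = 0.0
    return np.fft.irfft(spec, n=t, axis=-1)


def normalize_and_concatenate(runs: list[np.ndarray]) -> CleanSeries:
    """Demean and unit-variance-scale each run per node, then concatenate.

    Zero-variance node runs are left as zeros (flagged in provenance).
    """
    if not runs:
        raise ValueError("need at least one run")
    n_nodes = runs[0].shape[0]
    if any(r.shape[0] != n_nodes for r in runs):
        raise ValueError("all runs must share the node count")
    out, boundaries, flagged = [], [], set()
    total = 0
    for run in runs:
        run = np.asarray(run, dtype=float)
        mean = run.mean(axis=1, keepdims=True)
        sd = run.std(axis=1, keepdims=True)
        zero = sd[:, 0] == 0
        flagged.update(np.flatnonzero(zero).tolist())
        sd[zero] = 1.0
        out.append((run - mean) / sd)
        total += run.shape[1]
        boundaries.append(total)
    return CleanSeries(
        data=np.concatenate(out, axis=1),
        run_boundaries=boundaries,
        tr=float("nan"),
        provenance={"zero_variance_nodes": sorted(flagged)},
    )


def apply_mask(volume_series: np.ndarray, mask: GrayMatterMask) -> np.ndarray:
    """Extract the node x time matrix of in-mask voxels from a 4D series.

    Row order follows the mask's x-fastest raster node index;
    :func:`unmask` restores voxel placement exactly.
    """
    volume_series = np.asarray(volume_series)
    if volume_series.ndim != 4 or volume_series.shape[:3] != mask.shape:
        raise ValueError(
            f"volume shape {volume_series.shape} does not match mask {mask.shape}"
        )
    flat = volume_series.reshape(-1, volume_series.shape[3], order="F")
    return flat[mask.flat_indices]


def unmask(series: np.ndarray, mask: GrayMatterMask, fill: float = 0.0) -> np.ndarray:
    """Place node rows (or a node vector) back into the 3D grid."""
    series = np.asarray(series)
    one_d = series.ndim == 1
    if one_d:
        series = series[:, None]
    if series.shape[0] != mask.n_nodes:
        raise ValueError("row count does not match mask voxel count")
    flat = np.full((int(np.prod(mask.shape)), series.shape[1]), fill, dtype=float)
    flat[mask.flat_indices] = series
    vol = flat.reshape(*mask.shape, series.shape[1], order="F")
    return vol[..., 0] if one_d else vol


def voxelwise_psd(
    series: np.ndarray,
    tr_seconds: float,
    bands: list[tuple[float, float]] = ((0.0, 0.016), (0.019, 0.03)),
) -> pd.DataFrame:
    """Per-node mean periodogram power within each requested frequency band.

    Returns a DataFrame with one ``band_<lo>_<hi>`` column per band.  Bands
    must lie within ``(0, Nyquist]``; the default pair targets the low
    frequencies used for spectral QC of the cleaned series.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 8:
        raise ValueError("need at least 8 time points for a PSD")
    nyquist = 1.0 / (2.0 * tr_seconds)
    for lo, hi in bands:
        if not (0 <= lo < hi <= nyquist):
            raise ValueError(f"band ({lo}, {hi}) outside (0, {nyquist}]")
    freqs, power = periodogram(series, fs=1.0 / tr_seconds, axis=-1)
    cols = {}
    for lo, hi in bands:
        sel = (freqs > lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"band ({lo}, {hi}) contains no frequency bins")
        cols[f"band_{lo:g}_{hi:g}"] = power[:, sel].mean(axis=1)
    return pd.DataFrame(cols)


# --------------------------------------------------------------------------- #
# subject-level pipeline


def build_nuisance_design(
    run_series: np.ndarray,
    motion: np.ndarray | None = None,
    extra: dict[str, np.ndarray] | None = None,
) -> NuisanceDesign:
    """Assemble the standard nuisance design for one run.

    Columns: intercept, the global (mean over nodes) signal of the run, six
    motion parameters when provided, plus any extra labeled regressors
    (e.g. white-matter / CSF / visual-cortex ROI means).
    """
    run_series = np.asarray(run_series, dtype=float)
    t = run_series.shape[1]
    cols = [np.ones(t)]
    labels = ["intercept"]
    cols.append(run_series.mean(axis=0))
    labels.append("global")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != t:
            raise ValueError("motion regressors do not match run length")
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            labels.append(f"motion_{j + 1}")
    for name, col in (extra or {}).items():
        cols.append(np.asarray(col, dtype=float))
        labels.append(name)
    return NuisanceDesign(np.column_stack(cols), labels)


def preprocess_subject(
    runs: list[np.ndarray],
    motion_series: list[np.ndarray] | None = None,
    tr_seconds: float = 1.5,
    lo_hz: float = DEFAULT_LO_HZ,
    hi_hz: float = DEFAULT_HI_HZ,
    extra_regressors: list[dict[str, np.ndarray]] | None = None,
) -> CleanSeries:
    """Run the full per-subject chain: regress -> band-pass -> normalize/concat.

    Re-running on identical input reproduces identical output (every step is
    deterministic).  The stage order is recorded in the result's provenance.
    """
    cleaned = []
    for i, run in enumerate(runs):
        motion = motion_series[i] if motion_series is not None else None
        extra = extra_regressors[i] if extra_regressors is not None else None
        design = build_nuisance_design(run, motion, extra)
        resid = regress_nuisance(run, design)
        cleaned.append(bandpass(resid, lo_hz, hi_hz, tr_seconds))
    out = normalize_and_concatenate(cleaned)
    out.tr = tr_seconds
    out.provenance.update(
        {
            "order": ["regress_nuisance", "bandpass", "normalize_and_concatenate"],
            "lo_hz": lo_hz,
            "hi_hz": hi_hz,
            "tr_seconds": tr_seconds,
        }
    )
    return out
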