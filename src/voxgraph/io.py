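"""File formats and provenance: NIfTI volumes, TSV tables, configs, logs.

Voxel coordinates are 0-based internally; the NIfTI affine is respected on
export (identity affine for synthetic grids unless one is supplied).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .preprocess import GrayMatterMask, unmask

__all__ = [
    "read_nifti",
    "write_nifti",
    "write_metric_nifti",
    "read_tsv",
    "write_tsv",
    "config_hash",
    "ProvenanceLog",
]


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI-1 file; returns ``(data, affine)``."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_nifti(path, data: np.ndarray, affine: np.ndarray | None = None, dtype=None):
    """Write a 3D/4D array as NIfTI-1; round-trips data and affine."""
    data = np.asarray(data)
    if dtype is not None:
        data = data.astype(dtype)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_metric_nifti(path, node_values: np.ndarray, mask: GrayMatterMask,
                       affine: np.ndarray | None = None):
    """Project per-node values back into brain space and save as float NIfTI."""
    return write_nifti(path, unmask(np.asarray(node_values, float), mask), affine,
                       dtype=np.float32)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.10g"):
    """Deterministic TSV writer (fixed float formatting, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
    return path


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration fragment."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


class ProvenanceLog:
    """JSON-lines log: one record per pipeline stage execution.

    Every numeric output directory carries a ``.stage.json`` sidecar whose
    hash refers back to the record written here.
    """

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def record(self, stage: str, cfg_hash: str, seed: int | None, **extra):
        entry = {
            "stage": stage,
            "config_hash": cfg_hash,
            "seed": seed,
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            **extra,
        }
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
        return entry
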