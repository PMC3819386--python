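"""Pipeline configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline.

    Defaults mirror the standard analysis: density levels S = 2.5 and 3.0,
    top-20% metric cut, 50% overlap display threshold, 25-point difference
    criterion, 0.008-0.08 Hz band at TR = 1.5 s.
    """

    out_dir: str = "voxgraph_out"
    # cohort
    n_young: int = 15
    n_old: int = 15
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    run_lengths: tuple[int, ...] = (150, 220, 180)
    tr_seconds: float = 1.5
    # preprocessing
    lo_hz: float = 0.008
    hi_hz: float = 0.08
    # network + topology
    s_levels: tuple[float, ...] = (2.5, 3.0)
    top_fraction: float = 0.20
    display_cutoff: float = 50.0
    difference_criterion: float = 25.0
    roi_min_size: int = 2
    # stats
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if any(s <= 1 for s in self.s_levels):
            raise ValueError("S levels must exceed 1")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if not 0 < self.difference_criterion < 100:
            raise ValueError("difference_criterion must be in (0, 100)")
        self.grid_dims = tuple(self.grid_dims)
        self.run_lengths = tuple(self.run_lengths)
        self.s_levels = tuple(float(s) for s in self.s_levels)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def save_config(cfg: PipelineConfig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return path
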