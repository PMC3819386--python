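"""Behavioral scoring: life-satisfaction (SWLS), task-switching costs, spatial
working memory.

The three instruments scored here are the standard ones used in cognitive-aging
cohorts:

* **SWLS** — Satisfaction With Life Scale: five statements rated on a 1-7
  Likert scale, summed to a total between 5 and 35.
* **Task switching** — a speeded judgment task with single-task blocks and a
  mixed (switching) block.  *Local* switch cost is the mean RT difference
  between switch and non-switch trials within the mixed block; *global* cost
  is the mean RT difference between all mixed-block trials and all
  single-block trials.
* **Spatial working memory** — match/non-match probe task at set sizes 1-3;
  summarised by mean RT, mean accuracy, and a standardized speed-accuracy
  composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorRecord",
    "score_swls",
    "compute_switch_costs",
    "spatial_wm_composite",
]

#: trial categories expected by :func:`compute_switch_costs`
SINGLE = "single-block"
SWITCH = "mixed-switch"
NONSWITCH = "mixed-nonswitch"

SWLS_N_ITEMS = 5
SWLS_MIN_RATING = 1
SWLS_MAX_RATING = 7


@dataclass
class BehaviorRecord:
    """Scored behavior for one participant.

    RTs are in milliseconds; accuracy is a proportion in [0, 1]; the working
    memory composite is unitless (cohort-standardized).
    """

    swls_items: tuple[int, ...] | None = None
    swls_total: int | None = None
    single_task_rt: float | None = None
    switch_rt: float | None = None
    nonswitch_rt: float | None = None
    mixed_block_rt: float | None = None
    local_cost: float | None = None
    global_cost: float | None = None
    spwm_rt: float | None = None
    spwm_accuracy: float | None = None
    wm_composite: float | None = None
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "metadata"}
        d["swls_items"] = (
            ",".join(str(i) for i in self.swls_items) if self.swls_items else None
        )
        return d


def score_swls(items) -> int:
    """Sum five 1-7 Likert ratings into an SWLS total in [5, 35].

    Parameters
    ----------
    items : sequence of int
        Exactly five ratings, each an integer between 1 and 7 inclusive.
    """
    items = list(items)
    if len(items) != SWLS_N_ITEMS:
        raise ValueError(f"SWLS requires exactly {SWLS_N_ITEMS} items, got {len(items)}")
    for rating in items:
        if int(rating) != rating or not (SWLS_MIN_RATING <= rating <= SWLS_MAX_RATING):
            raise ValueError(
                f"SWLS rating {rating!r} outside integer range "
                f"[{SWLS_MIN_RATING}, {SWLS_MAX_RATING}]"
            )
    return int(sum(int(r) for r in items))


def compute_switch_costs(trials: pd.DataFrame) -> tuple[float, float]:
    """Local and global switch costs from a labeled trial table.

    Parameters
    ----------
    trials : DataFrame with columns ``condition`` and ``rt_ms``
        ``condition`` must use the labels ``single-block``, ``mixed-switch``
        and ``mixed-nonswitch``; all RTs must be positive.

    Returns
    -------
    (local_cost, global_cost) : tuple of float, milliseconds
        ``local = mean(switch) - mean(nonswitch)``;
        ``global = mean(all mixed trials) - mean(single-block trials)``.
    """
    if not {"condition", "rt_ms"}.issubset(trials.columns):
        raise ValueError("trial table needs 'condition' and 'rt_ms' columns")
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("all RTs must be positive")
    groups = {
        name: trials.loc[trials["condition"] == name, "rt_ms"].to_numpy(float)
        for name in (SINGLE, SWITCH, NONSWITCH)
    }
    for name, values in groups.items():
        if values.size == 0:
            raise ValueError(f"no trials in category {name!r}")
    local = float(groups[SWITCH].mean() - groups[NONSWITCH].mean())
    mixed = np.concatenate([groups[SWITCH], groups[NONSWITCH]])
    global_ = float(mixed.mean() - groups[SINGLE].mean())
    return local, global_


REQUIRED_SET_SIZES = (1, 2, 3)


def spatial_wm_composite(trials: pd.DataFrame, cohort: pd.DataFrame | None = None):
    """Summarise spatial working memory performance across set sizes 1-3.

    Parameters
    ----------
    trials : DataFrame with columns ``set_size``, ``rt_ms``, ``accuracy``
        One row per set size (condition means) or per trial; rows are averaged
        within set size first.
    cohort : DataFrame, optional
        Cohort table with columns ``spwm_rt`` and ``spwm_accuracy`` used to
        standardize the composite.  Without it the subject-level means are
        returned with ``wm_composite=None`` (a single subject cannot be
        z-scored against itself).

    Returns
    -------
    dict with keys ``spwm_rt`` (mean RT, ms), ``spwm_accuracy`` (mean
    proportion), ``wm_composite`` and ``standardization`` metadata.

    Notes
    -----
    The composite is ``z(accuracy) - z(mean RT)`` averaged and re-standardized
    against the cohort, so higher values mean faster *and* more accurate; by
    construction it has mean 0 and SD 1 over the standardization cohort.
    """
    if not {"set_size", "rt_ms", "accuracy"}.issubset(trials.columns):
        raise ValueError("trial table needs 'set_size', 'rt_ms', 'accuracy' columns")
    present = set(trials["set_size"].unique())
    missing = [s for s in REQUIRED_SET_SIZES if s not in present]
    if missing:
        raise ValueError(f"missing set size(s): {missing}")
    per_cond = trials.groupby("set_size")[["rt_ms", "accuracy"]].mean()
    per_cond = per_cond.loc[list(REQUIRED_SET_SIZES)]
    mean_rt = float(per_cond["rt_ms"].mean())
    mean_acc = float(per_cond["accuracy"].mean())
    out = {
        "spwm_rt": mean_rt,
        "spwm_accuracy": mean_acc,
        "wm_composite": None,
        "standardization": "cohort z(acc) - z(RT), averaged, re-standardized",
    }
    if cohort is not None:
        out["wm_composite"] = float(
            wm_composite_scores(
                np.append(cohort["spwm_rt"].to_numpy(float), mean_rt),
                np.append(cohort["spwm_accuracy"].to_numpy(float), mean_acc),
            )[-1]
        )
    return out


def wm_composite_scores(rt: np.ndarray, accuracy: np.ndarray) -> np.ndarray:
    """Cohort-standardized working-memory composite for every subject.

    ``(z(accuracy) - z(rt)) / 2`` re-standardized to mean 0, SD 1 (ddof=0)
    over the cohort.  Degenerate cohorts (zero variance in both inputs)
    return zeros.
    """
    rt = np.asarray(rt, float)
    accuracy = np.asarray(accuracy, float)
    if rt.shape != accuracy.shape or rt.ndim != 1:
        raise ValueError("rt and accuracy must be 1-D arrays of equal length")

    def _z(x):
        sd = x.std()
        return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd

    raw = (_z(accuracy) - _z(rt)) / 2.0
    return _z(raw)
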