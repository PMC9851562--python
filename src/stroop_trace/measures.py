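"""Trial-level kinematic measures.

Four measures per kept trial:

* initiation time (IT): click to first cursor displacement;
* response time (RT): click to response selection (last sample);
* maximum deviation above the direct path (MD): the largest signed orthogonal
  distance from the aligned trajectory to the straight line from (0, 0) to
  (1, 1.5), positive above the line — i.e. toward the incorrect-response side
  after rightward remapping. Computed on the raw-resolution aligned path, so
  a trajectory that never rises above the direct path yields MD <= 0;
* 101-step profiles: the signed deviation d_t and the x coordinate x_t of the
  time-normalized trajectory at each step t (x_t < 0 means the cursor is on
  the incorrect-response side).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .layout import ScreenLayout
from .preprocess import (
    ALIGNED_END,
    ALIGNED_START,
    AlignedTrajectory,
    TimeNormalizedTrajectory,
    remap_and_align,
    time_normalize,
)
from .trial import RawTrial


def signed_deviation(
    points: np.ndarray,
    start: tuple[float, float] = ALIGNED_START,
    end: tuple[float, float] = ALIGNED_END,
) -> np.ndarray:
    """Signed orthogonal distance of point(s) from the start->end line.

    d = (p_x q_y - p_y q_x) / |p| with p = end - start and q = point - start;
    positive values lie left of the start->end direction ("above" the direct
    path, toward the incorrect-response side).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    p = np.asarray(end, dtype=float) - np.asarray(start, dtype=float)
    q = pts - np.asarray(start, dtype=float)
    d = (p[0] * q[:, 1] - p[1] * q[:, 0]) / np.hypot(*p)
    return d if np.asarray(points).ndim > 1 else float(d[0])


def initiation_time(trial: RawTrial, movement_threshold_px: float = 0.0) -> float:
    """Time of the first sample displaced more than the threshold from start.

    With the default threshold of 0 px this is the first positional change.
    If the cursor never moves, the trial duration is returned (callers can
    flag this via :func:`trial_measures`).
    """
    xy = trial.samples.xy
    disp = np.hypot(xy[:, 0] - xy[0, 0], xy[:, 1] - xy[0, 1])
    moved = np.flatnonzero(disp > movement_threshold_px)
    t = trial.samples.time_ms
    if moved.size == 0:
        return float(t[-1] - t[0])
    return float(t[moved[0]] - t[0])


def response_time(trial: RawTrial) -> float:
    """Click-to-selection latency: last sample time minus click time."""
    t = trial.samples.time_ms
    return float(t[-1] - t[0])


def max_deviation_above(traj: AlignedTrajectory) -> float:
    """Maximum signed deviation over all raw-resolution aligned points."""
    return float(np.max(signed_deviation(traj.xy)))


def profiles(tnorm: TimeNormalizedTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """(deviation profile d_t, x-coordinate profile x_t) at each time step."""
    dev = signed_deviation(np.column_stack([tnorm.x, tnorm.y]))
    return dev, tnorm.x.copy()


@dataclass
class TrialMeasures:
    """All kinematic measures of one trial."""

    participant_id: str
    trial_index: int
    condition: str
    it_ms: float
    rt_ms: float
    md_above: float
    dev_profile: np.ndarray
    x_profile: np.ndarray
    no_movement: bool = False


def trial_measures(
    trial: RawTrial,
    layout: ScreenLayout,
    movement_threshold_px: float = 0.0,
    n_time_steps: int = 101,
) -> TrialMeasures:
    aligned = remap_and_align(trial, layout)
    tnorm = time_normalize(aligned, n_time_steps)
    dev, x = profiles(tnorm)
    it = initiation_time(trial, movement_threshold_px)
    rt = response_time(trial)
    return TrialMeasures(
        participant_id=trial.participant_id,
        trial_index=trial.trial_index,
        condition=trial.condition,
        it_ms=it,
        rt_ms=rt,
        md_above=max_deviation_above(aligned),
        dev_profile=dev,
        x_profile=x,
        no_movement=bool(it >= rt),
    )


def measures_table(
    trials: Sequence[RawTrial],
    layout: ScreenLayout,
    movement_threshold_px: float = 0.0,
) -> pd.DataFrame:
    """Per-trial measures as one row per trial."""
    rows = [trial_measures(t, layout, movement_threshold_px) for t in trials]
    return pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in rows],
            "trial_index": [m.trial_index for m in rows],
            "condition": [m.condition for m in rows],
            "it_ms": [m.it_ms for m in rows],
            "rt_ms": [m.rt_ms for m in rows],
            "md_above": [m.md_above for m in rows],
            "no_movement": [m.no_movement for m in rows],
        }
    )


def profiles_table(
    trials: Sequence[RawTrial],
    layout: ScreenLayout,
    n_time_steps: int = 101,
) -> pd.DataFrame:
    """Long-format profile table: one row per trial per time step.

    Columns: participant_id, trial_index, condition, step (1-based),
    deviation, x_coordinate.
    """
    n = len(trials)
    dev = np.empty((n, n_time_steps))
    xs = np.empty((n, n_time_steps))
    for i, t in enumerate(trials):
        tn = time_normalize(remap_and_align(t, layout), n_time_steps)
        dev[i], xs[i] = profiles(tn)
    steps = np.tile(np.arange(1, n_time_steps + 1), n)
    return pd.DataFrame(
        {
            "participant_id": np.repeat([t.participant_id for t in trials], n_time_steps),
            "trial_index": np.repeat([t.trial_index for t in trials], n_time_steps),
            "condition": np.repeat([t.condition for t in trials], n_time_steps),
            "step": steps,
            "deviation": dev.ravel(),
            "x_coordinate": xs.ravel(),
        }
    )
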