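"""Trial exclusion, rightward remapping, endpoint anchoring, and normalization.

Exclusion follows the study's rules: omissions and incorrect responses are
removed first; then, within each participant x condition cell, correct trials
whose RT falls outside the cell mean +/- 3 SD are removed (cells with fewer
than two trials are left untouched and logged).

Alignment maps every correct trial into a common task space: if the correct
box lies left of the start box the x coordinates are mirrored about the start
x (rightward remapping), then an affine map (translation plus independent,
possibly sign-flipping, x and y scalings) sends the first sample exactly to
(0, 0) and the last exactly to (1, 1.5). Because the y scale factor carries
the sign of the movement direction, screen-pixel input (y down) comes out
with y increasing toward the response boxes without any separate flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError
from .layout import ScreenLayout
from .trial import RawTrial

#: Anchored endpoints of every aligned trajectory.
ALIGNED_START = (0.0, 0.0)
ALIGNED_END = (1.0, 1.5)

RT_SD_CRITERION = 3.0


@dataclass
class ExclusionReport:
    """Counts and percentages removed by each exclusion rule."""

    n_total: int
    n_omission: int
    n_error: int
    n_rt_outlier: int
    skipped_cells: list[tuple[str, str]] = field(default_factory=list)
    per_participant: pd.DataFrame | None = None

    @property
    def n_kept(self) -> int:
        return self.n_total - self.n_omission - self.n_error - self.n_rt_outlier

    def percentages(self) -> dict[str, float]:
        tot = max(self.n_total, 1)
        return {
            "omission": 100.0 * self.n_omission / tot,
            "error": 100.0 * self.n_error / tot,
            "rt_outlier": 100.0 * self.n_rt_outlier / tot,
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        return pd.DataFrame(
            {
                "rule": ["omission", "error", "rt_outlier"],
                "n_removed": [self.n_omission, self.n_error, self.n_rt_outlier],
                "pct_of_total": [pct["omission"], pct["error"], pct["rt_outlier"]],
            }
        )


def filter_trials(trials: Sequence[RawTrial]) -> tuple[list[RawTrial], ExclusionReport]:
    """Apply the exclusion rules; returns kept trials and a report."""
    n_total = len(trials)
    n_omission = sum(t.status == "timeout" for t in trials)
    n_error = sum(t.status == "error" for t in trials)
    correct = [t for t in trials if t.status == "correct"]
    for t in correct:
        if t.rt_ms is None:
            raise DataError(f"trial {t.key}: correct trial without rt_ms")

    skipped: list[tuple[str, str]] = []
    removed_rows: dict[tuple[str, int], bool] = {}
    cells: dict[tuple[str, str], list[RawTrial]] = {}
    for t in correct:
        cells.setdefault((t.participant_id, t.condition), []).append(t)
    for (pid, condition), cell in cells.items():
        if len(cell) < 2:
            skipped.append((pid, condition))
            continue
        rts = np.array([t.rt_ms for t in cell])
        sd = rts.std(ddof=1)
        if sd == 0:
            continue
        mean = rts.mean()
        out = np.abs(rts - mean) > RT_SD_CRITERION * sd
        for t, flag in zip(cell, out):
            if flag:
                removed_rows[t.key] = True

    kept = [t for t in correct if t.key not in removed_rows]
    per_part = (
        pd.DataFrame(
            {
                "participant_id": [t.participant_id for t in trials],
                "rule": [
                    "omission"
                    if t.status == "timeout"
                    else "error"
                    if t.status == "error"
                    else ("rt_outlier" if t.key in removed_rows else "kept")
                    for t in trials
                ],
            }
        )
        .groupby(["participant_id", "rule"])
        .size()
        .unstack(fill_value=0)
        .reset_index()
    )
    report = ExclusionReport(
        n_total=n_total,
        n_omission=n_omission,
        n_error=n_error,
        n_rt_outlier=len(removed_rows),
        skipped_cells=skipped,
        per_participant=per_part,
    )
    return kept, report


@dataclass
class AlignedTrajectory:
    """Remapped, endpoint-anchored trajectory in normalized task units."""

    x: np.ndarray
    y: np.ndarray
    time_ms: np.ndarray
    remap_applied: bool

    def __len__(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def remap_and_align(trial: RawTrial, layout: ScreenLayout) -> AlignedTrajectory:
    """Mirror leftward trials rightward, then anchor endpoints to (0,0)/(1,1.5)."""
    if trial.status != "correct":
        raise DataError(f"trial {trial.key}: only correct trials are aligned")
    x = trial.samples.x_px.astype(float).copy()
    y = trial.samples.y_px.astype(float).copy()
    start_x = layout.start_center[0]
    box_x = layout.response_centers[trial.correct_box][0]
    remap = box_x < start_x
    if remap:
        x = 2.0 * start_x - x
    dx = x[-1] - x[0]
    dy = y[-1] - y[0]
    if dx == 0.0 or dy == 0.0:
        raise AlignmentError(
            f"trial {trial.key}: degenerate path (no net displacement on an axis)"
        )
    ax = (x - x[0]) * (ALIGNED_END[0] / dx)
    ay = (y - y[0]) * (ALIGNED_END[1] / dy)
    return AlignedTrajectory(
        x=ax, y=ay, time_ms=trial.samples.time_ms.astype(float).copy(), remap_applied=bool(remap)
    )


@dataclass
class TimeNormalizedTrajectory:
    """Exactly ``n_steps`` points at equally spaced times over the full trial.

    Step s (1-based) corresponds to approximately (s-1)% of the total response
    duration, which includes the pre-initiation dwell.
    """

    x: np.ndarray
    y: np.ndarray
    total_duration_ms: float

    def __len__(self) -> int:
        return len(self.x)

    @property
    def steps(self) -> np.ndarray:
        return np.arange(1, len(self.x) + 1)


def time_normalize(traj: AlignedTrajectory, n_steps: int = 101) -> TimeNormalizedTrajectory:
    """Linear interpolation of (x, y) at ``n_steps`` equally spaced times."""
    t = traj.time_ms
    if len(t) < 2 or t[-1] <= t[0]:
        raise DataError("time_normalize: zero total duration")
    grid = np.linspace(t[0], t[-1], n_steps)
    return TimeNormalizedTrajectory(
        x=np.interp(grid, t, traj.x),
        y=np.interp(grid, t, traj.y),
        total_duration_ms=float(t[-1] - t[0]),
    )


@dataclass
class SpaceNormalizedTrajectory:
    """Exactly ``n_points`` points evenly spaced along the path's arc length."""

    x: np.ndarray
    y: np.ndarray
    arc_length: float

    def __len__(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def space_normalize(traj: AlignedTrajectory, n_points: int = 100) -> SpaceNormalizedTrajectory:
    """Resample the polyline at equal arc-length increments.

    Repeated (dwell) samples contribute zero-length segments and do not
    change the result.
    """
    seg = np.hypot(np.diff(traj.x), np.diff(traj.y))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0.0:
        raise DataError("space_normalize: zero arc length")
    # collapse duplicate arc positions so interpolation is well defined
    keep = np.concatenate([[True], np.diff(arc) > 0])
    arc_u, x_u, y_u = arc[keep], traj.x[keep], traj.y[keep]
    grid = np.linspace(0.0, total, n_points)
    return SpaceNormalizedTrajectory(
        x=np.interp(grid, arc_u, x_u),
        y=np.interp(grid, arc_u, y_u),
        arc_length=float(total),
    )


def preprocess_trials(
    trials: Sequence[RawTrial],
    layout: ScreenLayout,
    n_time_steps: int = 101,
    n_space_points: int = 100,
) -> tuple[list[RawTrial], ExclusionReport, dict[tuple[str, int], AlignedTrajectory],
           dict[tuple[str, int], TimeNormalizedTrajectory],
           dict[tuple[str, int], SpaceNormalizedTrajectory]]:
    """Filter then align and normalize every kept trial (convenience wrapper)."""
    kept, report = filter_trials(trials)
    aligned = {t.key: remap_and_align(t, layout) for t in kept}
    tnorm = {k: time_normalize(a, n_time_steps) for k, a in aligned.items()}
    snorm = {k: space_normalize(a, n_space_points) for k, a in aligned.items()}
    return kept, report, aligned, tnorm, snorm
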