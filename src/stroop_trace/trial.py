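"""Trial-level containers shared by the generator and the preprocessing stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

STATUSES = ("correct", "error", "timeout")


@dataclass
class TrajectorySamples:
    """Cursor samples of one trial, time-ordered from the start-box click."""

    time_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if not (len(self.time_ms) == len(self.x_px) == len(self.y_px)):
            raise DataError("samples: time/x/y lengths differ")
        if np.any(np.diff(self.time_ms) < 0):
            raise DataError("samples: time_ms must be nondecreasing")

    def __len__(self) -> int:
        return len(self.time_ms)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_px, self.y_px])


@dataclass
class RawTrial:
    """One trial's metadata plus its cursor samples."""

    participant_id: str
    trial_index: int
    condition: str
    word: str
    ink: str
    correct_box: str
    chosen_box: str | None
    status: str
    rt_ms: float | None
    it_ms: float | None
    samples: TrajectorySamples
    #: Generator annotation: True when the trial was drawn from the
    #: partial-error regime. None for trials read from real recordings.
    pe_regime: bool | None = field(default=None)

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise DataError(
                f"trial {self.key}: status {self.status!r} not in {STATUSES}"
            )
        if (self.status == "timeout") != (self.chosen_box is None):
            raise DataError(
                f"trial {self.key}: chosen_box must be absent iff status is timeout"
            )
        if self.status == "correct" and self.chosen_box != self.correct_box:
            raise DataError(
                f"trial {self.key}: status 'correct' requires chosen_box == correct_box"
            )
        if self.status == "error" and self.chosen_box == self.correct_box:
            raise DataError(
                f"trial {self.key}: status 'error' requires chosen_box != correct_box"
            )
        if self.status != "timeout" and len(self.samples) < 2:
            raise DataError(f"trial {self.key}: completed trials need >= 2 samples")

    @property
    def key(self) -> tuple[str, int]:
        return (self.participant_id, self.trial_index)
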