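"""CSV input/output for trial tables.

Two plain CSV files describe a dataset:

* metadata: one row per trial with columns ``participant_id, trial_index,
  condition, word, ink, correct_box, chosen_box, status, rt_ms, it_ms``
  (plus an optional ``pe_regime`` column written by the simulator);
* samples: long format with columns ``participant_id, trial_index, time_ms,
  x_px, y_px`` at the recording rate, ordered by time within each trial.

Coordinates are screen pixels (y increases downward); times are milliseconds
from the start-box click.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .trial import RawTrial, TrajectorySamples

METADATA_COLUMNS = (
    "participant_id",
    "trial_index",
    "condition",
    "word",
    "ink",
    "correct_box",
    "chosen_box",
    "status",
    "rt_ms",
    "it_ms",
)
SAMPLE_COLUMNS = ("participant_id", "trial_index", "time_ms", "x_px", "y_px")


def trials_to_frames(trials: Sequence[RawTrial]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten trials into (metadata, samples) DataFrames."""
    meta = pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trials],
            "trial_index": [t.trial_index for t in trials],
            "condition": [t.condition for t in trials],
            "word": [t.word for t in trials],
            "ink": [t.ink for t in trials],
            "correct_box": [t.correct_box for t in trials],
            "chosen_box": [t.chosen_box if t.chosen_box is not None else "" for t in trials],
            "status": [t.status for t in trials],
            "rt_ms": [t.rt_ms if t.rt_ms is not None else np.nan for t in trials],
            "it_ms": [t.it_ms if t.it_ms is not None else np.nan for t in trials],
            "pe_regime": [t.pe_regime for t in trials],
        }
    )
    if meta["pe_regime"].isna().all():
        meta = meta.drop(columns=["pe_regime"])
    lengths = np.array([len(t.samples) for t in trials])
    samples = pd.DataFrame(
        {
            "participant_id": np.repeat(meta["participant_id"].to_numpy(), lengths),
            "trial_index": np.repeat(meta["trial_index"].to_numpy(), lengths),
            "time_ms": np.concatenate([t.samples.time_ms for t in trials]),
            "x_px": np.concatenate([t.samples.x_px for t in trials]),
            "y_px": np.concatenate([t.samples.y_px for t in trials]),
        }
    )
    return meta, samples


def write_trials(
    trials: Sequence[RawTrial],
    metadata_path: str | Path,
    samples_path: str | Path,
    float_format: str | None = None,
) -> None:
    """Write trials to the two-file CSV format.

    The default float formatting is the shortest round-tripping repr, so
    ``read_trials(write_trials(x))`` reproduces ``x`` exactly and output is
    byte-deterministic.
    """
    meta, samples = trials_to_frames(trials)
    meta.to_csv(metadata_path, index=False, float_format=float_format)
    samples.to_csv(samples_path, index=False, float_format=float_format)


def read_trials(metadata_path: str | Path, samples_path: str | Path) -> list[RawTrial]:
    """Read trials, joining each trial's samples in time order.

    Raises FormatError when a required column is missing, and DataError when
    samples reference unknown trials or a trial's times are non-monotone.
    """
    meta = pd.read_csv(metadata_path, dtype={"participant_id": str})
    samples = pd.read_csv(samples_path, dtype={"participant_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{metadata_path}: missing metadata columns {missing}")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"{samples_path}: missing sample columns {missing}")

    known = set(zip(meta["participant_id"], meta["trial_index"]))
    sample_keys = set(zip(samples["participant_id"], samples["trial_index"]))
    orphans = sorted(sample_keys - known)
    if orphans:
        raise DataError(f"{samples_path}: samples reference unknown trials {orphans[:10]}")

    grouped = {
        key: g for key, g in samples.groupby(["participant_id", "trial_index"], sort=False)
    }
    has_pe = "pe_regime" in meta.columns
    trials: list[RawTrial] = []
    for row in meta.itertuples(index=False):
        key = (row.participant_id, row.trial_index)
        g = grouped.get(key)
        if g is None:
            raise DataError(f"{metadata_path}: trial {key} has no samples")
        t = g["time_ms"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise DataError(f"{samples_path}: non-monotone time in trial {key}")
        chosen = row.chosen_box
        if chosen is None or (isinstance(chosen, float) and np.isnan(chosen)) or chosen == "":
            chosen = None
        pe = getattr(row, "pe_regime", None) if has_pe else None
        if pe is not None and not isinstance(pe, (bool, np.bool_)):
            pe = bool(pe) if not (isinstance(pe, float) and np.isnan(pe)) else None
        trials.append(
            RawTrial(
                participant_id=str(row.participant_id),
                trial_index=int(row.trial_index),
                condition=str(row.condition),
                word=str(row.word),
                ink=str(row.ink),
                correct_box=str(row.correct_box),
                chosen_box=chosen,
                status=str(row.status),
                rt_ms=None if np.isnan(row.rt_ms) else float(row.rt_ms),
                it_ms=None if np.isnan(row.it_ms) else float(row.it_ms),
                pe_regime=None if pe is None else bool(pe),
                samples=TrajectorySamples(
                    time_ms=t,
                    x_px=g["x_px"].to_numpy(dtype=float),
                    y_px=g["y_px"].to_numpy(dtype=float),
                ),
            )
        )
    return trials


def trial_keys(trials: Iterable[RawTrial]) -> list[tuple[str, int]]:
    return [t.key for t in trials]
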