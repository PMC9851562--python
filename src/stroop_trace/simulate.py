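"""Synthetic cursor-trajectory generator with known ground-truth effects.

The generator emulates the study design — six stimulus-type conditions, 32
trials each, ~80 participants, paired mirrored response boxes, a 500 ms
initiation deadline and a 2500 ms response deadline — with a two-attractor
co-activation model. On every trial the cursor moves toward a blended target

    T(s) = w(s) * incorrect_box + (1 - w(s)) * correct_box,

where s in [0, 1] is the fraction of movement time elapsed and w(s) is the
weight of the incorrect response: w holds at its initial value w0 until a
per-trial onset fraction, then decays geometrically toward ~0 so the movement
terminates at the correct box. Ordinary trials draw w0 near the condition's
``pull_amplitude`` (w0 < 0.5: the early movement launches up-centre and the
path bows toward the incorrect side without crossing it). With probability
``pull_prob`` a trial enters the partial-error regime: w0 = 1, so the cursor
genuinely heads for the incorrect box before a late correction — these
regime labels are the ground truth for validating the clustering detector.

Response time is realized near ``rt_base + rt_offsets[condition]`` with a
multiplicative (log-normal) participant effect and trial noise, both
mean-corrected so the expected RT equals the configured value exactly; the
configured offsets are therefore the ground-truth condition effects that the
mixed-model stage must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import conditions as cond
from .errors import ConfigError
from .layout import ScreenLayout, default_layout
from .trial import RawTrial, TrajectorySamples

# French stimulus words, organised by the response colour they evoke.
COLOUR_WORDS = {"red": "rouge", "green": "vert", "blue": "bleu", "yellow": "jaune"}
ASSOCIATED_WORDS = {"red": "tomate", "green": "salade", "blue": "ciel", "yellow": "mais"}
NEUTRAL_WORDS = {("red", "green"): ("balcon", "chien"), ("blue", "yellow"): ("pont", "cargo")}
NONRESPONSE_WORDS = {("red", "green"): ("violet", "gris"), ("blue", "yellow"): ("marron", "orange")}

# Mechanics of the co-activation weight w(s).
_W_END_ORDINARY = 0.03   # terminal weight, ordinary trials (geometric decay target)
_W_END_PARTIAL = 0.015   # terminal weight, partial-error regime (late hard correction)
_ONSET_LO, _ONSET_HI = 0.25, 0.60  # uniform range of the decay-onset fraction
_NOISE_SMOOTH = 9        # samples; motor noise is smoothed, not white
_IT_CLIP = (60.0, 450.0)  # ms; initiation times stay under the 500 ms deadline


def _table_calibrated(values: Sequence[float]) -> dict[str, float]:
    return dict(zip(cond.CONDITIONS, [float(v) for v in values]))


@dataclass
class SimulationConfig:
    """Study-design parameters; defaults reproduce the published conditions.

    ``rt_offsets`` are the ground-truth additive RT effects (ms) relative to
    ``rt_base`` (the colour-neutral mean); ``pull_prob`` the per-condition
    probability of a partial-error-regime trial; ``pull_amplitude`` the
    ordinary-trial co-activation weight, calibrated so mean maximum deviations
    approximate the reported per-condition values.
    """

    n_participants: int = 80
    n_trials_per_condition: int = 32
    sample_rate: float = 100.0  # Hz
    rt_base: float = 1070.0  # ms, colour-neutral mean RT
    rt_offsets: dict[str, float] = field(
        default_factory=lambda: _table_calibrated([119.0, 41.0, 5.0, 0.0, -25.0, -41.0])
    )
    pull_amplitude: dict[str, float] = field(
        default_factory=lambda: _table_calibrated([0.55, 0.47, 0.48, 0.44, 0.41, 0.38])
    )
    pull_prob: dict[str, float] = field(
        default_factory=lambda: _table_calibrated([0.367, 0.261, 0.286, 0.249, 0.240, 0.223])
    )
    it_mean: float = 168.0  # ms
    it_sd: float = 40.0  # ms
    rt_trial_sd: float = 180.0  # ms, within-participant trial scatter
    participant_sd_rt: float = 60.0  # ms, between-participant RT scale (log-normal)
    participant_sd_pull: float = 0.06  # between-participant shift of w0
    pull_trial_sd: float = 0.05  # trial-to-trial jitter of w0 on ordinary trials
    noise_sd: float = 12.0  # px, positional motor noise
    timeout: float = 2500.0  # ms, response deadline
    initiation_deadline: float = 500.0  # ms (feedback only; no trial is dropped)
    error_prob: float = 0.0058
    omission_prob: float = 0.0034
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_participants < 1:
            raise ConfigError("n_participants: must be >= 1")
        if self.n_trials_per_condition < 1:
            raise ConfigError("n_trials_per_condition: must be >= 1")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate: must be > 0")
        for name in ("error_prob", "omission_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}: probability must be in [0, 1]")
        for name in ("pull_prob", "pull_amplitude"):
            mapping = getattr(self, name)
            missing = [c for c in cond.CONDITIONS if c not in mapping]
            if missing:
                raise ConfigError(f"{name}: missing conditions {missing}")
            for c, v in mapping.items():
                cond.validate_condition(c)
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{name}[{c}]: must be in [0, 1]")
        missing = [c for c in cond.CONDITIONS if c not in self.rt_offsets]
        if missing:
            raise ConfigError(f"rt_offsets: missing conditions {missing}")
        if self.rt_base + min(self.rt_offsets.values()) <= 0:
            raise ConfigError("rt_base: rt_base + min(rt_offsets) must be > 0")
        for name in (
            "it_mean", "it_sd", "rt_trial_sd", "participant_sd_rt",
            "participant_sd_pull", "pull_trial_sd", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if self.timeout <= self.it_mean:
            raise ConfigError("timeout: must exceed it_mean")
        if self.initiation_deadline <= 0:
            raise ConfigError("initiation_deadline: must be > 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed: must be an integer")
        return self

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config fields: {sorted(unknown)}")
        return cls(**d)


def ground_truth_components(config: SimulationConfig) -> dict[str, float]:
    """The eight RT component values (ms) implied by the configured offsets."""
    config.validate()
    return cond.component_values(config.rt_offsets)


def _choose_words(rng, labels, inks, partners, pair_key):
    """Stimulus word per trial, following the condition's pairing rule."""
    words = np.empty(len(labels), dtype=object)
    for i, (lab, ink, partner) in enumerate(zip(labels, inks, partners)):
        key = pair_key[ink]
        if lab == cond.STANDARD_INCONGRUENT:
            words[i] = COLOUR_WORDS[partner]
        elif lab == cond.STANDARD_CONGRUENT:
            words[i] = COLOUR_WORDS[ink]
        elif lab == cond.ASSOCIATED_INCONGRUENT:
            words[i] = ASSOCIATED_WORDS[partner]
        elif lab == cond.ASSOCIATED_CONGRUENT:
            words[i] = ASSOCIATED_WORDS[ink]
        elif lab == cond.NONRESPONSE_SET:
            pool = NONRESPONSE_WORDS[key]
            words[i] = pool[rng.integers(len(pool))]
        else:
            pool = NEUTRAL_WORDS[key]
            words[i] = pool[rng.integers(len(pool))]
    return words


def simulate_dataset(
    config: SimulationConfig, layout: ScreenLayout | None = None
) -> list[RawTrial]:
    """Generate one full dataset of raw trials.

    Returns ``n_participants * 6 * n_trials_per_condition`` trials. Identical
    configurations (including the seed) produce byte-identical output.
    """
    config.validate()
    layout = layout or default_layout()
    rng = np.random.default_rng(config.seed)

    n_cond = len(cond.CONDITIONS)
    per_part = n_cond * config.n_trials_per_condition
    n = config.n_participants * per_part
    dt = 1000.0 / config.sample_rate

    part_idx = np.repeat(np.arange(config.n_participants), per_part)
    cond_idx = np.tile(np.repeat(np.arange(n_cond), config.n_trials_per_condition),
                       config.n_participants)
    # intermix conditions within each participant's block
    for p in range(config.n_participants):
        sl = slice(p * per_part, (p + 1) * per_part)
        cond_idx[sl] = rng.permutation(cond_idx[sl])
    labels = np.array(cond.CONDITIONS, dtype=object)[cond_idx]

    # participant effects
    sd_log = config.participant_sd_rt / config.rt_base
    b_rt = rng.normal(-0.5 * sd_log**2, sd_log, config.n_participants)
    b_pull = rng.normal(0.0, config.participant_sd_pull, config.n_participants)

    # stimulus identity
    colours = list(layout.response_centers)
    pair_key = {}
    for a, b in layout.pairs:
        key = (a, b) if (a, b) in NEUTRAL_WORDS else (b, a)
        pair_key[a] = pair_key[b] = key
    inks = np.array(colours, dtype=object)[rng.integers(0, len(colours), n)]
    partners = np.array([layout.pair_partner(c) for c in inks], dtype=object)
    words = _choose_words(rng, labels, inks, partners, pair_key)

    # chronometry
    offsets = np.array([config.rt_offsets[c] for c in cond.CONDITIONS])[cond_idx]
    it = np.clip(rng.normal(config.it_mean, config.it_sd, n), *_IT_CLIP)
    mu = config.rt_base + offsets
    sd_trial = config.rt_trial_sd / mu
    rt = mu * np.exp(b_rt[part_idx]) * np.exp(
        rng.normal(-0.5 * sd_trial**2, sd_trial, n)
    )
    rt = np.clip(rt, it + 15 * dt, config.timeout - 2 * dt)
    rt = np.round(rt / dt) * dt  # responses are observed on the sample grid

    # trial outcome regimes (independent draws, applied in order)
    is_error = rng.random(n) < config.error_prob
    is_timeout = (~is_error) & (rng.random(n) < config.omission_prob)
    pull_p = np.array([config.pull_prob[c] for c in cond.CONDITIONS])[cond_idx]
    is_pe = (~is_error) & (~is_timeout) & (rng.random(n) < pull_p)

    # co-activation weight parameters
    amp = np.array([config.pull_amplitude[c] for c in cond.CONDITIONS])[cond_idx]
    w0 = np.clip(amp + b_pull[part_idx] + rng.normal(0, config.pull_trial_sd, n), 0.0, 0.99)
    w0[is_pe] = 1.0
    w0[is_error] = 1.0
    s_onset = rng.uniform(_ONSET_LO, _ONSET_HI, n)
    s_onset[is_error] = 1.0  # never corrected: the movement completes at the wrong box
    w_end = np.where(is_pe, _W_END_PARTIAL, _W_END_ORDINARY)

    # padded sample grid
    dur = np.where(is_timeout, config.timeout, rt)
    n_steps = np.round(dur / dt).astype(int)
    max_len = int(n_steps.max()) + 1
    t = np.arange(max_len) * dt  # (L,)
    valid = t[None, :] <= dur[:, None] + 1e-9

    with np.errstate(divide="ignore", invalid="ignore"):
        s = (t[None, :] - it[:, None]) / (dur - it)[:, None]
    s = np.clip(s, 0.0, 1.0)

    decay_span = np.maximum(1.0 - s_onset, 1e-9)
    rate = np.where(
        s_onset >= 1.0 - 1e-9,
        0.0,
        np.log(np.maximum(w0, w_end + 1e-9) / w_end) / decay_span,
    )
    w = w0[:, None] * np.exp(-rate[:, None] * np.clip(s - s_onset[:, None], 0.0, None))

    start = np.asarray(layout.start_center)
    centers = {c: np.asarray(layout.response_centers[c]) for c in colours}
    c_box = np.stack([centers[c] for c in inks])     # (n, 2)
    i_box = np.stack([centers[c] for c in partners])  # (n, 2)

    # pos = start + s*(C - start) + s*w*(I - C), axis by axis to limit temporaries
    pos = np.empty((n, max_len, 2))
    sw = s * w
    for axis in range(2):
        np.multiply(s, (c_box[:, axis] - start[axis])[:, None], out=pos[:, :, axis])
        pos[:, :, axis] += sw * (i_box[:, axis] - c_box[:, axis])[:, None]
        pos[:, :, axis] += start[axis]
    # omission trials: a slow drift toward the correct box that never arrives
    if is_timeout.any():
        drift = 0.08 * s[is_timeout][..., None] * (c_box[is_timeout, None, :] - start)
        pos[is_timeout] = start[None, None, :] + drift

    if config.noise_sd > 0:
        noise = rng.standard_normal((n, max_len, 2))
        noise = uniform_filter1d(noise, size=_NOISE_SMOOTH, axis=1, mode="nearest")
        ramp = np.clip((t[None, :] - it[:, None]) / 80.0, 0.0, 1.0)
        ramp *= config.noise_sd * np.sqrt(_NOISE_SMOOTH)
        for axis in range(2):
            noise[:, :, axis] *= ramp
        pos += noise

    # outcomes from the realized endpoint
    last = n_steps  # index of the final sample per trial
    end_pos = pos[np.arange(n), last, :]
    box_centers = np.stack([centers[c] for c in colours])  # (4, 2)
    d_end = np.linalg.norm(end_pos[:, None, :] - box_centers[None, :, :], axis=2)
    chosen = np.array(colours, dtype=object)[np.argmin(d_end, axis=1)]

    trials: list[RawTrial] = []
    width = len(str(config.n_participants))
    pids = [f"P{p + 1:0{width}d}" for p in range(config.n_participants)]
    for i in range(n):
        k = last[i] + 1
        if is_timeout[i]:
            status, chosen_box, rt_ms = "timeout", None, None
        else:
            chosen_box = str(chosen[i])
            status = "correct" if chosen_box == inks[i] else "error"
            rt_ms = float(dur[i])
        trials.append(
            RawTrial(
                participant_id=pids[part_idx[i]],
                trial_index=int(i % per_part),
                condition=str(labels[i]),
                word=str(words[i]),
                ink=str(inks[i]),
                correct_box=str(inks[i]),
                chosen_box=chosen_box,
                status=status,
                rt_ms=rt_ms,
                it_ms=float(it[i]),
                pe_regime=bool(is_pe[i]),
                # views into the padded batch arrays (treated as read-only)
                samples=TrajectorySamples(
                    time_ms=t[:k],
                    x_px=pos[i, :k, 0],
                    y_px=pos[i, :k, 1],
                ),
            )
        )
    return trials
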