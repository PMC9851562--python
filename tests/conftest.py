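import pytest

from stroop_trace.conditions import CONDITIONS
from stroop_trace.layout import default_layout
from stroop_trace.preprocess import filter_trials
from stroop_trace.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def layout():
    return default_layout()


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A quick study: 8 participants x 8 trials per condition."""
    kwargs = dict(n_participants=8, n_trials_per_condition=8, seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def null_config(seed: int = 0, n_participants: int = 20, n_trials: int = 8) -> SimulationConfig:
    """All condition effects removed: shared offsets, pull and PE probability."""
    return SimulationConfig(
        n_participants=n_participants,
        n_trials_per_condition=n_trials,
        rt_offsets={c: 0.0 for c in CONDITIONS},
        pull_amplitude={c: 0.44 for c in CONDITIONS},
        pull_prob={c: 0.25 for c in CONDITIONS},
        seed=seed,
    )


def clean_config(seed: int = 7, **overrides) -> SimulationConfig:
    """Deterministic kinematics: no pull, no noise, no errors or omissions."""
    kwargs = dict(
        n_participants=3,
        n_trials_per_condition=4,
        pull_amplitude={c: 0.0 for c in CONDITIONS},
        pull_prob={c: 0.0 for c in CONDITIONS},
        participant_sd_pull=0.0,
        pull_trial_sd=0.0,
        noise_sd=0.0,
        error_prob=0.0,
        omission_prob=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_trials():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def kept_small(small_trials):
    kept, _ = filter_trials(small_trials)
    return kept
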