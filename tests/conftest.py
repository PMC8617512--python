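import numpy as np
import pytest

from reachkin import armsim
from reachkin.armsim import SimConfig, SubjectProfile


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Noise-free, jitter-free settings for exact round-trip checks."""
    return SimConfig(noise_sd=0.0, gap_rate=0.0, trial_jitter_sd=0.0,
                     between_subject_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def ctrl_profile() -> SubjectProfile:
    return SubjectProfile("S001", "CTRL")


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 subjects per group, 3 trials per movement, light noise — small
    enough for end-to-end tests."""
    config = SimConfig(n_per_group=2, noise_sd=0.2, gap_rate=0.0,
                       trial_jitter_sd=0.03, between_subject_sd=0.03, seed=11)
    return config, armsim.generate_cohort(config, trials_per_movement=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
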