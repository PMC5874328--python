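import numpy as np
import pytest

from imu2grf import NoiseScales, make_subject, preprocess_trial, simulate_trial
from imu2grf.models import TrainConfig


@pytest.fixture(scope="session")
def subject():
    """Midfoot-striking reference subject."""
    return make_subject(3)


@pytest.fixture(scope="session")
def rearfoot_subject():
    return make_subject(1)


@pytest.fixture(scope="session")
def raw_trial(subject):
    """30 s trial at 12 km/h, default noise."""
    return simulate_trial(subject, 12.0, 30.0, seed=3)


@pytest.fixture(scope="session")
def synced_trial(raw_trial):
    return preprocess_trial(raw_trial)


@pytest.fixture(scope="session")
def noise_free_trial():
    s = make_subject(3, overrides={"noise_scales": NoiseScales(0.0, 0.0, 0.0)})
    return preprocess_trial(simulate_trial(s, 12.0, 30.0, seed=3))


@pytest.fixture
def small_config():
    """Down-sized network for fast unit tests of the training machinery."""
    return TrainConfig(hidden_sizes=(16, 8), max_iterations=300, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240815)
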