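import numpy as np
import pytest

from gaitgen.synthetic import simulate_subject, simulate_trial


@pytest.fixture(scope="session")
def subject():
    return simulate_subject(3)


@pytest.fixture(scope="session")
def noise_free_trial(subject):
    """A 10 s noise-free treadmill trial at 4 km/h (right leg concerned)."""
    return simulate_trial(subject, 4.0, duration=10.0, noise_sd=0.0, seed=5)


@pytest.fixture(scope="session")
def noisy_trial(subject):
    """Same trial with the default 0.2 cm marker noise."""
    return simulate_trial(subject, 4.0, duration=10.0, noise_sd=0.2, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
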