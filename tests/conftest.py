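import numpy as np
import pytest

from pawkit.simulate import SimConfig, simulate_landing_trial, simulate_walking_trial


@pytest.fixture(scope="session")
def config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def walking_trial(config):
    """One rendered baseline walking pass (recording + ground truth)."""
    return simulate_walking_trial(config, cat=1, timepoint_h=-24.0, seed=42)


@pytest.fixture(scope="session")
def landing_trial(config):
    """One rendered post-operative landing (recording + ground truth)."""
    return simulate_landing_trial(config, cat=1, timepoint_h=6.0, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """A reduced crossover study (3 trials per session) for table-level tests."""
    from pawkit.simulate import simulate_study

    return simulate_study(seed=11, n_walk=3, n_land=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
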