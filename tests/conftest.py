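import numpy as np
import pytest

import anklemech as am


@pytest.fixture(scope="session")
def truth0():
    """Zero-noise ground truth: the deterministic reference configuration."""
    return am.default_truth(seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def trial0(truth0):
    return am.generate_trial(truth0, "rigid", 0)


@pytest.fixture(scope="session")
def forward0(truth0, trial0):
    return am.forward_simulate(trial0.emg, trial0.theta, trial0.rate,
                               truth0.model, truth0.geometry)


@pytest.fixture(scope="session")
def stance_pct(trial0):
    return 100.0 * trial0.time / trial0.time[-1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
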