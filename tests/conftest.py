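import numpy as np
import pytest

import imuplace as ip


@pytest.fixture(scope="session")
def small_trials():
    """3 participants x 2 trials x 7 surfaces, smoothed; cheap shared input."""
    cfg = ip.GaitSimConfig(n_participants=3, trials_per_surface=2, seed=11)
    return ip.generate_trials(cfg)


@pytest.fixture(scope="session")
def default_trials():
    """The full emulated design: 10 participants x 6 trials x 7 surfaces."""
    cfg = ip.GaitSimConfig(seed=7)
    return ip.generate_trials(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
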