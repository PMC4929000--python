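import numpy as np
import pytest

from swrgamma.synthetic import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact simulated session (95 s at 1 kHz) with its ground truth."""
    cfg = SimConfig(duration=95.0, fs=1000.0, quiet_pre=45.0, gamma_len=5.0,
                    seed=7)
    trace, truth = simulate_session(cfg)
    return cfg, trace, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
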