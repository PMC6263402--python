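import numpy as np
import pytest

from stepmatch import SimConfig, make_library, simulate_recording


@pytest.fixture(scope="session")
def library10():
    """Ten-template synthetic library shared across tests."""
    return make_library(10, rng=42)


@pytest.fixture(scope="session")
def benchmark_suite(library10):
    """20 seeded recordings, 30 steps each, 5% noise: the parameter-recovery suite."""
    suite = []
    for i in range(20):
        cfg = SimConfig(n_steps=30, noise_sigma=0.05, seed=500 + i)
        suite.append(simulate_recording(cfg, library10))
    return suite


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
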