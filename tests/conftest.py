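import numpy as np
import pytest

from otogeo.simulate import SimScenario, simulate_all


@pytest.fixture()
def rng():
    return np.random.default_rng(20160225)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared across read-only tests."""
    sc = SimScenario(n_fish=10, n_obs=120, seed=42)
    return simulate_all(sc)
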