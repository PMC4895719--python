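import numpy as np
import pytest

from subtracta.synthgen import default_scenario, simulate_scenario


@pytest.fixture(scope="session")
def sim():
    """Default planted scenario, generated once per session."""
    return simulate_scenario(default_scenario(seed=1))


@pytest.fixture(scope="session")
def truth(sim):
    return sim.truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
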