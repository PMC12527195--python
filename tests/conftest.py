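import numpy as np
import pytest

from bluffbeach.io import load_table1
from bluffbeach.simulate import SimulationConfig, simulate_sites


@pytest.fixture(scope="session")
def table1():
    """Packaged treatment-mean table, metrics x treatments."""
    return load_table1()


@pytest.fixture(scope="session")
def default_campaign():
    """One simulated 20-site campaign with realistic noise (seed fixed)."""
    cfg = SimulationConfig()
    return cfg, simulate_sites(cfg, seed=20220501)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
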