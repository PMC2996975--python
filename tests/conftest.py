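import numpy as np
import pytest

from mitotrna.reference import human_record
from mitotrna.simulate import SimulationConfig, simulate_usage_and_positions


@pytest.fixture(scope="session")
def human():
    return human_record()


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-species cohort with sequences, shared across tests."""
    cfg = SimulationConfig(seed=42, n_species=6, rho_usage_position=-0.4)
    return simulate_usage_and_positions(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
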