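import numpy as np
import pytest
from hypothesis import settings

from clockrank import SimulationConfig, pipeline, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic universe shared across the session."""
    return synthetic.simulate_all(SimulationConfig(n_genes=1000, n_clock=17, seed=3))


@pytest.fixture(scope="session")
def default_table(default_sim):
    return pipeline.feature_table_from_simulation(default_sim)


@pytest.fixture(scope="session")
def small_sim():
    """A smaller universe for CV-heavy checks."""
    return synthetic.simulate_all(SimulationConfig(n_genes=300, n_clock=10, seed=11))


@pytest.fixture(scope="session")
def small_table(small_sim):
    return pipeline.feature_table_from_simulation(small_sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240321)
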