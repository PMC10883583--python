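import pytest

from sefingerprint.pipeline import run_on_dataset
from sefingerprint.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact panel (4 cancers x 3 cell lines x 2 replicates) for
    structural tests that do not assert statistical recovery."""
    return SimulationConfig(n_cancers=4, cells_per_cancer=3, n_ses=30,
                            ces_per_se=3, n_other_enhancers=150, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    return run_on_dataset(small_dataset)
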