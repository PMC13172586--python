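import numpy as np
import pytest

from stonescreen import SimulationConfig, generate_dataset
from stonescreen.synthetic_data import default_motifs


@pytest.fixture(scope="session")
def patterns():
    return default_motifs()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 4 fractions, short proteins, links planted on
    aggregation/adhesion as in the default conditions."""
    return SimulationConfig(
        seed=11,
        n_fractions=4,
        proteins_per_fraction=(6, 8, 10, 5),
        length_range=(80, 400),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
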