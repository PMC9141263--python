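import numpy as np
import pytest

from lurgbm import kriging as kg
from lurgbm import synthetic as syn


@pytest.fixture(scope="session")
def small_truth():
    """A compact simulated region: 10×10 cells of 25 km, January 2016."""
    cfg = syn.SyntheticConfig(
        grid_nx=10,
        grid_ny=10,
        n_stations=20,
        date_start="2016-01-01",
        date_end="2016-01-31",
        seed=7,
    )
    return syn.simulate_truth(cfg)


@pytest.fixture(scope="session")
def small_records(small_truth):
    return syn.sample_stations(small_truth, 20, seed=8)


@pytest.fixture(scope="session")
def toy_variogram():
    return kg.VariogramModel("spherical", nugget=0.0, partial_sill=25.0, range_km=150.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
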