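import numpy as np
import pytest

from barrierpop.simulate import SimConfig, simulate_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """A cheap 4-pair null landscape shared across tests."""
    cfg = SimConfig(n_pairs=4, treatments=("R", "H", "CB", "R"),
                    n_low=30, n_peak=120, generations=9,
                    n_sample_min=12, n_sample_max=18, seed=20)
    return simulate_landscape(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
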