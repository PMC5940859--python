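import numpy as np
import pytest

from sizevarpart import SimConfig, simulate_stock


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_stock():
    """A quick synthetic stock for plumbing tests (15 years, light sampling)."""
    return simulate_stock(SimConfig(n_years=15, N_sample=800, seed=99))
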