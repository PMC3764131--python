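import numpy as np
import pytest

from ribosim import KineticConstants, build_rate_table
from ribosim.fixtures import make_minimal_pool, make_trna_pool

CELL_VOLUME = 1e-18  # m^3


@pytest.fixture(scope="session")
def pool_and_constants():
    return make_trna_pool(seed=12345)


@pytest.fixture(scope="session")
def rate_table(pool_and_constants):
    pool, kc = pool_and_constants
    return build_rate_table(pool, kc, CELL_VOLUME, organism="synthetic")


@pytest.fixture(scope="session")
def uniform_table():
    """All 61 codons at exactly 0.1 s (competition-free universal decoder)."""
    return build_rate_table(
        make_minimal_pool(), KineticConstants(tau_cognate=0.1), CELL_VOLUME
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
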