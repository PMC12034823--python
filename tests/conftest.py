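import numpy as np
import pytest

from oddstream import generate_session


@pytest.fixture(scope="session")
def small_session():
    """Two-block session, 10 sets per block (100 deviants)."""
    return generate_session(11, n_blocks=2, n_sets_per_block=10)


@pytest.fixture(scope="session")
def default_session():
    """Default-size session: 6 blocks x 60 sets -> 1800 deviants."""
    return generate_session(1, n_blocks=6, n_sets_per_block=60)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
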