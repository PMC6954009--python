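import numpy as np
import pytest

from respulse import LocalParams, make_continuous


@pytest.fixture
def default_params() -> LocalParams:
    return LocalParams()


@pytest.fixture
def small_grid():
    """Fast 20x20 continuous landscape covering the standard 100 m domain."""
    return make_continuous(2.5, LocalParams(), n_x=20, n_y=20, cell_size=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
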