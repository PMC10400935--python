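import numpy as np
import pytest

from burstscape import ParamGrid


@pytest.fixture(scope="session")
def default_grid():
    """The standard fitting grid with all PMFs cached (built once)."""
    grid = ParamGrid.default()
    grid.log_pmf  # trigger the cache build
    return grid


@pytest.fixture(scope="session")
def small_grid():
    """A compact grid for unit tests that exercise fitting logic cheaply."""
    grid = ParamGrid(
        theta_on=np.logspace(-2, 1, 8),
        theta_off=np.logspace(-2, 2, 8),
        theta_t=np.logspace(-1, np.log10(120.0), 10),
        m_max=120,
    )
    grid.log_pmf
    return grid
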