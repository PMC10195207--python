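import numpy as np
import pytest

from dbsi import build_grid_scheme
from dbsi.fit import FitConfig


@pytest.fixture(scope="session")
def table():
    """The grid-based multi-b-value scheme (r=3, b_max 1500 s/mm^2)."""
    return build_grid_scheme(3, 1500)


@pytest.fixture(scope="session")
def config():
    return FitConfig()


@pytest.fixture(scope="session")
def spectrum_grid(config):
    return config.spectrum_grid


def spike_spectrum(grid, placements):
    """Weights vector with the given {D: weight} placed on grid points."""
    w = np.zeros(len(grid))
    for D, wt in placements.items():
        j = int(np.argmin(np.abs(grid - D)))
        assert np.isclose(grid[j], D), f"D={D} not on grid"
        w[j] += wt
    return w
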