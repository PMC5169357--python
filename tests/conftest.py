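import numpy as np
import pytest

import roadscape as rs


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def flat_grid():
    """10x10 all-valid grid near the equator (nearly equal cell areas)."""
    return rs.Grid(10, 10, cell_size=0.0833, origin=(100.0, 0.4165))


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic landscape shared by read-only tests."""
    params = rs.LandscapeParams(n_rows=40, n_cols=40, n_species=10,
                                n_crops=5, n_proposals=4, seed=7)
    return rs.generate_landscape(params)


def random_surface(grid, rng, low=0.0, high=1.0, units=""):
    vals = rng.uniform(low, high, grid.shape)
    return rs.Surface(grid, vals, units)
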