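import numpy as np
import pytest

from hpvsdm import GridSpec, LandscapeConfig, InvasionConfig, make_study


@pytest.fixture
def small_grid() -> GridSpec:
    """20 x 20 cells of 1/120 degree near latitude 52 N."""
    return GridSpec.from_origin(19.0, 52.0, 20, 20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_study():
    """A fast 100 x 100 synthetic study shared across tests."""
    grid = GridSpec.from_origin(19.0, 52.0 - 100.0 / 240.0, 100, 100)
    lc = LandscapeConfig(grid=grid, seed=3)
    ic = InvasionConfig(seed=4)
    return make_study(lc, ic)


def random_points(rng, grid: GridSpec, n: int) -> np.ndarray:
    lon = rng.uniform(grid.xmin, grid.xmax - 1e-9, n)
    lat = rng.uniform(grid.ymin + 1e-9, grid.ymax, n)
    return np.column_stack((lon, lat))
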