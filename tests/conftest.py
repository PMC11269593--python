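import numpy as np
import pytest

from batwind.grids import GridSpec, RasterLayer
from batwind.landscape import DEFAULT_TRUTH, LandscapeConfig, generate_env_stack


@pytest.fixture
def grid_small() -> GridSpec:
    """10x10 grid, 1-km cells, anchored at the origin."""
    return GridSpec(0.0, 10_000.0, 1000.0, 10, 10, "test-plane")


@pytest.fixture
def grid_3x3() -> GridSpec:
    return GridSpec(0.0, 3000.0, 1000.0, 3, 3, "test-plane")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def env_spring():
    """One season's environmental stack on a 40x40 grid (session-cached)."""
    grid = GridSpec(0.0, 40_000.0, 1000.0, 40, 40, "test-plane")
    cfg = LandscapeConfig(grid=grid, seed=77, autocorr_len=4.0, n_seasons=1)
    return generate_env_stack(cfg)["spring"]


@pytest.fixture(scope="session")
def truth_model():
    return DEFAULT_TRUTH


def make_raster(grid: GridSpec, values, nodata=-9999.0, kind="continuous") -> RasterLayer:
    return RasterLayer(grid, np.asarray(values), nodata=nodata, kind=kind)
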