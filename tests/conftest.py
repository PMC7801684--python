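import numpy as np
import pytest

from dipsdm.core_rasters import EnvStack, RasterGrid
from dipsdm.synthetic_data import generate_env_stack


@pytest.fixture(scope="session")
def small_stack_and_dem():
    """A deterministic 64x64 synthetic landscape shared across tests."""
    return generate_env_stack(64, 64, n_bioclim=3, n_soil=8, seed=42)


@pytest.fixture(scope="session")
def small_stack(small_stack_and_dem):
    return small_stack_and_dem[0]


@pytest.fixture(scope="session")
def small_dem(small_stack_and_dem):
    return small_stack_and_dem[1]


@pytest.fixture()
def unit_grid():
    """10x10 planar grid of ones with 1-km cells."""
    return RasterGrid(np.ones((10, 10)), x0=0.0, y0=10.0, dx=1.0, dy=1.0)


def make_stack(arrays: dict, cell_km: float = 1.0, scenario_id: str = "current") -> EnvStack:
    nr, nc = next(iter(arrays.values())).shape
    return EnvStack(
        {
            name: RasterGrid(np.asarray(a, dtype=float), x0=0.0, y0=nr * cell_km,
                             dx=cell_km, dy=cell_km)
            for name, a in arrays.items()
        },
        scenario_id=scenario_id,
    )
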