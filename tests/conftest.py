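import numpy as np
import pytest
from shapely.geometry import box

from pestmap import synth
from pestmap.bayes import build_adjacency
from pestmap.grids import DistrictGeometry, EnvGrid


@pytest.fixture(scope="session")
def landscape():
    """Small deterministic landscape: 24x24, 3 months."""
    return synth.make_landscape(24, 24, 3, seed=11)


@pytest.fixture(scope="session")
def square_districts():
    """2x2 tessellation of a 400 m x 400 m extent (4 districts)."""
    out = []
    for iy in range(2):
        for ix in range(2):
            out.append(DistrictGeometry(
                district_id=f"D{iy}{ix}",
                polygon=box(ix * 200, -(iy + 1) * 200, (ix + 1) * 200, -iy * 200)))
    return out


@pytest.fixture(scope="session")
def district_scene():
    """100-district scene with populations and adjacency, for model tests."""
    grid = synth.make_landscape(32, 32, 1, seed=7)
    districts, pops = synth.make_districts(grid, 10, 10, seed=7)
    graph = build_adjacency(districts)
    return grid, districts, pops, graph


@pytest.fixture
def small_grid():
    g = EnvGrid(4, 4, cell_size_m=100.0, origin=(0.0, 0.0))
    g.add_layer("slope_deg", np.full((4, 4), 5.0))
    g.add_layer("soc_percent", np.full((4, 4), 2.0))
    g.add_layer("precip_mm[0]", np.full((4, 4), 100.0))
    g.add_layer("runoff_mm[0]", np.full((4, 4), 30.0))
    return g
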