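import numpy as np
import pytest

from marineqc import (
    LightRasterStack,
    Polygon,
    PolygonSet,
    WorldConfig,
    build_world,
    generate_records,
)


def rect_ring(x0, y0, x1, y1):
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)]


@pytest.fixture(scope="session")
def world_cfg():
    return WorldConfig(seed=7)


@pytest.fixture(scope="session")
def world(world_cfg):
    return build_world(world_cfg)


@pytest.fixture(scope="session")
def labelled_records(world, world_cfg):
    """A 500-record synthetic set with its ground truth (session-cached)."""
    return generate_records(world, 500, seed=11, cfg=world_cfg)


@pytest.fixture()
def unit_square():
    return Polygon(outer=rect_ring(0.0, 0.0, 1.0, 1.0))


@pytest.fixture()
def uniform_stack():
    def make(value: float, n: int = 10, cellsize: float = 0.1):
        grid = np.full((n, n), value)
        return LightRasterStack(xll=0.0, yll=0.0, cellsize=cellsize,
                                layers=[grid.copy() for _ in range(3)])

    return make


@pytest.fixture()
def island_world():
    """A tiny hand-built landscape: one 1-degree island with known geometry."""
    land = PolygonSet([Polygon(outer=rect_ring(2.0, 2.0, 3.0, 3.0))])
    provinces = PolygonSet([
        Polygon(outer=rect_ring(0.0, 0.0, 2.5, 5.0), attribute=1),
        Polygon(outer=rect_ring(2.5, 0.0, 5.0, 5.0), attribute=2),
    ])
    return land, provinces
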