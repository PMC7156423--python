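"""Geometric kernels against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from marineqc import (
    GeoPoint,
    LightRasterStack,
    Polygon,
    PolygonSet,
    distance_to_shoreline_km,
    haversine_km,
    locate_province,
    point_in_polygon,
    sample_light_max,
)
from marineqc.geospatial import EARTH_RADIUS_KM, _read_ascii_grid

from conftest import rect_ring

R = EARTH_RADIUS_KM


# ---------------------------------------------------------------- haversine

def test_haversine_closed_forms():
    # one degree of latitude at the equator: pi*R/180
    d = haversine_km(GeoPoint(0, 0), GeoPoint(0, 1))
    assert d == pytest.approx(math.pi * R / 180.0, abs=1e-3)
    # antipodal along the equator: pi*R
    d = haversine_km(GeoPoint(0, 0), GeoPoint(180, 0))
    assert d == pytest.approx(math.pi * R, abs=1e-2)
    assert haversine_km(GeoPoint(12.3, -45.6), GeoPoint(12.3, -45.6)) == 0.0


@settings(max_examples=200, derandomize=True)
@given(
    lon1=st.floats(-180, 180), lat1=st.floats(-90, 90),
    lon2=st.floats(-180, 180), lat2=st.floats(-90, 90),
)
def test_haversine_properties(lon1, lat1, lon2, lat2):
    a, b = GeoPoint(lon1, lat1), GeoPoint(lon2, lat2)
    d_ab, d_ba = haversine_km(a, b), haversine_km(b, a)
    assert d_ab == pytest.approx(d_ba, abs=1e-9)
    assert 0.0 <= d_ab <= math.pi * R + 1e-6


def test_geopoint_range_validation():
    with pytest.raises(ValueError):
        GeoPoint(181.0, 0.0)
    with pytest.raises(ValueError):
        GeoPoint(0.0, -91.0)


# ----------------------------------------------------------- point in polygon

def _winding_number(px, py, ring):
    """Signed-angle winding number oracle (independent of ray casting)."""
    total = 0.0
    for i in range(len(ring) - 1):
        ax, ay = ring[i][0] - px, ring[i][1] - py
        bx, by = ring[i + 1][0] - px, ring[i + 1][1] - py
        total += math.atan2(ax * by - ay * bx, ax * bx + ay * by)
    return total  # ~ +/-2*pi inside, ~0 outside


def _random_star_polygon(rng, cx, cy, n_vertices=12, rmax=1.0):
    # jittered regular angular spacing keeps every gap below pi, so the
    # star polygon is simple by construction
    angles = (np.arange(n_vertices) + rng.uniform(0.05, 0.95, n_vertices)) \
        * 2 * math.pi / n_vertices
    radii = rng.uniform(0.2 * rmax, rmax, n_vertices)
    ring = [(cx + r * math.cos(a), cy + r * math.sin(a)) for a, r in zip(angles, radii)]
    ring.append(ring[0])
    return Polygon(outer=ring)


def test_point_in_polygon_basics(unit_square):
    assert point_in_polygon(GeoPoint(0.5, 0.5), unit_square)
    assert not point_in_polygon(GeoPoint(10.0, 10.0), unit_square)
    # boundary edges and vertices count as inside
    assert point_in_polygon(GeoPoint(0.0, 0.5), unit_square)
    assert point_in_polygon(GeoPoint(1.0, 1.0), unit_square)


def test_point_in_polygon_with_hole():
    poly = Polygon(outer=rect_ring(0, 0, 4, 4), holes=[rect_ring(1, 1, 3, 3)])
    assert point_in_polygon(GeoPoint(0.5, 0.5), poly)
    assert not point_in_polygon(GeoPoint(2.0, 2.0), poly)  # inside the hole
    assert point_in_polygon(GeoPoint(1.0, 2.0), poly)      # hole boundary


def test_point_in_polygon_against_winding_oracle():
    """Ray casting agrees with the winding-number oracle on 50 random
    simple polygons x 1000 uniform points."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        poly = _random_star_polygon(rng, cx=rng.uniform(-5, 5), cy=rng.uniform(-5, 5))
        minx, miny, maxx, maxy = poly.bbox
        pts_x = rng.uniform(minx - 0.5, maxx + 0.5, 1000)
        pts_y = rng.uniform(miny - 0.5, maxy + 0.5, 1000)
        for px, py in zip(pts_x, pts_y):
            expected = abs(_winding_number(px, py, poly.outer)) > math.pi
            assert point_in_polygon(GeoPoint(px, py), poly) == expected


def test_point_in_polygon_against_shapely():
    shapely = pytest.importorskip("shapely")
    from shapely.geometry import Point as SPoint, Polygon as SPolygon

    rng = np.random.default_rng(7)
    for _ in range(20):
        poly = _random_star_polygon(rng, cx=0.0, cy=0.0)
        sp = SPolygon(poly.outer)
        for _ in range(200):
            px, py = rng.uniform(-1.5, 1.5, 2)
            assert point_in_polygon(GeoPoint(px, py), poly) == sp.covers(SPoint(px, py))


def test_polygon_validation_errors():
    with pytest.raises(ValueError, match="closed"):
        Polygon(outer=[(0, 0), (1, 0), (1, 1)]).validate()
    bowtie = [(0, 0), (1, 1), (1, 0), (0, 1), (0, 0)]
    with pytest.raises(ValueError, match="self-intersecting"):
        Polygon(outer=bowtie).validate()
    spanning = [(-170, 0), (170, 0), (170, 1), (-170, 1), (-170, 0)]
    with pytest.raises(ValueError, match="antimeridian|180"):
        Polygon(outer=spanning).validate()


# ------------------------------------------------------- shoreline distance

def _dense_boundary_oracle(p, polys, step=0.001):
    """Independent oracle: min haversine over boundary points at 0.001 deg."""
    best = math.inf
    for poly in polys.polygons:
        for ring in [poly.outer, *poly.holes]:
            for i in range(len(ring) - 1):
                (ax, ay), (bx, by) = ring[i], ring[i + 1]
                n = max(1, int(math.ceil(max(abs(bx - ax), abs(by - ay)) / step)))
                for t in np.linspace(0.0, 1.0, n + 1):
                    best = min(best, haversine_km(p, GeoPoint(ax + t * (bx - ax), ay + t * (by - ay))))
    return best


def test_shoreline_distance_closed_form():
    land = PolygonSet([Polygon(outer=rect_ring(-1.0, -1.0, 0.0, 1.0))])
    # 0.1 degree of longitude at the equator from the meridian edge
    d = distance_to_shoreline_km(GeoPoint(0.1, 0.0), land)
    assert d == pytest.approx(math.pi * R / 1800.0, abs=0.01)


def test_shoreline_distance_vertex_is_zero(unit_square):
    land = PolygonSet([unit_square])
    assert distance_to_shoreline_km(GeoPoint(1.0, 1.0), land) == 0.0


def test_shoreline_distance_empty_set_fatal():
    with pytest.raises(ValueError):
        distance_to_shoreline_km(GeoPoint(0, 0), PolygonSet([]))


def test_shoreline_distance_against_dense_oracle():
    """Within 0.05 km of a 0.001-degree dense-sampling oracle on 100
    random point/polygon pairs."""
    rng = np.random.default_rng(3)
    for _ in range(100):
        cx, cy = rng.uniform(-40, 40, 2)
        poly = _random_star_polygon(rng, cx, cy, n_vertices=8, rmax=0.5)
        land = PolygonSet([poly])
        p = GeoPoint(cx + rng.uniform(-1.5, 1.5), cy + rng.uniform(-1.5, 1.5))
        assert distance_to_shoreline_km(p, land) == pytest.approx(
            _dense_boundary_oracle(p, land), abs=0.05
        )


# -------------------------------------------------------------- light raster

def test_sample_light_max_rules():
    nodata = -9999.0
    mk = lambda v: np.full((4, 4), float(v))
    stack = LightRasterStack(xll=0, yll=0, cellsize=1.0,
                             layers=[mk(10), mk(40), mk(60)])
    p = GeoPoint(2.5, 2.5)
    assert sample_light_max(p, stack) == 60.0
    stack = LightRasterStack(xll=0, yll=0, cellsize=1.0,
                             layers=[mk(nodata), mk(20), mk(nodata)], nodata=nodata)
    assert sample_light_max(p, stack) == 20.0
    stack = LightRasterStack(xll=0, yll=0, cellsize=1.0,
                             layers=[mk(nodata)] * 3, nodata=nodata)
    assert sample_light_max(p, stack) is None
    assert sample_light_max(GeoPoint(9.0, 9.0), stack) is None  # outside grid


def test_sample_light_max_layer_order_invariant():
    rng = np.random.default_rng(0)
    layers = [rng.uniform(0, 100, (5, 5)) for _ in range(3)]
    p = GeoPoint(2.2, 3.7)
    vals = set()
    import itertools
    for perm in itertools.permutations(layers):
        stack = LightRasterStack(xll=0, yll=0, cellsize=1.0, layers=list(perm))
        vals.add(sample_light_max(p, stack))
    assert len(vals) == 1


def test_sample_light_nearest_cell_addressing():
    grid = np.arange(12, dtype=float).reshape(3, 4)  # row 0 = north
    stack = LightRasterStack(xll=10.0, yll=20.0, cellsize=0.5,
                             layers=[grid, grid, grid])
    # south-west cell is the last row, first column
    assert sample_light_max(GeoPoint(10.1, 20.1), stack) == grid[2, 0]
    # north-east cell is the first row, last column
    assert sample_light_max(GeoPoint(11.9, 21.4), stack) == grid[0, 3]


def test_ascii_grid_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    stack = LightRasterStack(xll=-3.25, yll=40.0, cellsize=0.25,
                             layers=[rng.uniform(0, 200, (6, 9)) for _ in range(3)])
    paths = stack.to_ascii_grids(tmp_path)
    back = LightRasterStack.from_ascii_grids(paths)
    assert back.xll == stack.xll and back.yll == stack.yll and back.cellsize == stack.cellsize
    for a, b in zip(stack.layers, back.layers):
        np.testing.assert_array_equal(a, b)


# ----------------------------------------------------------------- provinces

def test_locate_province(island_world):
    _, provinces = island_world
    assert locate_province(GeoPoint(1.0, 1.0), provinces) == 1
    assert locate_province(GeoPoint(4.0, 4.0), provinces) == 2
    assert locate_province(GeoPoint(9.0, 9.0), provinces) is None
    # shared edge: lowest ID wins
    assert locate_province(GeoPoint(2.5, 2.0), provinces) == 1


def test_geojson_round_trip(tmp_path, island_world):
    _, provinces = island_world
    path = provinces.to_geojson(tmp_path / "prov.geojson")
    back = PolygonSet.from_geojson(path, attribute_property="province_id")
    assert len(back) == 2
    assert [p.attribute for p in back.polygons] == [1, 2]
    assert back.polygons[0].outer == provinces.polygons[0].outer
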