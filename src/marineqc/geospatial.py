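"""Self-contained geometric kernels for occurrence-record quality control.

All computations are spherical (mean Earth radius 6371.0 km) on WGS84-style
longitude/latitude degrees. Polygons are simple rings in lon/lat space with
optional holes; rasters are regular lon/lat grids in the plain-text ESRI
ASCII grid format, one file per benthic-light depth layer.

The kernels are deliberately small and independently verifiable: haversine
against its closed forms, ray-casting point-in-polygon against a
winding-number oracle, shoreline distance against dense boundary sampling.
Antimeridian-crossing polygons are not supported; inputs must be split at
±180° (rejected on load).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "Polygon",
    "PolygonSet",
    "LightRasterStack",
    "haversine_km",
    "point_in_polygon",
    "distance_to_shoreline_km",
    "sample_light_max",
    "locate_province",
]


@dataclass(frozen=True)
class GeoPoint:
    """A longitude/latitude pair in decimal degrees."""

    longitude: float
    latitude: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")


Ring = Sequence[tuple[float, float]]


def _ring_is_closed(ring: Ring) -> bool:
    return len(ring) >= 4 and ring[0] == ring[-1]


def _segments_properly_intersect(p1, p2, q1, q2) -> bool:
    """True if open segments p1p2 and q1q2 cross at an interior point."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if v > 1e-15:
            return 1
        if v < -1e-15:
            return -1
        return 0

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def _validate_ring(ring: Ring) -> None:
    if not _ring_is_closed(ring):
        raise ValueError("polygon ring must be closed (first vertex = last) with >= 4 vertices")
    lons = [v[0] for v in ring]
    if max(lons) - min(lons) > 180.0:
        raise ValueError(
            "ring spans more than 180 degrees of longitude; "
            "antimeridian-crossing polygons must be split at +/-180"
        )
    # O(n^2) proper-intersection scan; rings here are small (synthetic islands,
    # province tiles, coarse coastlines).
    n = len(ring) - 1
    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (0, 1) or (i == 0 and j == n - 1):
                continue
            if _segments_properly_intersect(ring[i], ring[i + 1], ring[j], ring[j + 1]):
                raise ValueError("self-intersecting polygon ring")


@dataclass
class Polygon:
    """One outer ring plus zero or more hole rings, with an optional attribute."""

    outer: list[tuple[float, float]]
    holes: list[list[tuple[float, float]]] = field(default_factory=list)
    attribute: object | None = None

    def validate(self) -> "Polygon":
        _validate_ring(self.outer)
        for h in self.holes:
            _validate_ring(h)
        return self

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        xs = [v[0] for v in self.outer]
        ys = [v[1] for v in self.outer]
        return min(xs), min(ys), max(xs), max(ys)


@dataclass
class PolygonSet:
    """A validated collection of attributed polygons (landmass, provinces)."""

    polygons: list[Polygon]

    def __post_init__(self) -> None:
        for p in self.polygons:
            p.validate()

    def __len__(self) -> int:
        return len(self.polygons)

    @classmethod
    def from_geojson(cls, path: str | Path, attribute_property: str | None = None) -> "PolygonSet":
        """Load Polygon/MultiPolygon features from a GeoJSON FeatureCollection.

        ``attribute_property`` names the feature property carried as each
        polygon's attribute (e.g. ``"province_id"``).
        """
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        if gj.get("type") != "FeatureCollection":
            raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
        polys: list[Polygon] = []
        for feat in gj.get("features", []):
            geom = feat.get("geometry") or {}
            attr = None
            if attribute_property is not None:
                attr = (feat.get("properties") or {}).get(attribute_property)
            gtype = geom.get("type")
            if gtype == "Polygon":
                parts = [geom["coordinates"]]
            elif gtype == "MultiPolygon":
                parts = geom["coordinates"]
            else:
                raise ValueError(f"{path}: unsupported geometry type {gtype!r}")
            for rings in parts:
                outer = [tuple(map(float, v)) for v in rings[0]]
                holes = [[tuple(map(float, v)) for v in r] for r in rings[1:]]
                polys.append(Polygon(outer=outer, holes=holes, attribute=attr))
        return cls(polys)

    def to_geojson(self, path: str | Path, attribute_property: str = "province_id") -> Path:
        feats = []
        for p in self.polygons:
            props = {} if p.attribute is None else {attribute_property: p.attribute}
            feats.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[list(v) for v in p.outer]]
                        + [[list(v) for v in h] for h in p.holes],
                    },
                }
            )
        path = Path(path)
        path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}), encoding="utf-8")
        return path


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0 km."""
    la1, lo1 = math.radians(a.latitude), math.radians(a.longitude)
    la2, lo2 = math.radians(b.latitude), math.radians(b.longitude)
    s = (
        math.sin((la2 - la1) / 2.0) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def _haversine_km_vec(lon: float, lat: float, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    la1, lo1 = math.radians(lat), math.radians(lon)
    la2, lo2 = np.radians(lats), np.radians(lons)
    s = np.sin((la2 - la1) / 2.0) ** 2 + math.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(s)))


_EPS = 1e-12


def _on_segment(px: float, py: float, ax: float, ay: float, bx: float, by: float) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > 1e-12:
        return False
    return min(ax, bx) - _EPS <= px <= max(ax, bx) + _EPS and min(ay, by) - _EPS <= py <= max(ay, by) + _EPS


def _ray_cast(px: float, py: float, ring: Ring) -> bool:
    """Even-odd ray casting; boundary handled separately by the caller."""
    inside = False
    n = len(ring) - 1
    for i in range(n):
        ax, ay = ring[i]
        bx, by = ring[i + 1]
        if (ay > py) != (by > py):
            x_int = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_int:
                inside = not inside
    return inside


def _on_ring_boundary(px: float, py: float, ring: Ring) -> bool:
    for i in range(len(ring) - 1):
        ax, ay = ring[i]
        bx, by = ring[i + 1]
        if _on_segment(px, py, ax, ay, bx, by):
            return True
    return False


def point_in_polygon(p: GeoPoint, poly: Polygon) -> bool:
    """Even-odd containment test; points exactly on any boundary edge count
    as inside (including hole boundaries); hole interiors are excluded."""
    px, py = p.longitude, p.latitude
    minx, miny, maxx, maxy = poly.bbox
    if not (minx - _EPS <= px <= maxx + _EPS and miny - _EPS <= py <= maxy + _EPS):
        return False
    if _on_ring_boundary(px, py, poly.outer):
        return True
    for h in poly.holes:
        if _on_ring_boundary(px, py, h):
            return True
    if not _ray_cast(px, py, poly.outer):
        return False
    return not any(_ray_cast(px, py, h) for h in poly.holes)


def point_in_polygonset(p: GeoPoint, polys: PolygonSet) -> bool:
    return any(point_in_polygon(p, poly) for poly in polys.polygons)


class ShorelineDistance:
    """Reusable shoreline-distance evaluator caching the densified boundary.

    Every boundary segment is sampled at steps of at most ``step_deg``
    degrees (~1.1 km at the equator by default). A query takes the minimum
    haversine distance over all coarse samples, then refines: each segment
    whose best coarse sample is within one step of the global best is
    re-sampled at 1/1000 of the coarse step around that sample, bounding
    the discretization error by roughly a metre.
    """

    _REFINE = 1000

    def __init__(self, land: PolygonSet, step_deg: float = 0.01) -> None:
        if len(land) == 0:
            raise ValueError("empty PolygonSet: no shoreline to measure against")
        self.step_deg = step_deg
        segs: list[tuple[float, float, float, float]] = []
        xs: list[np.ndarray] = []
        ys: list[np.ndarray] = []
        seg_ids: list[np.ndarray] = []
        ts: list[np.ndarray] = []
        dts: list[np.ndarray] = []
        for poly in land.polygons:
            for ring in [poly.outer, *poly.holes]:
                for i in range(len(ring) - 1):
                    ax, ay = ring[i]
                    bx, by = ring[i + 1]
                    sid = len(segs)
                    segs.append((ax, ay, bx, by))
                    n = max(1, int(math.ceil(max(abs(bx - ax), abs(by - ay)) / step_deg)))
                    t = np.linspace(0.0, 1.0, n + 1)
                    xs.append(ax + t * (bx - ax))
                    ys.append(ay + t * (by - ay))
                    seg_ids.append(np.full(n + 1, sid))
                    ts.append(t)
                    dts.append(np.full(n + 1, 1.0 / n))
        self._segs = np.asarray(segs)
        self._bx = np.concatenate(xs)
        self._by = np.concatenate(ys)
        self._sid = np.concatenate(seg_ids)
        self._t = np.concatenate(ts)
        self._dt = np.concatenate(dts)

    def __call__(self, p: GeoPoint) -> float:
        d = _haversine_km_vec(p.longitude, p.latitude, self._bx, self._by)
        best = float(np.min(d))
        if best == 0.0:
            return 0.0
        # The true minimizer lies within one coarse step of some sample whose
        # distance is within one step-length (in km) of the global coarse
        # minimum; fine-sample a +/- one-step window around each such sample.
        margin = self.step_deg * math.pi * EARTH_RADIUS_KM / 180.0
        idx = np.nonzero(d <= best + margin)[0]
        fine = np.linspace(-1.0, 1.0, self._REFINE + 1)
        t = np.clip(self._t[idx, None] + self._dt[idx, None] * fine[None, :], 0.0, 1.0)
        ax, ay, bx, by = (self._segs[self._sid[idx]][:, k, None] for k in range(4))
        fx = (ax + t * (bx - ax)).ravel()
        fy = (ay + t * (by - ay)).ravel()
        return min(best, float(np.min(_haversine_km_vec(p.longitude, p.latitude, fx, fy))))


def distance_to_shoreline_km(
    p: GeoPoint, land: PolygonSet, step_deg: float = 0.01
) -> float:
    """Minimum great-circle distance from ``p`` to any land boundary ring.

    Convenience wrapper over :class:`ShorelineDistance`; build that class
    directly when measuring many points against the same landmass.
    """
    return ShorelineDistance(land, step_deg)(p)


@dataclass
class LightRasterStack:
    """Three benthic-light layers (one per depth range) on one regular grid.

    Grid geometry follows the ESRI ASCII convention: ``xll, yll`` are the
    lower-left corner, rows are stored north-to-south. Values are annual
    light doses in E·m⁻²·yr⁻¹; ``nodata`` marks land or unlit cells.
    """

    xll: float
    yll: float
    cellsize: float
    layers: list[np.ndarray]  # each (nrows, ncols), row 0 = northernmost
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if len(self.layers) != 3:
            raise ValueError("LightRasterStack requires exactly 3 layers")
        shapes = {l.shape for l in self.layers}
        if len(shapes) != 1:
            raise ValueError("all layers must share the same grid geometry")

    @property
    def nrows(self) -> int:
        return self.layers[0].shape[0]

    @property
    def ncols(self) -> int:
        return self.layers[0].shape[1]

    def cell_index(self, p: GeoPoint) -> tuple[int, int] | None:
        """(row, col) of the cell containing p, or None outside the grid."""
        col = int(math.floor((p.longitude - self.xll) / self.cellsize))
        row_s = int(math.floor((p.latitude - self.yll) / self.cellsize))
        if not (0 <= col < self.ncols and 0 <= row_s < self.nrows):
            return None
        return self.nrows - 1 - row_s, col

    @classmethod
    def from_ascii_grids(cls, paths: Sequence[str | Path]) -> "LightRasterStack":
        if len(paths) != 3:
            raise ValueError("expected 3 layer files (one per depth range)")
        geom = None
        layers = []
        nodata = -9999.0
        for path in paths:
            hdr, grid = _read_ascii_grid(path)
            g = (hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"], hdr["ncols"], hdr["nrows"])
            if geom is None:
                geom = g
                nodata = hdr["nodata_value"]
            elif g != geom:
                raise ValueError(f"{path}: grid geometry differs between layers")
            layers.append(grid)
        xll, yll, cs, _, _ = geom
        return cls(xll=xll, yll=yll, cellsize=cs, layers=layers, nodata=nodata)

    def to_ascii_grids(self, directory: str | Path, prefix: str = "light_layer") -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = []
        for k, layer in enumerate(self.layers, start=1):
            path = directory / f"{prefix}{k}.asc"
            _write_ascii_grid(path, layer, self.xll, self.yll, self.cellsize, self.nodata)
            out.append(path)
        return out


def _read_ascii_grid(path: str | Path) -> tuple[dict, np.ndarray]:
    header: dict = {}
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    with open(path, encoding="utf-8") as fh:
        pos = 0
        for _ in range(6):
            line = fh.readline()
            name, _, val = line.strip().partition(" ")
            name = name.lower()
            if name not in keys:
                break
            header[name] = float(val)
            pos = fh.tell()
        fh.seek(pos)
        grid = np.loadtxt(fh, ndmin=2)
    header["ncols"] = int(header["ncols"])
    header["nrows"] = int(header["nrows"])
    header.setdefault("nodata_value", -9999.0)
    if grid.shape != (header["nrows"], header["ncols"]):
        raise ValueError(f"{path}: grid shape {grid.shape} does not match header")
    return header, grid


def _write_ascii_grid(
    path: str | Path, grid: np.ndarray, xll: float, yll: float, cellsize: float, nodata: float
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in grid:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def sample_light_max(p: GeoPoint, stack: LightRasterStack) -> float | None:
    """Maximum benthic light over the three depth layers at the cell
    containing ``p`` (nearest-cell lookup, no interpolation).

    Taking the maximum over layers is the conservative choice when record
    depth is unknown: a site is only called light-limited if no depth range
    offers enough light. Returns None outside the grid or where all layers
    are nodata.
    """
    idx = stack.cell_index(p)
    if idx is None:
        return None
    r, c = idx
    vals = [layer[r, c] for layer in stack.layers]
    lit = [v for v in vals if v != stack.nodata]
    return float(max(lit)) if lit else None


def locate_province(p: GeoPoint, provinces: PolygonSet):
    """ID of the attributed province polygon containing ``p``.

    On shared boundaries more than one polygon may contain the point; the
    lowest ID wins (deterministic tie-break). Returns None if no polygon
    contains the point.
    """
    hits = [poly.attribute for poly in provinces.polygons if point_in_polygon(p, poly)]
    if not hits:
        return None
    return min(hits)
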