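"""Deterministic synthetic worlds with ground-truth labelled records.

The generator builds a complete, self-consistent miniature study system —
rectangular islands on a regular grid, a 3-layer benthic light raster
decaying with distance from shore, a rectangular province tiling, a taxon
registry with synonyms, a known-range table and a gazetteer — plus
occurrence record sets in which every record carries a ground-truth error
label. Because the geometry is cell-aligned and every placement keeps a
guard margin from each decision boundary (the 1 km shoreline tolerance,
the 50 E·m⁻²·yr⁻¹ light threshold, province edges), the quality-control
pipeline is expected to recover the labels *exactly*, not approximately.

Everything derives from a single integer seed; the same seed reproduces
the same world and records bit for bit.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .dwc_core import Gazetteer, OccurrenceRecord, RecordSet
from .geospatial import LightRasterStack, Polygon, PolygonSet
from .qcflags import KnownRangeTable
from .taxonomy import TaxonRecord, TaxonRegistry
from .world import World

#: Relative per-layer attenuation: deeper layers receive less light.
_LAYER_FACTORS = (1.0, 0.85, 0.70)

_KELP_GENERA = ["Fucus", "Laminaria", "Saccharina", "Cystoseira", "Ecklonia", "Halidrys"]
_KELP_ORDERS = ["Fucales", "Laminariales", "Tilopteridales"]
_KELP_FAMILIES = ["Fucaceae", "Laminariaceae", "Phyllariaceae"]
_SEAGRASS_GENERA = ["Zostera", "Posidonia", "Halophila", "Cymodocea"]
_SEAGRASS_FAMILIES = ["Zosteraceae", "Posidoniaceae", "Hydrocharitaceae", "Cymodoceaceae"]

_KM_PER_DEG = math.pi * 6371.0 / 180.0


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and biology of the synthetic world.

    Defaults describe a 9°x9° coastal domain at 0.1° resolution with four
    1.4° islands, a 3x3 province tiling and a dozen species carrying two
    registered synonyms each. Surface light of 200 E·m⁻²·yr⁻¹ decaying 10%
    per cell with distance from shore puts the 50-unit photosynthetic
    threshold about 1.3° offshore, so both suitable and light-limited
    habitat exist in quantity.
    """

    seed: int = 0
    n_islands: int = 4
    island_size_deg: float = 1.4
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    cell_size_deg: float = 0.1
    n_cols: int = 90
    n_rows: int = 90
    light_surface_max: float = 200.0
    light_decay_per_cell: float = 0.10
    province_grid: tuple[int, int] = (3, 3)
    n_species: int = 12
    synonyms_per_species: int = 2

    def __post_init__(self) -> None:
        if min(self.n_islands, self.n_cols, self.n_rows, self.n_species,
               self.synonyms_per_species) < 0:
            raise ValueError("counts must be non-negative")
        pr, pc = self.province_grid
        if self.n_rows % pr or self.n_cols % pc:
            raise ValueError("province grid must tile the raster in whole cells")


@dataclass
class GroundTruth:
    """Per-record labels and their expected counts.

    Labels: ``clean``, ``on_land``, ``low_light``, ``out_of_range``,
    ``duplicate_of:<id>``, ``synonym_used``, ``no_range_info``. A
    ``synonym_used`` record is otherwise clean; its label tracks synonym
    aggregation rather than an error to be flagged.
    """

    labels: dict[str, str] = field(default_factory=dict)
    species_drawn: set[str] = field(default_factory=set)

    def counts(self) -> Counter:
        c: Counter = Counter()
        for lab in self.labels.values():
            c["duplicate" if lab.startswith("duplicate_of:") else lab] += 1
        return c

    def ids_with(self, label: str) -> set[str]:
        if label == "duplicate":
            return {i for i, l in self.labels.items() if l.startswith("duplicate_of:")}
        return {i for i, l in self.labels.items() if l == label}


def _rect_ring(x0: float, y0: float, x1: float, y1: float) -> list[tuple[float, float]]:
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)]


def _build_registry(cfg: WorldConfig) -> tuple[TaxonRegistry, list[str], str]:
    """Registry of cfg.n_species ranged species plus one extra species that
    deliberately lacks a known-range entry, each with synonyms."""
    reg = TaxonRegistry()
    names: list[str] = []
    next_id = 100001
    for i in range(cfg.n_species + 1):
        kelp = i % 2 == 0
        if kelp:
            genus = _KELP_GENERA[i % len(_KELP_GENERA)]
            order = _KELP_ORDERS[i % len(_KELP_ORDERS)]
            family = _KELP_FAMILIES[i % len(_KELP_FAMILIES)]
            kingdom, phylum, cls = "Chromista", "Ochrophyta", "Phaeophyceae"
        else:
            genus = _SEAGRASS_GENERA[i % len(_SEAGRASS_GENERA)]
            family = _SEAGRASS_FAMILIES[i % len(_SEAGRASS_FAMILIES)]
            order = "Alismatales"
            kingdom, phylum, cls = "Plantae", "Tracheophyta", "Magnoliopsida"
        name = f"{genus} simulatus{i:02d}"
        sp_id = next_id
        next_id += 1
        reg.add(TaxonRecord(
            aphiaID=sp_id, scientificName=name, status="accepted",
            acceptedAphiaID=sp_id, rank="Species", kingdom=kingdom, phylum=phylum,
            taxon_class=cls, taxon_order=order, family=family, genus=genus,
        ))
        for j in range(cfg.synonyms_per_species):
            reg.add(TaxonRecord(
                aphiaID=next_id, scientificName=f"{genus} obsoletus{i:02d}{chr(97 + j)}",
                status="unaccepted", acceptedAphiaID=sp_id, rank="Species",
                kingdom=kingdom, phylum=phylum, taxon_class=cls,
                taxon_order=order, family=family, genus=genus,
            ))
            next_id += 1
        names.append(name)
    reg.validate()
    # last species generated is the one with no range information
    return reg, names[:-1], names[-1]


def build_world(cfg: WorldConfig) -> World:
    """Build the complete synthetic World from a config.

    Islands are rectangles aligned to raster cell boundaries and placed
    without overlap (a placement failure after many attempts is fatal).
    Light decays multiplicatively with distance from the nearest shoreline
    on both sides of the coast, with deeper layers uniformly dimmer, so the
    layer maxima are ordered layer1 >= layer2 >= layer3 everywhere.
    Provinces tile the domain exactly; each ranged species gets a
    contiguous block of province IDs.
    """
    rng = np.random.default_rng(cfg.seed)
    cs = cfg.cell_size_deg
    island_cells = max(1, int(round(cfg.island_size_deg / cs)))

    # cell-aligned island placement, non-overlapping with a 2-cell moat
    islands: list[tuple[float, float, float, float]] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(islands) < cfg.n_islands:
        attempts += 1
        if attempts > 1000:
            raise ValueError(
                f"could not place {cfg.n_islands} islands of {island_cells} cells "
                f"in a {cfg.n_cols}x{cfg.n_rows} grid without overlap"
            )
        c0 = int(rng.integers(1, cfg.n_cols - island_cells - 1))
        r0 = int(rng.integers(1, cfg.n_rows - island_cells - 1))
        if any(abs(c0 - c) < island_cells + 2 and abs(r0 - r) < island_cells + 2
               for c, r in occupied):
            continue
        occupied.append((c0, r0))
        x0 = cfg.origin_lon + c0 * cs
        y0 = cfg.origin_lat + r0 * cs
        islands.append((x0, y0, x0 + island_cells * cs, y0 + island_cells * cs))
    land = PolygonSet([Polygon(outer=_rect_ring(*isl)) for isl in islands])

    # light: per-cell distance (in cells) to the nearest island edge
    cols = np.arange(cfg.n_cols)
    rows_s = np.arange(cfg.n_rows)  # south-to-north index
    cx = cfg.origin_lon + (cols + 0.5) * cs
    cy = cfg.origin_lat + (rows_s + 0.5) * cs
    gx, gy = np.meshgrid(cx, cy)  # (n_rows, n_cols), row 0 = southernmost
    d_deg = np.full(gx.shape, np.inf)
    inside_any = np.zeros(gx.shape, dtype=bool)
    for x0, y0, x1, y1 in islands:
        inside = (gx > x0) & (gx < x1) & (gy > y0) & (gy < y1)
        edge_in = np.minimum.reduce([gx - x0, x1 - gx, gy - y0, y1 - gy])
        dx = np.maximum.reduce([x0 - gx, np.zeros_like(gx), gx - x1])
        dy = np.maximum.reduce([y0 - gy, np.zeros_like(gy), gy - y1])
        edge_out = np.hypot(dx, dy)
        d_deg = np.minimum(d_deg, np.where(inside, edge_in, edge_out))
        inside_any |= inside
    d_cells = d_deg / cs
    base = cfg.light_surface_max * (1.0 - cfg.light_decay_per_cell) ** d_cells
    layers = [np.flipud(f * base) for f in _LAYER_FACTORS]  # row 0 = north
    light = LightRasterStack(xll=cfg.origin_lon, yll=cfg.origin_lat, cellsize=cs,
                             layers=layers)

    # provinces: exact rectangular tiling, IDs 1..rows*cols
    pr, pc = cfg.province_grid
    tile_w = cfg.n_cols // pc * cs
    tile_h = cfg.n_rows // pr * cs
    provs = []
    pid = 1
    for tr in range(pr):
        for tc in range(pc):
            x0 = cfg.origin_lon + tc * tile_w
            y0 = cfg.origin_lat + tr * tile_h
            provs.append(Polygon(outer=_rect_ring(x0, y0, x0 + tile_w, y0 + tile_h),
                                 attribute=pid))
            pid += 1
    provinces = PolygonSet(provs)

    registry, ranged_names, unranged_name = _build_registry(cfg)
    n_prov = pr * pc
    width = max(1, (n_prov + 1) // 2)
    ranges = KnownRangeTable()
    for i, name in enumerate(ranged_names):
        start = i % max(1, n_prov - width + 1)
        ranges.ranges[name] = set(range(start + 1, start + width + 1))
        ranges.citations[name] = f"synthetic range assignment, seed {cfg.seed}"

    gaz = Gazetteer()
    for k, (x0, y0, x1, y1) in enumerate(islands, start=1):
        gaz.entries[f"island {k} shore"] = (round(x0 - 0.5 * cs, 6), round((y0 + y1) / 2, 6), 500.0)

    return World(land=land, light=light, provinces=provinces, ranges=ranges,
                 registry=registry, gazetteer=gaz)


@dataclass
class _CellIndex:
    """Eligible cell pools with guard margins from every decision boundary."""

    suitable_by_prov: dict[int, list[tuple[float, float]]]
    land_by_prov: dict[int, list[tuple[float, float]]]
    lowlight_by_prov: dict[int, list[tuple[float, float]]]


def _index_cells(world: World, cfg: WorldConfig) -> _CellIndex:
    cs = cfg.cell_size_deg
    pr, pc = cfg.province_grid
    tiles_c = cfg.n_cols // pc
    tiles_r = cfg.n_rows // pr
    # reconstruct per-cell geometry from the stored raster (layer 1 is the
    # brightest, so the 3-layer max equals layer 1 here)
    top = world.light.layers[0]
    suit: dict[int, list] = {}
    landc: dict[int, list] = {}
    low: dict[int, list] = {}
    min_inland_km = 1.0 + 4.0  # shoreline tolerance + guard margin

    def shore_clearance_km(x: float, y: float) -> float:
        best = math.inf
        for poly in world.land.polygons:
            x0, y0, x1, y1 = poly.bbox
            if x0 < x < x1 and y0 < y < y1:
                dlon = min(x - x0, x1 - x) * _KM_PER_DEG * math.cos(math.radians(y))
                dlat = min(y - y0, y1 - y) * _KM_PER_DEG
                best = min(best, dlon, dlat)
        return best

    for r in range(cfg.n_rows):       # south-to-north
        for c in range(cfg.n_cols):
            x = cfg.origin_lon + (c + 0.5) * cs
            y = cfg.origin_lat + (r + 0.5) * cs
            v = top[cfg.n_rows - 1 - r, c]
            prov = (r // tiles_r) * pc + (c // tiles_c) + 1
            on_land = any(p0 < x < p1 and q0 < y < q1
                          for p0, q0, p1, q1 in (pl.bbox for pl in world.land.polygons))
            if on_land:
                if v >= 55.0 and shore_clearance_km(x, y) >= min_inland_km:
                    landc.setdefault(prov, []).append((x, y))
            elif v >= 55.0:
                suit.setdefault(prov, []).append((x, y))
            elif v <= 45.0:
                low.setdefault(prov, []).append((x, y))
    return _CellIndex(suit, landc, low)


def _round_counts(n: int, error_mix: dict[str, float]) -> dict[str, int]:
    counts = {lab: int(math.floor(n * p + 0.5)) for lab, p in error_mix.items()}
    total_err = sum(counts.values())
    if total_err > n:
        raise ValueError("error mix proportions exceed 1")
    counts["clean"] = n - total_err
    return counts


DEFAULT_ERROR_MIX: dict[str, float] = {
    "on_land": 0.10,
    "low_light": 0.10,
    "out_of_range": 0.10,
    "duplicate": 0.10,
    "synonym_used": 0.05,
    "no_range_info": 0.05,
}


def generate_records(
    world: World,
    n: int,
    error_mix: dict[str, float] | None = None,
    seed: int = 0,
    cfg: WorldConfig | None = None,
) -> tuple[RecordSet, GroundTruth]:
    """Generate ``n`` records with exact per-label ground-truth counts.

    Label counts are round(n x proportion) with the remainder clean.
    Placements keep guard margins from every decision boundary, so the
    pipeline (standardize -> dedup -> flags) recovers each label set
    exactly. Duplicates are field-for-field copies (fresh id) of earlier
    clean records and are appended after all originals, so keep-first
    deduplication removes exactly the duplicates. Raises if the world
    offers no feasible placement for a requested label.
    """
    cfg = cfg or WorldConfig()
    error_mix = DEFAULT_ERROR_MIX if error_mix is None else error_mix
    rng = np.random.default_rng(seed)
    counts = _round_counts(n, error_mix)
    gt = GroundTruth()
    rs = RecordSet()
    if n == 0:
        rs.log("generate: 0 records")
        return rs, gt

    cells = _index_cells(world, cfg)
    reg = world.registry
    assert reg is not None
    accepted = [t for t in reg.by_id.values() if t.status == "accepted"]
    ranged = [t for t in accepted if t.scientificName in world.ranges]
    unranged = [t for t in accepted if t.scientificName not in world.ranges]
    synonyms_of: dict[str, list[TaxonRecord]] = {}
    for t in reg.by_id.values():
        if t.status == "unaccepted":
            acc = reg.resolve_id(t.aphiaID)
            synonyms_of.setdefault(acc.scientificName, []).append(t)

    jitter = 0.2 * cfg.cell_size_deg
    used_keys: set = set()
    records: list[OccurrenceRecord] = []
    seq = 0

    def _pick_cell(pools: dict[int, list], prov_ok) -> tuple[float, float, int]:
        provs = [p for p in pools if prov_ok(p) and pools[p]]
        if not provs:
            raise ValueError("no feasible placement for requested label in this world")
        p = provs[int(rng.integers(len(provs)))]
        x, y = pools[p][int(rng.integers(len(pools[p])))]
        return x, y, p

    def _emit(label: str, taxon: TaxonRecord, name: str, x: float, y: float) -> OccurrenceRecord:
        nonlocal seq
        seq += 1
        for _ in range(100):
            lon = round(x + float(rng.uniform(-jitter, jitter)), 6)
            lat = round(y + float(rng.uniform(-jitter, jitter)), 6)
            year = int(rng.integers(1980, 2019))
            month = int(rng.integers(1, 13))
            day = int(rng.integers(1, 29))
            depth = round(float(rng.uniform(0.5, 30.0)), 1) if rng.random() < 0.6 else None
            key = (taxon.aphiaID, lon, lat, depth, year, month, day)
            if key not in used_keys:
                used_keys.add(key)
                break
        else:  # pragma: no cover - jitter collisions are vanishingly rare
            raise RuntimeError("could not draw a unique record key")
        rec = OccurrenceRecord(
            id=f"SYN-{seq:06d}",
            name=name,
            decimalLongitude=lon,
            decimalLatitude=lat,
            coordinateUncertaintyInMeters=float(rng.integers(10, 1000)),
            verbatimDepth=depth,
            year=year, month=month, day=day,
            sourceType=["literature", "herbaria", "repositories"][int(rng.integers(3))],
            bibliographicCitation=f"Synthetic source {int(rng.integers(1, 50))}",
        )
        records.append(rec)
        gt.labels[rec.id] = label
        gt.species_drawn.add(taxon.scientificName)
        return rec

    def _ranged_species_for(prov: int, inside: bool) -> TaxonRecord:
        pool = [t for t in ranged if (prov in world.ranges.ranges[t.scientificName]) == inside]
        if not pool:
            raise ValueError("no species with a compatible range for this province")
        return pool[int(rng.integers(len(pool)))]

    order = (["clean"] * counts["clean"]
             + ["synonym_used"] * counts.get("synonym_used", 0)
             + ["on_land"] * counts.get("on_land", 0)
             + ["low_light"] * counts.get("low_light", 0)
             + ["out_of_range"] * counts.get("out_of_range", 0)
             + ["no_range_info"] * counts.get("no_range_info", 0))
    rng.shuffle(order)

    for label in order:
        if label in ("clean", "synonym_used"):
            x, y, prov = _pick_cell(cells.suitable_by_prov, lambda p: True)
            taxon = _ranged_species_for(prov, inside=True)
            if label == "synonym_used":
                syns = synonyms_of.get(taxon.scientificName)
                if not syns:
                    raise ValueError(f"species {taxon.scientificName} has no registered synonym")
                name = syns[int(rng.integers(len(syns)))].scientificName
            else:
                name = taxon.scientificName
            _emit(label, taxon, name, x, y)
        elif label == "on_land":
            x, y, prov = _pick_cell(cells.land_by_prov, lambda p: True)
            taxon = _ranged_species_for(prov, inside=True)
            _emit(label, taxon, taxon.scientificName, x, y)
        elif label == "low_light":
            x, y, prov = _pick_cell(cells.lowlight_by_prov, lambda p: True)
            taxon = _ranged_species_for(prov, inside=True)
            _emit(label, taxon, taxon.scientificName, x, y)
        elif label == "out_of_range":
            x, y, prov = _pick_cell(
                cells.suitable_by_prov,
                lambda p: any(p not in world.ranges.ranges[t.scientificName] for t in ranged),
            )
            taxon = _ranged_species_for(prov, inside=False)
            _emit(label, taxon, taxon.scientificName, x, y)
        elif label == "no_range_info":
            if not unranged:
                raise ValueError("world has no species lacking range information")
            x, y, prov = _pick_cell(cells.suitable_by_prov, lambda p: True)
            taxon = unranged[int(rng.integers(len(unranged)))]
            _emit(label, taxon, taxon.scientificName, x, y)

    # duplicates: exact copies (fresh id) of earlier non-duplicate clean records
    originals = [r for r in records if gt.labels[r.id] in ("clean", "synonym_used")]
    n_dup = counts.get("duplicate", 0)
    if n_dup and not originals:
        raise ValueError("cannot generate duplicates without any clean record")
    for _ in range(n_dup):
        src = originals[int(rng.integers(len(originals)))]
        seq += 1
        dup = OccurrenceRecord(**{
            **{f: getattr(src, f) for f in (
                "name", "decimalLongitude", "decimalLatitude",
                "coordinateUncertaintyInMeters", "verbatimDepth",
                "minimumDepthInMeters", "maximumDepthInMeters",
                "year", "month", "day", "country", "locality", "sourceType",
                "bibliographicCitation", "bibliographicCitationDOI",
            )},
            "id": f"SYN-{seq:06d}",
        })
        records.append(dup)
        gt.labels[dup.id] = f"duplicate_of:{src.id}"

    rs = RecordSet(records=records)
    rs.log(f"generate: {len(records)} records, seed {seed}")
    return rs, gt
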