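"""The three-part quality-flagging system for marine-forest occurrences.

Three independent checks annotate (never silently delete, with one
documented exception) each georeferenced record:

* **on land** — the point falls inside a landmass polygon more than a
  shoreline tolerance (default 1 km) from the coast. The tolerance absorbs
  the limited spatial resolution of coastline polygons, so records just
  inside a coarse coastline are not penalized.
* **unsuitable light** — the maximum benthic light over the three depth
  layers at the record's cell is strictly below the photosynthetic limit
  for marine forests (default 50 E·m⁻²·yr⁻¹). Holopelagic *Sargassum*
  species that complete their life cycle afloat are exempt.
* **outside known distribution** — the record falls in a marine province
  not listed in the species' curated known range. Species with no range
  information at all are removed (the one deletion): without literature
  support there is no baseline to flag against.

Flags are independent; a record may carry one, two or all three. Records
whose province cannot be determined (offshore beyond province coverage)
keep the distribution flag unevaluated — absence of a province is not
evidence of a range error.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dwc_core import Flag, OccurrenceRecord, RecordSet
from .geospatial import (
    GeoPoint,
    LightRasterStack,
    PolygonSet,
    ShorelineDistance,
    locate_province,
    point_in_polygon,
    sample_light_max,
)

#: Brown algae able to complete a full life cycle floating at the surface;
#: benthic light does not constrain them.
HOLOPELAGIC_SARGASSUM = frozenset(
    {"Sargassum fluitans", "Sargassum natans", "Sargassum pusillum"}
)


@dataclass(frozen=True)
class QCConfig:
    """Tunable thresholds of the flagging system.

    shoreline_threshold_km: tolerated distance inland before a record is
        called on-land; matches the spatial resolution of the landmass
        polygons (1 km for OpenStreetMap-derived coastlines).
    light_threshold: minimum annual benthic light dose (E·m⁻²·yr⁻¹)
        compatible with marine-forest photosynthesis; strictly-below is
        flagged.
    exempt_species: accepted species names never light-flagged.
    """

    shoreline_threshold_km: float = 1.0
    light_threshold: float = 50.0
    exempt_species: frozenset[str] = HOLOPELAGIC_SARGASSUM

    def __post_init__(self) -> None:
        if self.shoreline_threshold_km <= 0 or self.light_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "QCConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        if "shoreline_threshold_km" in data:
            kwargs["shoreline_threshold_km"] = float(data["shoreline_threshold_km"])
        if "light_threshold" in data:
            kwargs["light_threshold"] = float(data["light_threshold"])
        if "exempt_species" in data:
            kwargs["exempt_species"] = frozenset(data["exempt_species"])
        return cls(**kwargs)


@dataclass
class KnownRangeTable:
    """Curated known distribution per species, as sets of province IDs.

    A species mapped to an empty set is distinct from a species absent from
    the table: the former has (vacuous) range information, the latter has
    none and its records are removed.
    """

    ranges: dict[str, set] = field(default_factory=dict)
    citations: dict[str, str] = field(default_factory=dict)

    def __contains__(self, species: str) -> bool:
        return species in self.ranges

    @classmethod
    def from_csv(cls, path: str | Path) -> "KnownRangeTable":
        """Load a (species, province_id, citation) CSV; one row per
        species-province pair."""
        ranges: dict[str, set] = {}
        citations: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                sp = row["species"].strip()
                ranges.setdefault(sp, set())
                pid = (row.get("province_id") or "").strip()
                if pid:
                    ranges[sp].add(int(pid) if pid.lstrip("-").isdigit() else pid)
                if row.get("citation"):
                    citations[sp] = row["citation"]
        return cls(ranges, citations)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["species", "province_id", "citation"])
            for sp, pids in self.ranges.items():
                cite = self.citations.get(sp, "")
                if not pids:
                    w.writerow([sp, "", cite])
                for pid in sorted(pids, key=str):
                    w.writerow([sp, pid, cite])
        return path


def flag_on_land(
    r: OccurrenceRecord,
    land: PolygonSet,
    cfg: QCConfig | None = None,
    shoreline_distance: ShorelineDistance | None = None,
) -> Flag:
    """Flag records inside a land polygon beyond the shoreline tolerance.

    A cached :class:`ShorelineDistance` may be supplied when flagging many
    records against the same landmass.
    """
    cfg = cfg or QCConfig()
    if not r.has_coordinates():
        return Flag.UNEVALUATED
    p = GeoPoint(r.decimalLongitude, r.decimalLatitude)
    if not any(point_in_polygon(p, poly) for poly in land.polygons):
        return Flag.CLEAR
    dist = shoreline_distance(p) if shoreline_distance else ShorelineDistance(land)(p)
    return Flag.FLAGGED if dist > cfg.shoreline_threshold_km else Flag.CLEAR


def flag_unsuitable_light(
    r: OccurrenceRecord, stack: LightRasterStack, cfg: QCConfig | None = None
) -> Flag:
    """Flag records where the 3-layer maximum benthic light is strictly
    below the photosynthetic threshold; exempt species are never flagged."""
    cfg = cfg or QCConfig()
    if not r.has_coordinates():
        return Flag.UNEVALUATED
    if (r.acceptedName or r.name) in cfg.exempt_species:
        return Flag.CLEAR
    light = sample_light_max(GeoPoint(r.decimalLongitude, r.decimalLatitude), stack)
    if light is None:
        return Flag.UNEVALUATED
    return Flag.FLAGGED if light < cfg.light_threshold else Flag.CLEAR


REMOVE = "remove"


def flag_outside_distribution(
    r: OccurrenceRecord, provinces: PolygonSet, ranges: KnownRangeTable
) -> Flag | str:
    """Compare the record's province against the species' known range.

    Returns a Flag, or the sentinel ``REMOVE`` for species absent from the
    range table altogether.
    """
    species = r.acceptedName or r.name
    if species is None or not r.has_coordinates():
        return Flag.UNEVALUATED
    if species not in ranges:
        return REMOVE
    prov = locate_province(GeoPoint(r.decimalLongitude, r.decimalLatitude), provinces)
    if prov is None:
        return Flag.UNEVALUATED
    return Flag.CLEAR if prov in ranges.ranges[species] else Flag.FLAGGED


def apply_flags(
    rs: RecordSet,
    land: PolygonSet,
    stack: LightRasterStack,
    provinces: PolygonSet,
    ranges: KnownRangeTable,
    cfg: QCConfig | None = None,
) -> RecordSet:
    """Evaluate all three flags on every record.

    Records of species with no known-range information are removed with a
    count; all other records are kept with their flags set. Each flag is
    computed from its own inputs only, so a record may carry any subset of
    the three.
    """
    cfg = cfg or QCConfig()
    shoredist = ShorelineDistance(land)
    kept: list[OccurrenceRecord] = []
    removed_no_info = 0
    for r in rs.records:
        dist_result = flag_outside_distribution(r, provinces, ranges)
        if dist_result == REMOVE:
            removed_no_info += 1
            continue
        r.flag_on_land = flag_on_land(r, land, cfg, shoreline_distance=shoredist)
        r.flag_unsuitable_light = flag_unsuitable_light(r, stack, cfg)
        r.flag_outside_distribution = dist_result
        for attr, label in [
            ("flag_on_land", "on-land"),
            ("flag_unsuitable_light", "light"),
            ("flag_outside_distribution", "distribution"),
        ]:
            if getattr(r, attr) is Flag.UNEVALUATED:
                r.append_note(f"{label} flag not evaluated")
        kept.append(r)
    n_land = sum(1 for r in kept if r.flag_on_land is Flag.FLAGGED)
    n_light = sum(1 for r in kept if r.flag_unsuitable_light is Flag.FLAGGED)
    n_dist = sum(1 for r in kept if r.flag_outside_distribution is Flag.FLAGGED)
    return rs.derive(
        kept,
        f"flags: {removed_no_info} removed (no range information); "
        f"flagged on-land {n_land}, unsuitable-light {n_light}, outside-distribution {n_dist}",
    )
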