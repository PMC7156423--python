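"""Geospatial context bundle for a quality-control run.

A :class:`World` gathers everything the flagging system needs besides the
records themselves: landmass polygons, the 3-layer benthic light raster,
province polygons, the curated known-range table, and a gazetteer for
geocoding. It can be loaded from user-supplied files (GeoJSON, ASCII grids,
CSV) or built synthetically (see :mod:`marineqc.synthetic_world`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .dwc_core import Gazetteer
from .geospatial import LightRasterStack, PolygonSet
from .qcflags import KnownRangeTable
from .taxonomy import TaxonRegistry, load_registry


@dataclass
class World:
    land: PolygonSet
    light: LightRasterStack
    provinces: PolygonSet
    ranges: KnownRangeTable
    registry: TaxonRegistry | None = None
    gazetteer: Gazetteer = field(default_factory=Gazetteer)


def load_world(
    land_path: str | Path,
    light_paths: Sequence[str | Path],
    provinces_path: str | Path,
    ranges_path: str | Path,
    registry_path: str | Path | None = None,
    gazetteer_path: str | Path | None = None,
) -> World:
    """Assemble a World from files on disk."""
    return World(
        land=PolygonSet.from_geojson(land_path),
        light=LightRasterStack.from_ascii_grids(list(light_paths)),
        provinces=PolygonSet.from_geojson(provinces_path, attribute_property="province_id"),
        ranges=KnownRangeTable.from_csv(ranges_path),
        registry=load_registry(registry_path) if registry_path else None,
        gazetteer=Gazetteer.from_csv(gazetteer_path) if gazetteer_path else Gazetteer(),
    )
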