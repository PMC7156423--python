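"""Summary tables and geospatial export.

The record-level summary mirrors the dataset's headline table: counts and
percentages of flagged records per ecological group (kelp/fucoid algae,
seagrasses) and original source type (literature, herbaria, repositories),
with flagged percentages taken over the overall count of the same
group x source cell. A species-level variant counts species with at least
one flagged record; its denominator is the number of species observed in
that group x source cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .dwc_core import COLUMNS, Flag, OccurrenceRecord, RecordSet, _COLUMN_TO_FIELD, _FLAG_COLUMNS
from .taxonomy import EcologicalGroup, GroupScheme, assign_group

GROUPS = ["kelp_fucoid", "seagrass"]
SOURCES = ["literature", "herbaria", "repositories"]
METRICS = ["overall", "flagged_on_land", "flagged_light", "flagged_distribution"]

_METRIC_ATTR = {
    "flagged_on_land": "flag_on_land",
    "flagged_light": "flag_unsuitable_light",
    "flagged_distribution": "flag_outside_distribution",
}


def round_percentage(count: int, denom: int) -> float:
    """Percentage to 2 decimals, half-up; 0 when the denominator is 0."""
    if denom == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(denom)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SummaryReport:
    """Counts and percentages keyed by (group, source, metric).

    ``records`` holds the record-level table, ``species`` the species-level
    one. Both include ``total`` rows/columns that are exact sums of their
    parts; percentages always recompute from the stored counts.
    """

    records: dict[tuple[str, str, str], int] = field(default_factory=dict)
    species: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def count(self, group: str, source: str, metric: str, table: str = "records") -> int:
        return getattr(self, table).get((group, source, metric), 0)

    def percentage(self, group: str, source: str, metric: str, table: str = "records") -> float:
        t = getattr(self, table)
        return round_percentage(
            t.get((group, source, metric), 0), t.get((group, source, "overall"), 0)
        )

    def _frame(self, table: str) -> pd.DataFrame:
        t = getattr(self, table)
        groups = [g for g in GROUPS + ["none"] if any(k[0] == g for k in t)] + ["total"]
        rows = []
        for g in groups:
            for m in METRICS:
                row = {"group": g, "metric": m}
                for s in SOURCES + ["total"]:
                    c = t.get((g, s, m), 0)
                    if m == "overall":
                        row[s] = str(c)
                    else:
                        row[s] = f"{c} ({self.percentage(g, s, m, table):.2f})"
                rows.append(row)
        return pd.DataFrame(rows)

    def to_dataframe(self, table: str = "records") -> pd.DataFrame:
        return self._frame(table)

    def __str__(self) -> str:
        return (
            "Records\n" + self._frame("records").to_string(index=False)
            + "\n\nSpecies\n" + self._frame("species").to_string(index=False)
        )


def _group_of(r: OccurrenceRecord, gs: GroupScheme) -> str:
    return assign_group(r, gs).value if assign_group(r, gs) is not EcologicalGroup.NONE else "none"


def summarize(rs: RecordSet, gs: GroupScheme | None = None) -> SummaryReport:
    """Build record- and species-level flag summaries.

    Requires evaluated flags and populated taxonomic hierarchies (groups are
    assigned from order/family). Records whose source type is missing are
    counted only in the ``total`` source column.
    """
    gs = gs or GroupScheme()
    rep = SummaryReport()
    species_seen: dict[tuple[str, str, str], set] = {}
    for r in rs.records:
        g = _group_of(r, gs)
        s = r.sourceType if r.sourceType in SOURCES else None
        sp = r.acceptedName or r.name or "?"
        cells = [(g, s), (g, "total"), ("total", s), ("total", "total")]
        cells = [(cg, cr) for cg, cr in cells if cr is not None]
        for cg, cr in cells:
            rep.records[(cg, cr, "overall")] = rep.records.get((cg, cr, "overall"), 0) + 1
            species_seen.setdefault((cg, cr, "overall"), set()).add(sp)
            for metric, attr in _METRIC_ATTR.items():
                if getattr(r, attr) is Flag.FLAGGED:
                    rep.records[(cg, cr, metric)] = rep.records.get((cg, cr, metric), 0) + 1
                    species_seen.setdefault((cg, cr, metric), set()).add(sp)
    rep.species = {k: len(v) for k, v in species_seen.items()}
    return rep


def export_geojson(rs: RecordSet, path: str | Path) -> Path:
    """Write records as a GeoJSON FeatureCollection of Point features.

    Coordinates are [longitude, latitude]; every Darwin Core field is
    carried as a feature property (flags in the -1/empty convention).
    Records without coordinates are skipped with a count in provenance.
    """
    feats = []
    skipped = 0
    for r in rs.records:
        if not r.has_coordinates():
            skipped += 1
            continue
        props: dict = {}
        for col in COLUMNS:
            if col in _FLAG_COLUMNS:
                flag = getattr(r, _FLAG_COLUMNS[col])
                props[col] = "-1" if flag is Flag.FLAGGED else ""
            else:
                v = getattr(r, _COLUMN_TO_FIELD.get(col, col))
                if v is not None:
                    props[col] = v
        props.update(r.extras)
        feats.append({
            "type": "Feature",
            "properties": props,
            "geometry": {"type": "Point",
                         "coordinates": [r.decimalLongitude, r.decimalLatitude]},
        })
    rs.log(f"export_geojson: {len(feats)} features, {skipped} skipped (no coordinates)")
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}),
                    encoding="utf-8")
    return path
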