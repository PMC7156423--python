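"""Darwin-Core-style occurrence records: model, CSV I/O, geocoding,
deduplication and pruning.

The record schema follows the Darwin Core terms used by the marine-forest
occurrence dataset (decimalLongitude, verbatimDepth, sourceType, ...) plus
three quality flags. Flags are tri-state in memory (flagged / clear /
unevaluated) and serialize to the dataset convention: ``-1`` for flagged,
empty for clear; a flag column that was never evaluated for any record is
omitted entirely so the tri-state survives a round trip.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable, Iterable, Iterator


class Flag(enum.Enum):
    """Tri-state quality flag."""

    FLAGGED = "flagged"
    CLEAR = "clear"
    UNEVALUATED = "unevaluated"


SOURCE_TYPES = {"literature", "herbaria", "repositories"}

#: Canonical column order for tabular output (Darwin Core terms).
COLUMNS = [
    "id",
    "aphiaID",
    "acceptedAphiaID",
    "name",
    "acceptedName",
    "taxonomicStatus",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "decimalLongitude",
    "decimalLatitude",
    "coordinateUncertaintyInMeters",
    "verbatimDepth",
    "minimumDepthInMeters",
    "maximumDepthInMeters",
    "year",
    "month",
    "day",
    "country",
    "locality",
    "sourceType",
    "bibliographicCitation",
    "bibliographicCitationDOI",
    "flagHumanCuratedDistribution",
    "flagMachineOnLand",
    "flagMachineSuitableLightBottom",
    "recordNotes",
]

_FLAG_COLUMNS = {
    "flagMachineOnLand": "flag_on_land",
    "flagMachineSuitableLightBottom": "flag_unsuitable_light",
    "flagHumanCuratedDistribution": "flag_outside_distribution",
}

# 'class' and 'order' are Python keywords / builtins shadowers; the dataclass
# uses taxon_class / taxon_order internally and maps on I/O.
_FIELD_TO_COLUMN = {"taxon_class": "class", "taxon_order": "order"}
_COLUMN_TO_FIELD = {v: k for k, v in _FIELD_TO_COLUMN.items()}


@dataclass
class OccurrenceRecord:
    """A single occurrence with taxonomy links, location, date and flags."""

    id: str
    name: str | None = None
    aphiaID: int | None = None
    acceptedAphiaID: int | None = None
    acceptedName: str | None = None
    taxonomicStatus: str | None = None
    kingdom: str | None = None
    phylum: str | None = None
    taxon_class: str | None = None
    taxon_order: str | None = None
    family: str | None = None
    genus: str | None = None
    decimalLongitude: float | None = None
    decimalLatitude: float | None = None
    coordinateUncertaintyInMeters: float | None = None
    verbatimDepth: float | None = None
    minimumDepthInMeters: float | None = None
    maximumDepthInMeters: float | None = None
    year: int | None = None
    month: int | None = None
    day: int | None = None
    country: str | None = None
    locality: str | None = None
    sourceType: str | None = None
    bibliographicCitation: str | None = None
    bibliographicCitationDOI: str | None = None
    flag_on_land: Flag = Flag.UNEVALUATED
    flag_unsuitable_light: Flag = Flag.UNEVALUATED
    flag_outside_distribution: Flag = Flag.UNEVALUATED
    recordNotes: str | None = None
    extras: dict[str, str] = field(default_factory=dict)

    def has_coordinates(self) -> bool:
        return self.decimalLongitude is not None and self.decimalLatitude is not None

    def validate(self) -> list[str]:
        """Invariant violations as human-readable strings (empty = valid)."""
        problems = []
        if self.decimalLongitude is not None and not -180.0 <= self.decimalLongitude <= 180.0:
            problems.append(f"decimalLongitude {self.decimalLongitude} outside [-180, 180]")
        if self.decimalLatitude is not None and not -90.0 <= self.decimalLatitude <= 90.0:
            problems.append(f"decimalLatitude {self.decimalLatitude} outside [-90, 90]")
        if self.coordinateUncertaintyInMeters is not None and self.coordinateUncertaintyInMeters < 0:
            problems.append("negative coordinateUncertaintyInMeters")
        if self.month is not None and not 1 <= self.month <= 12:
            problems.append(f"month {self.month} outside [1, 12]")
        if self.day is not None and not 1 <= self.day <= 31:
            problems.append(f"day {self.day} outside [1, 31]")
        if self.year is not None and not 1000 <= self.year <= 9999:
            problems.append(f"year {self.year} is not a 4-digit year")
        if self.day is not None and self.month is None:
            problems.append("day given without month")
        if self.month is not None and self.year is None:
            problems.append("month given without year")
        if self.sourceType is not None and self.sourceType not in SOURCE_TYPES:
            problems.append(f"sourceType {self.sourceType!r} not in {sorted(SOURCE_TYPES)}")
        return problems

    def flags(self) -> tuple[Flag, Flag, Flag]:
        return (self.flag_on_land, self.flag_unsuitable_light, self.flag_outside_distribution)

    def is_flagged(self) -> bool:
        return Flag.FLAGGED in self.flags()

    def all_clear(self) -> bool:
        return all(f is Flag.CLEAR for f in self.flags())

    def append_note(self, note: str) -> None:
        self.recordNotes = note if not self.recordNotes else f"{self.recordNotes}; {note}"


@dataclass
class RecordSet:
    """An ordered collection of occurrence records with a provenance log.

    Every destructive operation appends a provenance entry carrying its
    removal count, so counts across a pipeline run always reconcile:
    sum of removals = |input| - |output|.
    """

    records: list[OccurrenceRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids within RecordSet")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[OccurrenceRecord]:
        return iter(self.records)

    def log(self, entry: str) -> None:
        self.provenance.append(entry)

    def removed_total(self) -> int:
        """Sum of the removal counts recorded in provenance."""
        total = 0
        for entry in self.provenance:
            m = re.search(r"(\d+) (?:dropped|removed)", entry)
            if m:
                total += int(m.group(1))
        return total

    def derive(self, records: list[OccurrenceRecord], entry: str) -> "RecordSet":
        rs = RecordSet(records=records, provenance=list(self.provenance))
        rs.log(entry)
        return rs


@dataclass
class Gazetteer:
    """Locality-name -> coordinate lookup used to geocode records that lack
    coordinates but carry a textual locality (a local stand-in for a live
    geocoding service)."""

    entries: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    @staticmethod
    def normalize(locality: str) -> str:
        return re.sub(r"\s+", " ", locality.strip().lower())

    def lookup(self, locality: str | None, country: str | None = None):
        if locality is None:
            return None
        hit = self.entries.get(self.normalize(locality))
        if hit is None and country:
            hit = self.entries.get(self.normalize(f"{locality}, {country}"))
        return hit

    @classmethod
    def from_csv(cls, path: str | Path) -> "Gazetteer":
        entries = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                lon = float(row["longitude"])
                lat = float(row["latitude"])
                unc = float(row.get("uncertainty_m") or 0.0)
                if not (-180 <= lon <= 180 and -90 <= lat <= 90) or unc < 0:
                    raise ValueError(f"{path}: invalid gazetteer entry {row}")
                entries[cls.normalize(row["locality"])] = (lon, lat, unc)
        return cls(entries)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["locality", "longitude", "latitude", "uncertainty_m"])
            for loc, (lon, lat, unc) in self.entries.items():
                w.writerow([loc, repr(lon), repr(lat), repr(unc)])
        return path


def _parse_float(s: str | None) -> float | None:
    if s is None or s.strip() == "":
        return None
    return float(s)


def _parse_int(s: str | None) -> int | None:
    if s is None or s.strip() == "":
        return None
    return int(float(s))


def _parse_str(s: str | None) -> str | None:
    if s is None or s.strip() == "":
        return None
    return s


def _parse_flag(s: str | None) -> Flag:
    if s is None:
        return Flag.UNEVALUATED
    s = s.strip().replace("−", "-")  # unicode minus
    if s == "-1":
        return Flag.FLAGGED
    if s == "":
        return Flag.CLEAR
    raise ValueError(f"invalid flag value {s!r} (expected -1 or empty)")


_PARSERS: dict[str, Callable] = {
    "aphiaID": _parse_int,
    "acceptedAphiaID": _parse_int,
    "decimalLongitude": _parse_float,
    "decimalLatitude": _parse_float,
    "coordinateUncertaintyInMeters": _parse_float,
    "verbatimDepth": _parse_float,
    "minimumDepthInMeters": _parse_float,
    "maximumDepthInMeters": _parse_float,
    "year": _parse_int,
    "month": _parse_int,
    "day": _parse_int,
}


def read_records(path: str | Path, delimiter: str = ",") -> RecordSet:
    """Read occurrence records from a delimited text file.

    Rows that violate type invariants (coordinates out of range, bad dates,
    unparseable numbers) are excluded and counted in provenance rather than
    repaired. Flag columns holding ``-1`` map to flagged, empty to clear; a
    flag column absent from the header leaves that flag unevaluated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    known = set(COLUMNS)
    record_fields = {f.name for f in dc_fields(OccurrenceRecord)}
    records: list[OccurrenceRecord] = []
    dropped = 0
    seen_ids: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        if "name" not in reader.fieldnames and "acceptedName" not in reader.fieldnames:
            raise ValueError(f"{path}: schema error, need at least one of 'name'/'acceptedName'")
        for i, row in enumerate(reader):
            try:
                kwargs: dict = {"extras": {}}
                for col, raw in row.items():
                    if col is None:
                        raise ValueError("row has more fields than the header")
                    if col in _FLAG_COLUMNS:
                        kwargs[_FLAG_COLUMNS[col]] = _parse_flag(raw)
                    elif col in known:
                        fieldname = _COLUMN_TO_FIELD.get(col, col)
                        parser = _PARSERS.get(col, _parse_str)
                        kwargs[fieldname] = parser(raw)
                    else:
                        kwargs["extras"][col] = raw if raw is not None else ""
                if not kwargs.get("id"):
                    kwargs["id"] = f"row-{i + 1}"
                if kwargs["id"] in seen_ids:
                    raise ValueError(f"duplicate id {kwargs['id']}")
                rec = OccurrenceRecord(**{k: v for k, v in kwargs.items() if k in record_fields})
                if rec.validate():
                    raise ValueError("; ".join(rec.validate()))
                seen_ids.add(rec.id)
                records.append(rec)
            except (ValueError, TypeError):
                dropped += 1
    rs = RecordSet(records=records)
    rs.log(f"read {path.name}: {len(records)} kept, {dropped} dropped")
    return rs


def _format_value(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_records(rs: RecordSet, path: str | Path, pruned: bool = False, delimiter: str = ",") -> Path:
    """Write a RecordSet as delimited text with Darwin Core column names.

    ``pruned=True`` writes only records with all three flags clear. Flags
    serialize as ``-1`` / empty; a flag left unevaluated on every record has
    its column omitted so it reads back as unevaluated.
    """
    path = Path(path)
    records = [r for r in rs.records if r.all_clear()] if pruned else rs.records
    flag_cols = [
        col
        for col, attr in _FLAG_COLUMNS.items()
        if any(getattr(r, attr) is not Flag.UNEVALUATED for r in records)
    ]
    extra_cols: list[str] = []
    for r in records:
        for k in r.extras:
            if k not in extra_cols:
                extra_cols.append(k)
    cols = [c for c in COLUMNS if c not in _FLAG_COLUMNS or c in flag_cols] + extra_cols
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(cols)
        for r in records:
            row = []
            for col in cols:
                if col in _FLAG_COLUMNS:
                    flag = getattr(r, _FLAG_COLUMNS[col])
                    row.append("-1" if flag is Flag.FLAGGED else "")
                elif col in extra_cols:
                    row.append(r.extras.get(col, ""))
                else:
                    row.append(_format_value(getattr(r, _COLUMN_TO_FIELD.get(col, col))))
            w.writerow(row)
    return path


def geocode_records(rs: RecordSet, gaz: Gazetteer) -> RecordSet:
    """Fill coordinates from the gazetteer for records lacking them.

    Records with coordinates pass through untouched. Records without
    coordinates whose locality matches a gazetteer entry get coordinates and
    an uncertainty plus a note; unmatched coordinate-less records are removed
    (they cannot enter any geographic quality check).
    """
    kept: list[OccurrenceRecord] = []
    geocoded = 0
    removed = 0
    for r in rs.records:
        if r.has_coordinates():
            kept.append(r)
            continue
        hit = gaz.lookup(r.locality, r.country)
        if hit is None:
            removed += 1
            continue
        lon, lat, unc = hit
        r.decimalLongitude = lon
        r.decimalLatitude = lat
        r.coordinateUncertaintyInMeters = unc
        r.append_note("coordinates geocoded from gazetteer locality")
        geocoded += 1
        kept.append(r)
    return rs.derive(kept, f"geocode: {geocoded} geocoded, {removed} removed (no coordinates)")


def _depth_key(r: OccurrenceRecord):
    # verbatim depth is the least-processed depth value; fall back to the
    # (min, max) pair when it is absent
    if r.verbatimDepth is not None:
        return ("v", r.verbatimDepth)
    return ("mm", r.minimumDepthInMeters, r.maximumDepthInMeters)


def duplicate_key(r: OccurrenceRecord):
    """Key under which two records are considered the same observation:
    same taxon, same exact location (longitude, latitude, depth) and same
    date (year, month, day); absent compares equal to absent."""
    taxon = r.acceptedAphiaID if r.acceptedAphiaID is not None else ("name", (r.name or "").strip().lower())
    return (taxon, r.decimalLongitude, r.decimalLatitude, _depth_key(r), r.year, r.month, r.day)


def dedup_records(rs: RecordSet) -> RecordSet:
    """Drop exact duplicates, keeping the first record in input order."""
    seen: set = set()
    kept = []
    removed = 0
    for r in rs.records:
        k = duplicate_key(r)
        if k in seen:
            removed += 1
            continue
        seen.add(k)
        kept.append(r)
    return rs.derive(kept, f"dedup: {len(kept)} kept, {removed} removed")


def prune_records(rs: RecordSet) -> RecordSet:
    """Keep only records with all three quality flags clear.

    Pruning before every flag has been evaluated is a pipeline error."""
    for r in rs.records:
        if Flag.UNEVALUATED in r.flags():
            raise ValueError(
                f"record {r.id} has an unevaluated flag; run the flagging step before pruning"
            )
    kept = [r for r in rs.records if r.all_clear()]
    removed = len(rs.records) - len(kept)
    return rs.derive(kept, f"prune: {len(kept)} kept, {removed} removed (>=1 flag)")
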