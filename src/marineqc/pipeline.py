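"""End-to-end quality-control pipeline.

Stage order follows the data-treatment workflow: taxonomic
standardization, geocoding of coordinate-less records, exact-duplicate
removal, then the three-flag evaluation (which also removes records of
species with no known-range information). Every stage appends its removal
counts to the RecordSet provenance, so |input| - |output| always equals
the sum of logged removals.
"""

from __future__ import annotations

from .dwc_core import RecordSet, dedup_records, geocode_records, prune_records
from .qcflags import QCConfig, apply_flags
from .taxonomy import standardize_records
from .world import World


def run_pipeline(
    rs: RecordSet,
    world: World,
    cfg: QCConfig | None = None,
    prune: bool = False,
) -> RecordSet:
    """Standardize, geocode, deduplicate and flag a record set.

    With ``prune=True`` the result keeps only records with all three flags
    clear; otherwise flagged records are retained for the user to judge
    (rafted specimens, for instance, are flagged but scientifically
    valuable).
    """
    cfg = cfg or QCConfig()
    if world.registry is not None:
        rs = standardize_records(rs, world.registry)
    rs = geocode_records(rs, world.gazetteer)
    rs = dedup_records(rs)
    rs = apply_flags(rs, world.land, world.light, world.provinces, world.ranges, cfg)
    if prune:
        rs = prune_records(rs)
    return rs
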