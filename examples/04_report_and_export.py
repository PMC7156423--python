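"""Summaries per ecological group and source type, plus GeoJSON export."""

import tempfile
from pathlib import Path

from marineqc import (
    WorldConfig,
    build_world,
    export_geojson,
    generate_records,
    prune_records,
    run_pipeline,
    summarize,
)

cfg = WorldConfig(seed=7)
world = build_world(cfg)
records, _ = generate_records(world, n=1000, seed=7, cfg=cfg)
flagged = run_pipeline(records, world)

report = summarize(flagged)
print(report.to_dataframe("records").to_string(index=False))
print()
print("pruned dataset:", len(prune_records(flagged)), "of", len(flagged),
      "records carry no flag")

out = Path(tempfile.mkdtemp()) / "records.geojson"
export_geojson(flagged, out)
print("GeoJSON written to", out)
# Flagged cells show count (percentage of that group x source overall);
# the total column is the exact sum of the three source columns.
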