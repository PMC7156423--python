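# marineqc

Quality control for marine-forest occurrence records.

Occurrence records of kelps, fucoids (orders Fucales, Laminariales,
Tilopteridales) and seagrasses (families Cymodoceaceae, Hydrocharitaceae,
Posidoniaceae, Zosteraceae) aggregated from literature, herbaria and online
repositories are riddled with recurring defects: unstandardized and
misspelled taxon names, records placed on land, records in water too dark
for photosynthesis, records far outside a species' documented range, and
duplicated observations shared between interoperating databases. `marineqc`
is a library and CLI that cleans and *flags* such Darwin-Core-termed record
tables, so users can prune or keep doubtful records (for instance rafted
specimens, which are wrong for niche models but valuable for dispersal
ecology).

## The method

A record table passes through four stages, each logged with removal counts:

1. **Taxonomic standardization.** Verbatim names are matched exactly
   (case/whitespace-insensitive) against a local WoRMS-style registry of
   `aphiaID`-keyed taxa; synonyms are followed along `acceptedAphiaID`
   chains to the accepted species. No-match (including misspelled) and
   uncertain-status names are removed, not repaired.
2. **Geocoding.** Records lacking coordinates are geolocated from a
   gazetteer table by locality name; unmatched coordinate-less records are
   removed.
3. **Deduplication.** Two records are duplicates when they agree exactly on
   accepted taxon, longitude, latitude, depth, and date (year, month, day),
   with missing comparing equal to missing; the first in input order is
   kept.
4. **Flagging.** Three independent tri-state flags
   (flagged = `-1` / clear = empty / unevaluated):
   - *on land* — the point lies inside a landmass polygon more than
     `d` km from the shoreline (default `d = 1`, absorbing the spatial
     resolution of the coastline polygons);
   - *unsuitable light* — the maximum benthic light over the three
     Bio-ORACLE-style depth layers at the point is strictly below
     `E_min = 50` E·m⁻²·yr⁻¹, the limiting annual dose for marine-forest
     photosynthesis (holopelagic *Sargassum fluitans*, *S. natans* and
     *S. pusillum* are exempt);
   - *outside known distribution* — the point falls in a marine province
     (MEOW-style polygon) not in the species' curated known-range table.
     Species absent from that table are removed entirely.

Because the real deposited dataset (~2.8 M records) and its geospatial
layers are large external downloads, the package ships a deterministic
**synthetic world generator**: cell-aligned rectangular islands, a 3-layer
light raster decaying with distance from shore, a rectangular province
tiling, a registry with synonyms, a range table and a gazetteer — plus
record generators that plant exact, labelled counts of every error type
with guard margins from each decision boundary. The pipeline is expected to
recover those labels *exactly*, which is what the test suite and the
acceptance script verify.

## Worked example

```python
from marineqc import WorldConfig, build_world, generate_records, run_pipeline

cfg = WorldConfig(seed=42)
world = build_world(cfg)
records, truth = generate_records(world, n=2000, seed=42, cfg=cfg)
flagged = run_pipeline(records, world)
for line in flagged.provenance:
    print(line)
```

prints

```
generate: 2000 records, seed 42
standardize: 2000 kept, 0 removed (0 no-match, 0 uncertain)
geocode: 0 geocoded, 0 removed (no coordinates)
dedup: 1800 kept, 200 removed
flags: 100 removed (no range information); flagged on-land 200, unsuitable-light 200, outside-distribution 200
```

The generator planted 200 duplicates, 100 records of a species with no
range information, and 200 records each on land, in light-limited water
and outside the species' provinces — and the pipeline recovered every
group exactly: 2000 − 200 − 100 = 1700 records remain, 600 of them
carrying exactly the planted flags. See `examples/` for more: taxonomy
(`02_taxonomy.py`), geometry kernels (`03_geometry.py`), summary tables
and GeoJSON export (`04_report_and_export.py`).

The same pipeline runs from the shell on user-supplied files:

```bash
marineqc simulate --seed 5 --n-records 2000 -o world/      # or your own data
marineqc run --records world/records.csv --registry world/registry.csv \
    --land world/land.geojson --light-dir world/ --provinces world/provinces.geojson \
    --ranges world/ranges.csv --pruned -o out/
marineqc summarize --records out/records_flagged.csv
```

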