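# Methods

This note documents the models, rules and numerical choices behind
`marineqc`, and what the synthetic-world tests do and do not demonstrate
about real data.

## Record model and serialization

Records follow Darwin Core term names (`decimalLongitude`,
`verbatimDepth`, `sourceType`, ...) with three quality-flag columns
(`flagMachineOnLand`, `flagMachineSuitableLightBottom`,
`flagHumanCuratedDistribution`). Flags are tri-state in memory —
flagged / clear / unevaluated — but the tabular convention is binary:
`-1` for flagged, empty otherwise. To keep the third state visible across
a write/read cycle, a flag column in which *no* record was evaluated is
omitted from the output entirely (column absent ⇒ unevaluated on read);
a record left unevaluated among evaluated ones serializes as empty and
receives a `recordNotes` annotation. Rows violating type invariants on
read (coordinates out of range, day without month, month without year,
non-4-digit years, unparseable numbers, unknown source types) are dropped
and counted in the provenance log rather than repaired — unusable entries
are removed, not guessed at.

Every destructive operation appends a provenance entry with its removal
count, so `|input| − |output|` always equals the sum of logged removals.

## Taxonomic standardization

Matching is exact after lower-casing and whitespace collapsing; no fuzzy
matching, because misspellings are treated as removals, not repairs.
Synonym chains (`acceptedAphiaID` pointers) are followed transitively
with a depth cap of 20 and a cycle check; real registries contain
multi-hop synonymies even though single hops dominate. Registries are
validated on load: duplicate `aphiaID`s, dangling pointers and cycles are
fatal. Accepted records whose rank is below species are rolled up to the
species-rank parent when the registry holds the binomial (first two name
tokens); otherwise the infraspecific accepted record is kept. This makes
species-level counting well defined without inventing parents.

Ecological groups are assigned from the hierarchy: order ∈ {Fucales,
Laminariales, Tilopteridales} ⇒ kelp/fucoid; family ∈ {Cymodoceaceae,
Hydrocharitaceae, Posidoniaceae, Zosteraceae} ⇒ seagrass.

## Deduplication

The duplicate key is (accepted taxon, longitude, latitude, depth, year,
month, day). Depth uses `verbatimDepth` when present — the least
processed value — else the (min, max) depth pair. Equality is exact value
equality of the parsed numbers, which is insensitive to trailing zeros
("1.50" ≡ "1.5") and applies no rounding; missing compares equal to
missing. The first record in input order survives: stable and
reproducible, with no judgment about source credibility.

## Geometry kernels

All kernels are spherical with R = 6371.0 km (mean Earth radius); no
ellipsoidal geodesy, since the decision thresholds (1 km, cell-sized
rasters) dwarf the spherical error at these scales.

- **Containment** is even-odd ray casting with an explicit boundary test:
  points exactly on any ring edge (outer or hole) count as inside. Tested
  against a signed-angle winding-number oracle and against `shapely`.
- **Shoreline distance** densifies every boundary segment to ≤ 0.01°
  steps and minimizes the haversine distance over the samples, then
  refines: every sample within one step-length (km) of the coarse minimum
  gets a ±1-step window re-sampled 1000× finer, bounding the
  discretization error by about a metre. The refinement matters: coarse
  sampling alone can overestimate by up to ~0.5 km, which is material
  against a 1 km threshold.
- **Raster sampling** is nearest-cell (the cell containing the point), no
  interpolation; the benthic-light value at a record is the maximum over
  the three depth layers with nodata skipped — the conservative choice
  when record depth is unknown, applied unconditionally even when depth
  is recorded. A record outside the grid, or with all layers nodata, is
  unevaluated.
- **Province lookup** returns the lowest ID when a point lies on a shared
  boundary — deterministic and testable.
- Antimeridian-crossing polygons are rejected on load (rings spanning
  > 180° of longitude); inputs must be split at ±180°. Rings are
  validated as closed (≥ 4 vertices) and non-self-intersecting via an
  O(n²) proper-crossing scan, adequate for the ring sizes used here.

## Flag semantics

- **On land**: flagged iff *inside* a land polygon *and* more than
  `shoreline_threshold_km` (default 1.0) from the nearest boundary. The
  threshold is read as a tolerance for the limited spatial resolution of
  the coastline polygons: a point just inside a coarse coastline is more
  likely a digitization artifact than a terrestrial alga.
- **Unsuitable light**: strictly below `light_threshold` (default 50
  E·m⁻²·yr⁻¹) is flagged; exactly at the threshold is clear. The three
  holopelagic *Sargassum* species that complete their life cycle afloat
  are exempt by accepted name (the set is configurable).
- **Outside distribution**: the record's province is compared with the
  species' curated range set. A species *absent* from the range table has
  no baseline at all and its records are removed; a species with an empty
  range set is flagged everywhere (the two cases are distinct). A record
  whose province cannot be determined (offshore beyond province coverage)
  is left unevaluated — provinces cover shelf waters, so absence of a
  province is not evidence of error.

Flags are computed independently; a record may carry any subset. Pruning
keeps records with all three flags clear and refuses to run on
unevaluated flags (a pipeline-order error).

## Synthetic world and what the tests show

The generator builds a 9° × 9° domain at 0.1° resolution (defaults):
four 1.4° rectangular islands aligned to cell boundaries, surface light
200 E·m⁻²·yr⁻¹ decaying 10 % per cell of distance from the nearest
shoreline (on both sides of the coast, so near-shore land cells are
bright and deep-interior cells dim), per-layer attenuation factors
(1.0, 0.85, 0.70) keeping layer maxima ordered, a 3 × 3 province tiling
aligned to whole cells, 12 ranged species (half kelp/fucoid, half
seagrass) each with 2 registered synonyms and a contiguous block of
province IDs as known range, plus one extra registry species deliberately
left out of the range table to exercise the removal rule.

Error placement uses guard margins so recovery is exact rather than
tolerance-dependent: light-suitable placements require cell values ≥ 55
and light-limited ones ≤ 45 (5 units clear of the 50 threshold); on-land
placements require ≥ 5 km of shore clearance (4 km beyond the 1 km
tolerance); records are jittered within ±0.2 cell of cell centres, which
cannot cross a cell, province, or island boundary by construction.
Duplicates are field-for-field copies (fresh id) of earlier clean
records, appended after all originals so keep-first deduplication removes
exactly them. Label counts are round(n·p) with the remainder clean.
Requested placements that are infeasible in a given world (e.g. on-land
records in a world without land) are fatal with a diagnostic.

Rectangles make the ground truth trivially computable *without* the
kernels under test, so fixture correctness does not depend on the code
being tested. The flip side: the synthetic world has no fractal
coastlines, no bathymetry, no antimeridian geometry, no source-type
imbalance, and its light field is a clean monotone gradient. Exact
recovery there demonstrates the decision logic and the bookkeeping, not
robustness to the noise and boundary-adjacent ambiguity of real layers —
on real data, records genuinely near a threshold will flip with layer
resolution, which is precisely why the output is flags rather than
deletions.

Problem sizes used by the test suite and acceptance script — 20 seeds ×
2,000 records, 50 polygons × 1,000 points, 100 shoreline cases — keep a
full run in the tens of seconds while exercising every label class
hundreds of times per world.

## Reporting

Percentages are count/overall of the same group × source cell, to two
decimals, half-up (`Decimal` quantization, avoiding binary-float rounding
surprises). Total columns/rows are exact sums of their parts. The
species-level table counts species with ≥ 1 flagged record; its
denominator is the number of species *observed in that group × source
cell*, the one unambiguous choice available from the data itself.

## Design notes

- Plain dataclasses with explicit `validate()` rather than a validation
  framework: reading needs row-level drop-with-count semantics, not
  exception-per-model.
- GeoJSON I/O via the stdlib `json` module and rasters via the plain-text
  ESRI ASCII grid format keep the package free of compiled geospatial
  dependencies; `shapely` appears only in the test suite as an
  independent oracle.
- The CLI is a thin `click` layer; every verb is one or two library calls
  plus file I/O, and the `run` verb writes a machine-readable manifest of
  stage counts alongside its outputs.
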