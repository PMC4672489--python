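# Methods

## Data model

The store organises data in four layers: a **user** (a logical owner — a
project or research group) holds **experiments**; an experiment holds
**nodes** (experimental units, e.g. field plots, optionally georeferenced
with latitude/longitude validated to ±90/±180); a node holds **streams**,
each a timestamp/real-value series with a measurement unit. Key/value
metadata (strings only) attaches at every layer and is the filtering
surface: stream selection composes case-insensitive substring matches on
entity names and units with exact-match metadata predicates at any ancestor
level, returning a deterministic (experiment, node, stream) name order.

Entity names are case-sensitive identifiers matching `[A-Za-z0-9._-]+`
because they appear in file names and API paths; path-form ids join the
four names with `~`, a character excluded from the name alphabet so the
encoding never collides. Each experiment carries a timezone label
(default `UTC`) that is display-only: all storage and window arithmetic is
UTC, which keeps window boundaries unambiguous across sites. Deletion
cascades through the subtree and requires an explicit force flag in the
CLI.

## Window statistics

Seven aggregation levels maintain summaries (`raw` is pass-through): 1-min,
15-min, 1-hour and 1-day windows are fixed spans aligned to the UTC epoch;
1-month and 1-year are UTC-calendar aligned and therefore variable-length
(a fixed span cannot represent a calendar month); `overall` is a single
window with sentinel start 0. All windows are half-open `[start, next)`.

Each summary holds count, mean, the `M₂` sum-of-squared-deviations
accumulator, min/max with occurrence times, and the last value/timestamp.
Updates use the Welford recurrence (each increment of `M₂` is a
non-negative product, so `M₂ ≥ 0` holds exactly); merges use the parallel
(Chan) combination. `M₂` rather than the standard deviation is what is
stored and persisted, so merges stay exact and σ is derived on read.

Deliberate conventions, chosen so results are independent of arrival order:

- **Standard deviation is population (`√(M₂/n)`) by default**, sample
  (`n−1`) by flag. Population matches the streaming-moment definition and
  SQL's `STD` default, the natural cross-check for a GROUP-BY oracle.
- **Min/max ties keep the earliest occurrence time** — deterministic under
  any ingest order.
- **"last" means greatest data timestamp, not most recent arrival** —
  well-defined under out-of-order and batched ingest.

## The store and the pre-aggregation contract

Raw points are kept per stream as sorted int64/float64 arrays (timestamps
are integer seconds UTC; sub-second data is out of scope since the target
cadences are 1 s and slower). A batch append validates every row first
(non-finite values and, under the `reject` policy, duplicate timestamps are
reported with reasons), then applies the whole batch, so a failure leaves
no partial state.

Duplicate timestamps default to **replace** (last write wins), because
re-uploads of cleaned or re-exported logger files are routine in field
work. Replacement cannot be applied incrementally — min/max have no
inverse — so the affected 1-min windows are rebuilt from raw and every
ancestor window is re-derived by merging its children; a re-ingest of
identical values is detected and skipped, making it exactly idempotent.

Aggregated reads never touch raw data: window queries enumerate the aligned
window starts in the requested span analytically and look summaries up by
key, so their cost is bounded by the number of windows in the span, not by
the amount of data stored. A `TouchCounter` on the store counts raw and
summary records read per query; it is the instrument behind the scaling
benchmark and turns "pre-aggregated queries don't rescan raw data" from a
design intention into an asserted invariant.

Persistence is one JSON-lines file per concern: `entities.jsonl` for the
hierarchy, `data/<stream>.jsonl` for raw points (ISO-8601 timestamps),
`agg/<stream>.<level>.jsonl` for summaries. Summary files carry an MD5
checksum of the raw arrays; on load, a mismatch (e.g. a hand-edited data
file) triggers a rebuild of all windows from raw. JSON-lines was chosen
over a binary tier because the store's unit of trust is the raw series:
storage stays transparent, diffable and recoverable.

## Diagnostics

Three detectors run per stream over one UTC calendar day:

- **Gaps**: every interval between successive readings longer than the
  threshold, *including* the edges from midnight to the first reading and
  from the last reading to midnight — a sensor that dies at 13:00 must be
  flagged that evening, not a day later.
- **Range violations**: values strictly below/above configured physical
  bounds (a value exactly at a bound is legal). Screening is hierarchical:
  the day window's min/max is checked first, then 15-min windows, and raw
  points are read only inside 15-min windows that flag — identical findings
  to a full scan, at summary cost on a healthy day.
- **Missing sensors**: streams with zero points that day, decided from the
  day-window count alone. A missing stream is never also reported as a gap.

Thresholds and bounds are configuration with no asserted defaults, since
they are deployment-specific (canopy-temperature bounds differ from soil
moisture). The report renders as text and JSON; delivery (e-mail, chat) is
left to whatever pipes the file onward. Tagging or cleaning flagged values
is deliberately not implemented: the intended workflow is to clean
downstream and re-ingest as a new stream, keeping the original record
immutable.

## Synthetic irradiance and the benchmark

The generator emulates clear-sky global irradiance at fixed cadence: solar
declination `δ = −23.44° · cos(2π(doy+10)/365)`, hour angle from clock
time (clock time is treated as local solar time, so solar noon is 12:00),
`sin(elevation) = sinφ sinδ + cosφ cosδ cosH`, irradiance
`peak · max(sin e, 0)` plus seeded Gaussian noise, clipped at zero, and
exactly zero whenever the sun is below the horizon. Defaults: latitude
−35° (a southern temperate field site), peak 1000 W/m², noise σ 5 W/m² —
small relative to the diurnal signal, as befits a clear-sky simulation
whose deterministic backbone carries the structure. The approximation is a
standard declination/hour-angle formula, not an ephemeris: the benchmark
needs a plausible diurnal shape, not astronomical accuracy.

Benchmark datasets use **30-day months**, making one month at 1 Hz exactly
2,592,000 points; the store's 1-month windows remain true calendar months —
the two conventions serve different purposes and coexist. The benchmark
layout ingests one stream per dataset duration (1..12 months → 12 streams).

`brute_force_aggregate` is the independent oracle: pandas group-by with a
two-pass standard deviation (mean first, then squared deviations), sharing
only the window-boundary arithmetic with the incremental engine. The
latency benchmark reports **records touched** per (engine, dataset size,
level) rather than wall-clock time: operation counts are exact,
deterministic and machine-independent, while absolute query times are a
property of the hardware (wall clock is logged for interest, never
asserted). The headline result is structural: pre-aggregated summary reads
for a fixed-span query are constant in dataset size; brute-force raw reads
grow linearly with fitted slope equal to the points per month.

## Problem sizes and numerical tolerances

The test suite and acceptance script run the full pipeline at sizes chosen
to exercise every window level while staying desk-sized: oracle
equivalence uses 1,000 randomized streams (most under 180 points, a few
thousands, timestamps spread over two years so month/year windows
multiply); the hierarchy and scaling checks use scaled sampling (60 s and
coarser) of the 30-day-month generator, with the point-count identities
checked at full 1 Hz. Counts, extrema, occurrence times and last-point
fields are compared exactly; mean and σ to 1e-9 relative. Property tests
compare `M₂` under an explicit floating-point error model
(`O(n · ε · scale²)`), since near-cancellation can make a fixed relative
tolerance meaningless when the true spread is tiny relative to the values.

## Known limitations

- Window durations are fixed; there are no sliding or custom windows, and
  no approximate sketches — the statistics are exact by design.
- Metadata values are plain strings; numeric range filtering on metadata is
  out of scope.
- The REST service holds the store in memory and is single-writer
  (concurrent writes are serialized by a lock; reads are concurrent); it is
  an access surface, not a distributed system — the merge contract is what
  would make partitioned deployment exact.
- Timestamps are whole seconds; sub-second instrumentation would need a
  finer time base throughout.
- The irradiance generator models clear-sky shape with additive noise; it
  does not emulate clouds, seasonal aerosol or sensor drift, so passing
  benchmarks say nothing about QC behaviour under weather-driven
  variability — the QC tests instead plant faults explicitly.
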