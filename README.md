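# fieldstore

A hierarchical store for biological and environmental sensor time series —
the kind produced by field phenomics trials, weather stations and wireless
sensor networks — in which every stream maintains pre-computed statistics
over fixed time-aggregation windows, updated incrementally on ingest, so
statistical queries at any aggregation level are answered without scanning
raw points.

It is written for researchers who run instrumented field experiments: the
data model mirrors how such experiments are organised (a research group owns
experiments; an experiment groups plots; a plot carries measurement streams;
metadata such as treatment, genotype, sensor depth or serial number attaches
at every layer and drives filtering), and the daily QC report answers the
question a deployment maintainer actually asks each morning — which sensors
went silent, stalled, or read something physically impossible yesterday?

## The model

A stream is a series of `(timestamp, value)` pairs with a unit. Each stream
maintains, for every window *w* at levels 1-min, 15-min, 1-hour, 1-day,
1-month, 1-year and overall, the summary

- `n` — point count,
- `x̄` — mean, via the single-pass (Welford) recurrence
  `x̄ₙ = x̄ₙ₋₁ + (xₙ − x̄ₙ₋₁)/n`,
- `M₂ = Σ(xᵢ − x̄)²` — the spread accumulator, with population standard
  deviation `σ = √(M₂/n)` derived on read,
- min and max with their occurrence times (ties keep the earliest),
- the last value and last timestamp (greatest *data* timestamp, so
  out-of-order ingest is well defined).

Summaries of disjoint point sets merge exactly with the parallel
combination `M₂ = M₂ᵃ + M₂ᵇ + δ²·nᵃnᵇ/(nᵃ+nᵇ)` where `δ = x̄ᵇ − x̄ᵃ`; this
mergeability is what makes partitioned, shared-nothing processing return the
same answer as a single pass, and it is what the test suite verifies against
a brute-force GROUP-BY oracle.

## Worked example

```python
import math
from fieldstore import SensorStore, WindowLevel, iso, stats_std

store = SensorStore()
store.create_entity("user", "u")
store.create_entity("experiment", "demo", "u")
store.create_entity("node", "plot-R1C1", "u~demo")
store.create_entity("stream", "canopy-temp", "u~demo~plot-R1C1", attrs={"unit": "degC"})
sid = "u~demo~plot-R1C1~canopy-temp"

points = [(t, 18.0 + 9.0 * math.sin(2 * math.pi * (t - 9 * 3600) / 86400))
          for t in range(0, 86400, 60)]          # one day at 1-min cadence
report = store.append_points(sid, points)
print(report.accepted, report.windows_touched)   # -> 1440 1564

store.touch.reset()
hours = store.get_window_stats(sid, WindowLevel.HOUR1, 0, 86400)
start, w = hours[10]
print(len(hours), store.touch.raw_records_read)  # -> 24 0
print(iso(start), w.count, round(w.mean, 2), round(stats_std(w), 2))
# -> 1970-01-01T10:00:00Z 60 21.42 0.63
```

1440 one-minute readings land in 1564 windows across the seven levels; the
hourly query reads 24 summary records and **zero** raw records (the
pre-aggregation contract); hour 10 holds 60 points with mean 21.42 °C and
population σ 0.63 °C. Running `examples/04_scaling_benchmark.py` prints the
scaling consequence: a fixed one-day query touches the same number of
summary records whether the store holds 1 or 8 months of data, while a
brute-force GROUP-BY touches every raw row — its fitted slope equals the
points per month (8,640 at 5-min sampling).

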