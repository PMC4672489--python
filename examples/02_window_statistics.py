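"""Ingest a day of readings and query pre-computed window statistics.

A day of 1-minute canopy-temperature readings is appended once; afterwards
hourly and daily summaries (count, mean, std, min/max with times, last) are
read straight from the maintained windows — the raw series is never
rescanned, which the touch counter demonstrates.
"""

import math

from fieldstore import SensorStore, WindowLevel, iso, stats_std

store = SensorStore()
store.create_entity("user", "u")
store.create_entity("experiment", "demo", "u")
store.create_entity("node", "plot-R1C1", "u~demo")
store.create_entity("stream", "canopy-temp", "u~demo~plot-R1C1", attrs={"unit": "degC"})
sid = "u~demo~plot-R1C1~canopy-temp"

# one day at 1-min cadence: a diurnal sinusoid around 18 degC
points = [
    (t, 18.0 + 9.0 * math.sin(2 * math.pi * (t - 9 * 3600) / 86400))
    for t in range(0, 86400, 60)
]
report = store.append_points(sid, points)
print(f"ingested {report.accepted} points, touched {report.windows_touched} windows")

store.touch.reset()
hours = store.get_window_stats(sid, WindowLevel.HOUR1, 0, 86400)
print(f"\nhourly summaries: {len(hours)} windows, "
      f"raw records read: {store.touch.raw_records_read}")
print(f"{'window':>22}{'n':>5}{'mean':>9}{'std':>8}{'min':>8}{'max':>8}")
for start, w in hours[8:12]:
    print(
        f"{iso(start):>22}{w.count:>5}{w.mean:>9.2f}{stats_std(w):>8.2f}"
        f"{w.min_value:>8.2f}{w.max_value:>8.2f}"
    )

overview = store.stream_summary(sid)
day = overview["1-day"]
print(
    f"\nwhole-day overview: n={day.count}, mean={day.mean:.2f} degC, "
    f"max={day.max_value:.2f} at {iso(day.max_time)}"
)
# The daily maximum lands mid-afternoon (the sinusoid peaks at 15:00) and
# every level reports the same count: each point is in exactly one window.
for label in ("1-min", "1-hour", "1-day", "overall"):
    print(f"  {label:>8}: count {overview[label].count}")
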