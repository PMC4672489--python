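"""Daily sensor-network QC: find the dead, the gappy and the out-of-range.

A 15-minute canopy-temperature deployment is emulated for one day with three
planted faults — one silent sensor, one sensor missing three consecutive
readings, one with two impossible spikes — and the daily report flags
exactly them.
"""

from fieldstore import DiagnosticConfig, SensorStore, daily_report
from fieldstore.diagnostics import day_bounds

DAY = "2013-09-14"
t0, _ = day_bounds(DAY)

store = SensorStore()
store.create_entity("user", "diag")
store.create_entity("experiment", "ir-sensors", "diag")
store.create_entity("node", "mote-field-7", "diag~ir-sensors")

regular = [(t0 + k * 900, 21.0) for k in range(96)]  # every 15 min
fixtures = {
    "irt-healthy": regular,
    "irt-dead": [],  # never reported
    "irt-gappy": [p for p in regular if not (t0 + 36000 <= p[0] < t0 + 38700)],
    "irt-spiky": [
        (t, 85.0 if t in (t0 + 30 * 900, t0 + 31 * 900) else v) for t, v in regular
    ],
}
for name, pts in fixtures.items():
    store.create_entity("stream", name, "diag~ir-sensors~mote-field-7",
                        attrs={"unit": "degC"})
    if pts:
        store.append_points(f"diag~ir-sensors~mote-field-7~{name}", pts)

config = DiagnosticConfig(
    gap_threshold=1800,   # anything beyond 2 missed slots
    min_allowed=-10.0,    # plausible canopy temperature bounds, degC
    max_allowed=60.0,
    report_day=DAY,
)
report = daily_report(store, "diag~ir-sensors", config)
print(report.to_text())

# One gap (an hour between successive readings on irt-gappy), two range
# errors (the 85 degC spikes) and
# one missing sensor (irt-dead, which by design is never also a gap error).
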