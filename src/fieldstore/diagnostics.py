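"""Daily sensor-network QC report: gap, range and missing-sensor errors.

A field deployment of battery-powered loggers fails quietly: a radio dies, a
battery browns out, an infra-red thermometer reads the sky.  The daily
report flags, per stream of an experiment, (1) *gaps* — intervals between
successive readings longer than a threshold, including the edges from
midnight to the first reading and from the last reading to midnight;
(2) *range violations* — values strictly below/above configured physical
bounds; (3) *missing sensors* — streams with no data at all that day.  A
missing stream is reported once, never also as a gap.

Range screening consults window min/max summaries first and descends to raw
points only inside windows that flag, so a healthy day costs no raw reads.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from datetime import date, datetime, timezone

from .store import SensorStore, iso, parse_ts
from .windows import WindowLevel

__all__ = [
    "DiagnosticConfig",
    "GapError",
    "RangeError",
    "DiagnosticReport",
    "detect_gaps",
    "detect_range_violations",
    "daily_report",
    "day_bounds",
]


def day_bounds(day: "date | str") -> tuple[int, int]:
    """UTC [00:00, 24:00) epoch-second bounds of a calendar date."""
    if isinstance(day, str):
        day = date.fromisoformat(day)
    start = int(datetime(day.year, day.month, day.day, tzinfo=timezone.utc).timestamp())
    return start, start + 86400


@dataclass
class DiagnosticConfig:
    """Thresholds for one report run.  All durations in seconds.

    ``expected_period`` is the nominal reporting interval of the deployment
    (informational, shown in the text report); ``gap_threshold`` is the
    interval length that counts as a fault.  Range bounds are per-deployment
    physical limits for the monitored quantity.
    """

    gap_threshold: int
    min_allowed: float
    max_allowed: float
    report_day: "date | str"
    expected_period: int = 900

    def __post_init__(self) -> None:
        if self.gap_threshold <= 0:
            raise ValueError("gap_threshold must be > 0")
        if not self.min_allowed < self.max_allowed:
            raise ValueError("min_allowed must be < max_allowed")


@dataclass
class GapError:
    stream: str
    start: int
    length: int


@dataclass
class RangeError:
    stream: str
    timestamp: int
    value: float
    bound: str  # "min" | "max"


@dataclass
class DiagnosticReport:
    experiment: str
    day: str
    gap_errors: list[GapError] = field(default_factory=list)
    range_errors: list[RangeError] = field(default_factory=list)
    missing_sensors: list[str] = field(default_factory=list)
    generated_at: int = 0

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "day": self.day,
            "gap_errors": [
                {"stream": g.stream, "start": iso(g.start), "length_s": g.length}
                for g in self.gap_errors
            ],
            "range_errors": [
                {
                    "stream": r.stream,
                    "timestamp": iso(r.timestamp),
                    "value": r.value,
                    "bound": r.bound,
                }
                for r in self.range_errors
            ],
            "missing_sensors": list(self.missing_sensors),
            "generated_at": iso(self.generated_at),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DiagnosticReport":
        d = json.loads(text)
        return cls(
            experiment=d["experiment"],
            day=d["day"],
            gap_errors=[
                GapError(g["stream"], parse_ts(g["start"]), int(g["length_s"]))
                for g in d["gap_errors"]
            ],
            range_errors=[
                RangeError(r["stream"], parse_ts(r["timestamp"]), float(r["value"]), r["bound"])
                for r in d["range_errors"]
            ],
            missing_sensors=list(d["missing_sensors"]),
            generated_at=parse_ts(d["generated_at"]),
        )

    def to_text(self) -> str:
        lines = [
            f"Diagnostic report — experiment {self.experiment}, day {self.day}",
            f"generated at {iso(self.generated_at)}",
            "",
            f"Gap errors ({len(self.gap_errors)}):",
        ]
        for g in self.gap_errors:
            lines.append(f"  {g.stream}: gap of {g.length} s starting {iso(g.start)}")
        lines.append(f"Range errors ({len(self.range_errors)}):")
        for r in self.range_errors:
            lines.append(
                f"  {r.stream}: value {r.value} at {iso(r.timestamp)} beyond {r.bound} bound"
            )
        lines.append(f"Missing sensors ({len(self.missing_sensors)}):")
        for s in self.missing_sensors:
            lines.append(f"  {s}: no data reported")
        return "\n".join(lines)


def detect_gaps(
    store: SensorStore, stream, day: "date | str", threshold: int
) -> list[GapError]:
    """Intervals between successive readings on *day* longer than *threshold*.

    Day edges count: midnight→first reading and last reading→midnight are
    candidate gaps, so a sensor dying mid-afternoon is caught the same day.
    A stream with no points at all yields no gaps (it is a missing sensor).
    """
    if threshold <= 0:
        raise ValueError("gap threshold must be > 0")
    ent = store.tree.resolve(stream)
    t0, t1 = day_bounds(day)
    pts = store.get_raw(ent, t0, t1)
    if not pts:
        return []
    edges = [t0] + [p.timestamp for p in pts] + [t1]
    gaps = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a > threshold:
            gaps.append(GapError(ent.path, a, b - a))
    return gaps


def detect_range_violations(
    store: SensorStore,
    stream,
    day: "date | str",
    min_allowed: float,
    max_allowed: float,
) -> list[RangeError]:
    """Points on *day* strictly outside ``[min_allowed, max_allowed]``.

    Checks the day window's min/max first, then 15-min windows, and reads raw
    points only inside 15-min windows that flag — identical findings to a
    full raw scan, at summary cost when the day is healthy.
    """
    if not min_allowed < max_allowed:
        raise ValueError("min_allowed must be < max_allowed")
    ent = store.tree.resolve(stream)
    t0, t1 = day_bounds(day)

    def flags(w) -> bool:
        return w.min_value < min_allowed or w.max_value > max_allowed

    day_wins = store.get_window_stats(ent, WindowLevel.DAY1, t0, t1)
    if not any(flags(w) for _, w in day_wins):
        return []
    out: list[RangeError] = []
    for start, w in store.get_window_stats(ent, WindowLevel.MIN15, t0, t1):
        if not flags(w):
            continue
        for t, v in store.get_raw(ent, start, start + 900):
            if v < min_allowed:
                out.append(RangeError(ent.path, t, v, "min"))
            elif v > max_allowed:
                out.append(RangeError(ent.path, t, v, "max"))
    return out


def daily_report(
    store: SensorStore, experiment, config: DiagnosticConfig
) -> DiagnosticReport:
    """Run all three detectors over every stream of *experiment* for one day.

    Streams are visited in deterministic (node, stream) name order; a stream
    with zero points that day goes to ``missing_sensors`` only.
    """
    exp = store.tree.resolve(experiment)
    if exp.kind != "experiment":
        raise ValueError(f"no such experiment: {exp.path!r} is a {exp.kind}")
    day = config.report_day
    day_str = day if isinstance(day, str) else day.isoformat()
    t0, t1 = day_bounds(day)
    report = DiagnosticReport(
        experiment=exp.path, day=day_str, generated_at=int(time.time())
    )
    for s in store.tree.streams(exp):
        day_wins = store.get_window_stats(s, WindowLevel.DAY1, t0, t1)
        n_day = sum(w.count for _, w in day_wins)
        if n_day == 0:
            report.missing_sensors.append(s.path)
            continue
        report.gap_errors.extend(detect_gaps(store, s, day, config.gap_threshold))
        report.range_errors.extend(
            detect_range_violations(store, s, day, config.min_allowed, config.max_allowed)
        )
    return report
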