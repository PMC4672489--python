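"""Fixed time-aggregation windows and the running statistics each window maintains.

A stream's points are bucketed into non-overlapping windows at seven
aggregation levels (1-min, 15-min, 1-hour, 1-day, 1-month, 1-year, overall;
``raw`` is a pass-through level with no summaries).  Each window keeps a
single-pass summary — count, mean, an M2 spread accumulator, min/max with
occurrence times, and the point with the greatest timestamp — that is updated
per incoming point (Welford recurrence) and can be merged exactly across
disjoint partitions (Chan parallel combination).  Mergeability is what makes
partitioned, shared-nothing processing give the same answer as a single pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum

__all__ = [
    "WindowLevel",
    "WindowStats",
    "window_start",
    "window_end",
    "iter_window_starts",
    "stats_update",
    "stats_merge",
    "stats_std",
    "OVERALL_START",
]

#: Sentinel start for the single "overall" window of a stream.
OVERALL_START = 0


class WindowLevel(str, Enum):
    """The eight aggregation levels.  ``RAW`` has no summary rows."""

    RAW = "raw"
    MIN1 = "1-min"
    MIN15 = "15-min"
    HOUR1 = "1-hour"
    DAY1 = "1-day"
    MONTH1 = "1-month"
    YEAR1 = "1-year"
    OVERALL = "overall"

    @classmethod
    def aggregated(cls) -> tuple["WindowLevel", ...]:
        """All levels that maintain summary rows (everything but raw)."""
        return (
            cls.MIN1,
            cls.MIN15,
            cls.HOUR1,
            cls.DAY1,
            cls.MONTH1,
            cls.YEAR1,
            cls.OVERALL,
        )

    @classmethod
    def parse(cls, label: str) -> "WindowLevel":
        try:
            return cls(label)
        except ValueError:
            aliases = {
                "min1": cls.MIN1,
                "min15": cls.MIN15,
                "hour1": cls.HOUR1,
                "1-h": cls.HOUR1,
                "1-hour": cls.HOUR1,
                "day1": cls.DAY1,
                "month1": cls.MONTH1,
                "year1": cls.YEAR1,
            }
            if label in aliases:
                return aliases[label]
            raise ValueError(f"unknown aggregation level: {label!r}") from None


#: Span in seconds of the epoch-aligned fixed levels.
FIXED_SPANS: dict[WindowLevel, int] = {
    WindowLevel.MIN1: 60,
    WindowLevel.MIN15: 900,
    WindowLevel.HOUR1: 3600,
    WindowLevel.DAY1: 86400,
}


def _utc(ts: int) -> datetime:
    return datetime.fromtimestamp(ts, tz=timezone.utc)


def window_start(ts: int, level: WindowLevel) -> int:
    """Start (epoch seconds, UTC) of the window at *level* enclosing *ts*.

    Sub-day levels are fixed spans counted from the UTC epoch; month and year
    windows are UTC-calendar aligned (variable length).  Windows are half-open
    ``[start, next_start)``.
    """
    if level is WindowLevel.RAW:
        raise ValueError("raw has no windows")
    if level is WindowLevel.OVERALL:
        return OVERALL_START
    span = FIXED_SPANS.get(level)
    if span is not None:
        return int(ts) - int(ts) % span
    dt = _utc(int(ts))
    if level is WindowLevel.MONTH1:
        return int(dt.replace(day=1, hour=0, minute=0, second=0, microsecond=0).timestamp())
    if level is WindowLevel.YEAR1:
        return int(
            dt.replace(month=1, day=1, hour=0, minute=0, second=0, microsecond=0).timestamp()
        )
    raise ValueError(f"unhandled level {level}")


def window_end(start: int, level: WindowLevel) -> int:
    """Exclusive end of the window beginning at *start*."""
    if level is WindowLevel.RAW:
        raise ValueError("raw has no windows")
    if level is WindowLevel.OVERALL:
        return 2**62  # effectively +inf in epoch seconds
    span = FIXED_SPANS.get(level)
    if span is not None:
        return start + span
    dt = _utc(start)
    if level is WindowLevel.MONTH1:
        if dt.month == 12:
            nxt = dt.replace(year=dt.year + 1, month=1)
        else:
            nxt = dt.replace(month=dt.month + 1)
        return int(nxt.timestamp())
    if level is WindowLevel.YEAR1:
        return int(dt.replace(year=dt.year + 1).timestamp())
    raise ValueError(f"unhandled level {level}")


def iter_window_starts(t_from: int, t_to: int, level: WindowLevel):
    """Yield every aligned window start ``s`` with ``t_from <= s < t_to``.

    Enumerates boundaries analytically, so the cost is proportional to the
    number of windows in the span, never to the amount of data stored.
    """
    if level is WindowLevel.RAW:
        raise ValueError("raw has no windows")
    if t_from >= t_to:
        return
    if level is WindowLevel.OVERALL:
        if t_from <= OVERALL_START < t_to:
            yield OVERALL_START
        return
    span = FIXED_SPANS.get(level)
    if span is not None:
        s = t_from - t_from % span
        if s < t_from:
            s += span
        while s < t_to:
            yield s
            s += span
        return
    # calendar walk for month/year
    s = window_start(t_from, level)
    if s < t_from:
        s = window_end(s, level)
    while s < t_to:
        yield s
        s = window_end(s, level)


@dataclass
class WindowStats:
    """Running summary of the points inside one window.

    ``m2`` is the sum of squared deviations from the mean; the standard
    deviation is derived on read (see :func:`stats_std`) so merges stay exact.
    ``last`` is the point with the greatest *data* timestamp seen so far —
    not arrival order — so out-of-order ingest is well defined.  Min/max ties
    keep the earliest occurrence time.
    """

    count: int = 0
    mean: float = 0.0
    m2: float = 0.0
    min_value: float = math.nan
    min_time: int = 0
    max_value: float = math.nan
    max_time: int = 0
    last_value: float = math.nan
    last_time: int = 0

    def add(self, t: int, v: float) -> None:
        """Fold one point into the summary (in place, Welford recurrence)."""
        if not math.isfinite(v):
            raise ValueError("non-finite value rejected")
        if self.count == 0:
            self.count = 1
            self.mean = v
            self.m2 = 0.0
            self.min_value = self.max_value = self.last_value = v
            self.min_time = self.max_time = self.last_time = t
            return
        self.count += 1
        delta = v - self.mean
        self.mean += delta / self.count
        self.m2 += delta * (v - self.mean)
        if v < self.min_value or (v == self.min_value and t < self.min_time):
            self.min_value, self.min_time = v, t
        if v > self.max_value or (v == self.max_value and t < self.max_time):
            self.max_value, self.max_time = v, t
        if t > self.last_time:
            self.last_value, self.last_time = v, t

    def copy(self) -> "WindowStats":
        return WindowStats(
            self.count,
            self.mean,
            self.m2,
            self.min_value,
            self.min_time,
            self.max_value,
            self.max_time,
            self.last_value,
            self.last_time,
        )


def stats_update(s: WindowStats, t: int, v: float) -> WindowStats:
    """Functional form of :meth:`WindowStats.add`: returns an updated copy."""
    out = s.copy()
    out.add(t, v)
    return out


def stats_merge(a: WindowStats, b: WindowStats) -> WindowStats:
    """Combine summaries of two disjoint point multisets.

    The result equals the summary of the union: counts and extrema combine
    exactly; mean and m2 use the parallel (pairwise) combination so the
    merge of any partition agrees with a single pass up to rounding.
    The empty summary is the identity element.
    """
    if a.count == 0:
        return b.copy()
    if b.count == 0:
        return a.copy()
    out = WindowStats()
    n = a.count + b.count
    delta = b.mean - a.mean
    out.count = n
    out.mean = a.mean + delta * (b.count / n)
    out.m2 = a.m2 + b.m2 + delta * delta * (a.count * b.count / n)
    if b.min_value < a.min_value or (
        b.min_value == a.min_value and b.min_time < a.min_time
    ):
        out.min_value, out.min_time = b.min_value, b.min_time
    else:
        out.min_value, out.min_time = a.min_value, a.min_time
    if b.max_value > a.max_value or (
        b.max_value == a.max_value and b.max_time < a.max_time
    ):
        out.max_value, out.max_time = b.max_value, b.max_time
    else:
        out.max_value, out.max_time = a.max_value, a.max_time
    if b.last_time > a.last_time or (
        b.last_time == a.last_time and b.last_value > a.last_value
    ):
        out.last_value, out.last_time = b.last_value, b.last_time
    else:
        out.last_value, out.last_time = a.last_value, a.last_time
    return out


def stats_std(s: WindowStats, mode: str = "population") -> float:
    """Standard deviation of the window.

    ``population`` divides by n (the streaming-moment default, matching a SQL
    GROUP-BY STD); ``sample`` divides by n-1 and needs at least two points.
    """
    if mode == "population":
        if s.count < 1:
            raise ValueError("undefined std")
        return math.sqrt(max(s.m2, 0.0) / s.count)
    if mode == "sample":
        if s.count < 2:
            raise ValueError("undefined std")
        return math.sqrt(max(s.m2, 0.0) / (s.count - 1))
    raise ValueError(f"unknown std mode {mode!r}")
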