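"""CSV and batch ingestion, plus CSV export of query results.

Long-format CSV is the lingua franca of manual field measurements and
logger downloads: one row per reading, with a timestamp column, a value
column, and either a fixed target stream or a per-row stream-path column.
Malformed rows are collected with line numbers and reasons rather than
aborting the upload.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .model import SEP, NoSuchEntityError
from .store import IngestReport, SensorStore, iso, parse_ts
from .windows import WindowLevel, stats_std

__all__ = [
    "CsvIngestSpec",
    "ingest_csv",
    "batch_upload",
    "export_raw_csv",
    "export_window_csv",
]


@dataclass
class CsvIngestSpec:
    """How to read a long-format CSV of sensor readings.

    Exactly one of ``stream_column`` / ``stream_path`` must be set: either
    every row names its stream (path ``user~experiment~node~stream``, "/" also
    accepted) or the whole file goes to one stream.  ``timestamp_format`` is
    ``iso`` (ISO-8601, Z or offset) or ``epoch`` (integer seconds).
    """

    timestamp_column: str = "timestamp"
    value_column: str = "value"
    stream_column: str | None = None
    stream_path: str | None = None
    timestamp_format: str = "iso"
    delimiter: str = ","

    def __post_init__(self) -> None:
        if (self.stream_column is None) == (self.stream_path is None):
            raise ValueError("set exactly one of stream_column / stream_path")
        if self.timestamp_format not in ("iso", "epoch"):
            raise ValueError("timestamp_format must be 'iso' or 'epoch'")


def _ensure_stream(store: SensorStore, path: str, unit: str = "") -> None:
    parts = path.replace("/", SEP).split(SEP)
    if len(parts) != 4:
        raise NoSuchEntityError(f"no such stream: {path!r} (need user~experiment~node~stream)")
    prefix = ""
    for kind, name in zip(("user", "experiment", "node", "stream"), parts):
        full = name if not prefix else prefix + SEP + name
        if store.tree.get(full) is None:
            attrs = {"unit": unit} if kind == "stream" else None
            store.create_entity(kind, name, prefix or None, attrs)
        prefix = full


def ingest_csv(
    store: SensorStore,
    path: "str | Path | io.TextIOBase",
    spec: CsvIngestSpec,
    create_missing: bool = False,
    duplicate_policy: str = "replace",
) -> dict[str, IngestReport]:
    """Ingest a CSV file; returns a per-stream ingest report.

    Well-formed rows are appended via the store (all windows updated);
    malformed rows are recorded as ``(line_number, reason)`` in the report of
    the stream they addressed (or under ``""`` when the stream is unknown).
    """
    own = isinstance(path, (str, Path))
    fh = open(path, newline="", encoding="utf-8") if own else path
    reports: dict[str, IngestReport] = {}
    pending: dict[str, list[tuple[int, float]]] = {}
    try:
        reader = csv.DictReader(fh, delimiter=spec.delimiter)
        for lineno, row in enumerate(reader, start=2):  # 1 is the header
            target = (
                (row.get(spec.stream_column) or "").strip()
                if spec.stream_column
                else spec.stream_path
            )
            target = (target or "").replace("/", SEP)
            rep = reports.setdefault(target, IngestReport())
            try:
                raw_ts = row[spec.timestamp_column]
                t = (
                    int(str(raw_ts).strip())
                    if spec.timestamp_format == "epoch"
                    else parse_ts(raw_ts)
                )
            except (KeyError, ValueError, TypeError):
                rep.rejected += 1
                rep.errors.append((lineno, "bad timestamp"))
                continue
            try:
                v = float(row[spec.value_column])
            except (KeyError, ValueError, TypeError):
                rep.rejected += 1
                rep.errors.append((lineno, "bad value"))
                continue
            if store.tree.get(target) is None:
                if create_missing:
                    _ensure_stream(store, target)
                else:
                    rep.rejected += 1
                    rep.errors.append((lineno, "no such stream"))
                    continue
            pending.setdefault(target, []).append((t, v))
    finally:
        if own:
            fh.close()
    for target, pts in pending.items():
        reports[target].merge(
            store.append_points(target, pts, duplicate_policy=duplicate_policy)
        )
    return reports


def batch_upload(
    store: SensorStore,
    stream,
    points: Sequence[tuple[int, float]],
    chunk_size: int = 100,
    duplicate_policy: str = "replace",
) -> IngestReport:
    """Append *points* in chunks of *chunk_size*; equivalent to one big append.

    Chunking mirrors script-based bulk upload of historical data; it is
    invisible in the final state of the store.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    report = IngestReport()
    for i in range(0, len(points), chunk_size):
        report.merge(
            store.append_points(
                stream, points[i : i + chunk_size], duplicate_policy=duplicate_policy
            )
        )
    return report


def export_raw_csv(store: SensorStore, stream, t_from: int, t_to: int, out) -> int:
    """Write raw points as ``stream,timestamp,value`` rows; returns row count."""
    ent = store.tree.resolve(stream)
    w = csv.writer(out)
    w.writerow(["stream", "timestamp", "value"])
    pts = store.get_raw(ent, t_from, t_to)
    for t, v in pts:
        w.writerow([ent.path, iso(t), repr(v)])
    return len(pts)


def export_window_csv(
    store: SensorStore, stream, level: "WindowLevel | str", t_from: int, t_to: int, out
) -> int:
    """Write window summaries in the aggregated CSV layout; returns row count."""
    ent = store.tree.resolve(stream)
    rows = store.get_window_stats(ent, level, t_from, t_to)
    lvl = WindowLevel.parse(level) if isinstance(level, str) else level
    w = csv.writer(out)
    w.writerow(
        [
            "stream", "level", "window_start", "count", "mean", "std",
            "min", "min_time", "max", "max_time", "last", "last_time",
        ]
    )
    for start, s in rows:
        w.writerow(
            [
                ent.path, lvl.value, iso(start), s.count, repr(s.mean),
                repr(stats_std(s)), repr(s.min_value), iso(s.min_time),
                repr(s.max_value), iso(s.max_time), repr(s.last_value),
                iso(s.last_time),
            ]
        )
    return len(rows)
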