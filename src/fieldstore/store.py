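"""Append-oriented time-series store with transactional window maintenance.

Every ingested point updates the raw series *and* the summary of the
enclosing window at every aggregation level, so statistical queries are
answered from pre-computed summaries without scanning raw points.  A
:class:`TouchCounter` instruments the two record classes (raw vs summary)
read by each query, which is what makes the pre-aggregation contract — and
its scaling behaviour versus a brute-force GROUP-BY — testable without wall
clocks.

Timestamps are integer seconds UTC.  Raw points and window summaries persist
as JSON-lines files per stream; summaries carry a checksum of the raw series
and are rebuilt from raw when it mismatches.
"""

from __future__ import annotations

import hashlib
import json
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .model import SEP, EntityTree, Entity, NoSuchEntityError, StoreError
from .windows import (
    OVERALL_START,
    WindowLevel,
    WindowStats,
    iter_window_starts,
    stats_merge,
    stats_std,
    window_end,
    window_start,
)

__all__ = [
    "DataPoint",
    "IngestReport",
    "TouchCounter",
    "SensorStore",
    "iso",
    "parse_ts",
]


class DataPoint(NamedTuple):
    timestamp: int
    value: float


def iso(ts: int) -> str:
    """Epoch seconds → ISO-8601 UTC string (second resolution)."""
    return datetime.fromtimestamp(int(ts), tz=timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def parse_ts(text: "str | int | float") -> int:
    """ISO-8601 (Z or offset) or epoch-seconds → epoch seconds."""
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        return int(text)
    s = str(text).strip()
    try:
        return int(s)
    except ValueError:
        pass
    s = s.replace("Z", "+00:00").replace(" ", "T", 1)
    dt = datetime.fromisoformat(s)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return int(dt.timestamp())


@dataclass
class IngestReport:
    accepted: int = 0
    rejected: int = 0
    windows_touched: int = 0
    errors: list = field(default_factory=list)  # (row index or line, reason)

    def merge(self, other: "IngestReport") -> "IngestReport":
        self.accepted += other.accepted
        self.rejected += other.rejected
        self.windows_touched += other.windows_touched
        self.errors.extend(other.errors)
        return self


@dataclass
class TouchCounter:
    """Counts record reads per class; reset between queries to instrument one."""

    raw_records_read: int = 0
    summary_records_read: int = 0

    def reset(self) -> None:
        self.raw_records_read = 0
        self.summary_records_read = 0


class _StreamData:
    """Raw series (sorted int64/float64 arrays) plus per-level window maps."""

    __slots__ = ("ts", "vs", "windows", "_starts_cache")

    def __init__(self) -> None:
        self.ts = np.empty(0, dtype=np.int64)
        self.vs = np.empty(0, dtype=np.float64)
        self.windows: dict[WindowLevel, dict[int, WindowStats]] = {
            lvl: {} for lvl in WindowLevel.aggregated()
        }
        self._starts_cache: dict[WindowLevel, list[int]] = {}

    def sorted_starts(self, level: WindowLevel) -> list[int]:
        cached = self._starts_cache.get(level)
        if cached is None or len(cached) != len(self.windows[level]):
            cached = sorted(self.windows[level])
            self._starts_cache[level] = cached
        return cached

    def invalidate(self, level: WindowLevel) -> None:
        self._starts_cache.pop(level, None)

    def checksum(self) -> str:
        h = hashlib.md5()
        h.update(self.ts.tobytes())
        h.update(self.vs.tobytes())
        return h.hexdigest()


class SensorStore:
    """Entity hierarchy + per-stream raw data and window summaries.

    All mutation goes through :meth:`append_points`, which keeps every
    window summary consistent with the raw series.  Reads of aggregated
    statistics never touch raw records (asserted via :attr:`touch`).
    """

    def __init__(self, tree: EntityTree | None = None) -> None:
        self.tree = tree if tree is not None else EntityTree()
        self._data: dict[str, _StreamData] = {}
        self.touch = TouchCounter()

    # -- entity plumbing ---------------------------------------------------

    def create_entity(
        self, kind: str, name: str, parent=None, attrs: dict | None = None
    ) -> Entity:
        ent = self.tree.create(kind, name, parent, attrs)
        if kind == "stream":
            self._data[ent.path] = _StreamData()
        return ent

    def delete_entity(self, entity, cascade: bool = True) -> int:
        """Delete an entity subtree and its data; returns entities removed."""
        ent = self.tree.resolve(entity)
        if ent.children and not cascade:
            raise StoreError(f"{ent.path} has children; deletion cascades, pass cascade=True")
        removed = self.tree.delete(ent)
        for e in removed:
            if e.kind == "stream":
                self._data.pop(e.path, None)
        return len(removed)

    def _stream(self, stream) -> tuple[Entity, _StreamData]:
        ent = self.tree.resolve(stream)
        if ent.kind != "stream":
            raise NoSuchEntityError(f"no such stream: {ent.path!r} is a {ent.kind}")
        return ent, self._data[ent.path]

    # -- ingest ------------------------------------------------------------

    def append_points(
        self,
        stream,
        points: "Sequence[tuple[int, float]] | np.ndarray",
        duplicate_policy: str = "replace",
    ) -> IngestReport:
        """Append a batch of (timestamp, value) points to *stream*.

        Raw points are stored and every affected window at every level is
        updated before the call returns.  Rows with non-finite values are
        rejected; duplicate timestamps are rejected (``reject``) or take the
        last-written value (``replace``, the default).  The batch is applied
        all-or-nothing: inputs are validated before any state changes.
        """
        if duplicate_policy not in ("reject", "replace"):
            raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
        ent, sd = self._stream(stream)
        report = IngestReport()
        if len(points) == 0:
            return report

        arr = np.asarray(points, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be a sequence of (timestamp, value) pairs")
        ts_in = arr[:, 0].astype(np.int64)
        vs_in = arr[:, 1]

        # validation pass: nothing is applied until every row is classified
        finite = np.isfinite(vs_in)
        for i in np.flatnonzero(~finite):
            report.errors.append((int(i), "non-finite value rejected"))
        report.rejected += int((~finite).sum())
        ts_in, vs_in = ts_in[finite], vs_in[finite]
        if len(ts_in) == 0:
            return report

        # duplicates within the batch
        order = np.argsort(ts_in, kind="stable")
        ts_s, vs_s = ts_in[order], vs_in[order]
        dup_in_batch = np.zeros(len(ts_s), dtype=bool)
        dup_in_batch[1:] = ts_s[1:] == ts_s[:-1]
        if dup_in_batch.any():
            if duplicate_policy == "reject":
                # keep the first occurrence (stable sort keeps batch order)
                for i in np.flatnonzero(dup_in_batch):
                    report.errors.append((int(order[i]), "duplicate timestamp"))
                report.rejected += int(dup_in_batch.sum())
                keep = ~dup_in_batch
            else:
                # last write wins within the batch
                keep = np.ones(len(ts_s), dtype=bool)
                keep[:-1] = ts_s[:-1] != ts_s[1:]
            ts_s, vs_s = ts_s[keep], vs_s[keep]

        # duplicates against stored data
        if len(sd.ts):
            pos = np.searchsorted(sd.ts, ts_s)
            pos_c = np.clip(pos, 0, len(sd.ts) - 1)
            exists = sd.ts[pos_c] == ts_s
        else:
            pos = np.zeros(len(ts_s), dtype=np.int64)
            exists = np.zeros(len(ts_s), dtype=bool)

        if duplicate_policy == "reject" and exists.any():
            report.rejected += int(exists.sum())
            for t in ts_s[exists]:
                report.errors.append((int(t), "duplicate timestamp"))
            ts_s, vs_s, pos, exists = (
                ts_s[~exists],
                vs_s[~exists],
                pos[~exists],
                exists[~exists],
            )
        if len(ts_s) == 0:
            return report

        touched: set[tuple[WindowLevel, int]] = set()
        rebuild_min1: set[int] = set()

        # replacements: overwrite in place, remember windows needing rebuild
        if exists.any():
            idx = pos[exists]
            changed = sd.vs[idx] != vs_s[exists]  # identical re-ingest is a no-op
            sd.vs[idx[changed]] = vs_s[exists][changed]
            for t in ts_s[exists][changed].tolist():
                rebuild_min1.add(window_start(int(t), WindowLevel.MIN1))

        # brand-new points: insert and update incrementally at every level
        new_ts, new_vs = ts_s[~exists], vs_s[~exists]
        if len(new_ts):
            sd.ts = np.concatenate([sd.ts, new_ts])
            sd.vs = np.concatenate([sd.vs, new_vs])
            order2 = np.argsort(sd.ts, kind="stable")
            sd.ts, sd.vs = sd.ts[order2], sd.vs[order2]
            levels = WindowLevel.aggregated()
            for t, v in zip(new_ts.tolist(), new_vs.tolist()):
                for lvl in levels:
                    s = window_start(t, lvl)
                    w = sd.windows[lvl].get(s)
                    if w is None:
                        w = sd.windows[lvl][s] = WindowStats()
                        sd.invalidate(lvl)
                    w.add(t, v)
                    touched.add((lvl, s))

        if rebuild_min1:
            touched |= self._rebuild_from(sd, rebuild_min1)

        report.accepted += len(ts_s)
        report.windows_touched += len(touched)
        return report

    def _rebuild_from(self, sd: _StreamData, min1_starts: set[int]):
        """Rebuild the given 1-min windows from raw, then re-merge ancestors.

        Replacement cannot be applied incrementally (min/max have no inverse),
        so the smallest affected windows are recomputed from raw and every
        ancestor window is re-derived by merging its children.
        """
        touched: set[tuple[WindowLevel, int]] = set()
        for s in min1_starts:
            touched.add((WindowLevel.MIN1, s))
            lo = bisect_left(sd.ts, s)
            hi = bisect_left(sd.ts, s + 60)
            w = WindowStats()
            for t, v in zip(sd.ts[lo:hi].tolist(), sd.vs[lo:hi].tolist()):
                w.add(t, v)
            if w.count:
                sd.windows[WindowLevel.MIN1][s] = w
            else:
                sd.windows[WindowLevel.MIN1].pop(s, None)
                sd.invalidate(WindowLevel.MIN1)

        chain = [
            (WindowLevel.MIN15, WindowLevel.MIN1),
            (WindowLevel.HOUR1, WindowLevel.MIN15),
            (WindowLevel.DAY1, WindowLevel.HOUR1),
            (WindowLevel.MONTH1, WindowLevel.DAY1),
            (WindowLevel.YEAR1, WindowLevel.MONTH1),
        ]
        dirty = set(min1_starts)
        for parent_lvl, child_lvl in chain:
            parents = {window_start(s, parent_lvl) for s in dirty}
            for ps in parents:
                merged = WindowStats()
                for cs in iter_window_starts(ps, window_end(ps, parent_lvl), child_lvl):
                    cw = sd.windows[child_lvl].get(cs)
                    if cw is not None:
                        merged = stats_merge(merged, cw)
                touched.add((parent_lvl, ps))
                if merged.count:
                    sd.windows[parent_lvl][ps] = merged
                else:
                    sd.windows[parent_lvl].pop(ps, None)
                    sd.invalidate(parent_lvl)
            dirty = parents
        overall = WindowStats()
        for yw in sd.windows[WindowLevel.YEAR1].values():
            overall = stats_merge(overall, yw)
        touched.add((WindowLevel.OVERALL, OVERALL_START))
        if overall.count:
            sd.windows[WindowLevel.OVERALL][OVERALL_START] = overall
        else:
            sd.windows[WindowLevel.OVERALL].pop(OVERALL_START, None)
            sd.invalidate(WindowLevel.OVERALL)
        return touched

    # -- queries -----------------------------------------------------------

    def get_raw(self, stream, t_from: int, t_to: int) -> list[DataPoint]:
        """Points with ``t_from <= t < t_to`` (half-open), ascending."""
        ent, sd = self._stream(stream)
        if t_from > t_to:
            raise ValueError("empty range: t_from must be <= t_to")
        lo = np.searchsorted(sd.ts, t_from, side="left")
        hi = np.searchsorted(sd.ts, t_to, side="left")
        self.touch.raw_records_read += int(hi - lo)
        return [
            DataPoint(int(t), float(v))
            for t, v in zip(sd.ts[lo:hi].tolist(), sd.vs[lo:hi].tolist())
        ]

    def raw_count(self, stream) -> int:
        _, sd = self._stream(stream)
        return len(sd.ts)

    def get_window_stats(
        self, stream, level: "WindowLevel | str", t_from: int, t_to: int
    ) -> list[tuple[int, WindowStats]]:
        """All windows whose start lies in ``[t_from, t_to)``, ascending.

        Reads only summary records: cost is bounded by the number of windows
        in the span, independent of how many raw points the stream holds.
        """
        level = WindowLevel.parse(level) if isinstance(level, str) else level
        if level is WindowLevel.RAW:
            raise ValueError("raw has no windows; use get_raw")
        ent, sd = self._stream(stream)
        if t_from > t_to:
            raise ValueError("empty range: t_from must be <= t_to")
        wins = sd.windows[level]
        starts = sd.sorted_starts(level)
        lo = bisect_left(starts, t_from)
        hi = bisect_left(starts, t_to)
        out = [(s, wins[s]) for s in starts[lo:hi]]
        self.touch.summary_records_read += len(out)
        return out

    def stream_summary(self, stream) -> dict[str, WindowStats]:
        """Per-level overview: the merge of every window at each level.

        Keys are level labels including ``raw`` (whole-series stats, equal to
        ``overall``) so the row set matches the levels a user can query.
        """
        ent, sd = self._stream(stream)
        out: dict[str, WindowStats] = {}
        for lvl in WindowLevel.aggregated():
            merged = WindowStats()
            for s in sd.sorted_starts(lvl):
                merged = stats_merge(merged, sd.windows[lvl][s])
            self.touch.summary_records_read += len(sd.windows[lvl])
            out[lvl.value] = merged
        out[WindowLevel.RAW.value] = out[WindowLevel.OVERALL.value].copy()
        return out

    # -- persistence -------------------------------------------------------

    def save(self, root: "str | Path") -> None:
        root = Path(root)
        (root / "data").mkdir(parents=True, exist_ok=True)
        (root / "agg").mkdir(parents=True, exist_ok=True)
        self.tree.save(root / "entities.jsonl")
        for sid, sd in self._data.items():
            with open(root / "data" / f"{sid}.jsonl", "w", encoding="utf-8") as fh:
                for t, v in zip(sd.ts.tolist(), sd.vs.tolist()):
                    fh.write(json.dumps({"t": iso(t), "v": v}) + "\n")
            for lvl in WindowLevel.aggregated():
                path = root / "agg" / f"{sid}.{lvl.value}.jsonl"
                with open(path, "w", encoding="utf-8") as fh:
                    fh.write(json.dumps({"checksum": sd.checksum()}) + "\n")
                    for s in sd.sorted_starts(lvl):
                        w = sd.windows[lvl][s]
                        rec = {
                            "level": lvl.value,
                            "start": iso(s),
                            "count": w.count,
                            "mean": w.mean,
                            "std": stats_std(w),
                            "m2": w.m2,
                            "min": w.min_value,
                            "min_time": iso(w.min_time),
                            "max": w.max_value,
                            "max_time": iso(w.max_time),
                            "last": w.last_value,
                            "last_time": iso(w.last_time),
                        }
                        fh.write(json.dumps(rec) + "\n")

    @classmethod
    def load(cls, root: "str | Path") -> "SensorStore":
        root = Path(root)
        store = cls(EntityTree.load(root / "entities.jsonl"))
        for ent in store.tree.walk():
            if ent.kind != "stream":
                continue
            sid = ent.path
            sd = store._data[sid] = _StreamData()
            data_path = root / "data" / f"{sid}.jsonl"
            if data_path.exists():
                ts, vs = [], []
                with open(data_path, encoding="utf-8") as fh:
                    for line in fh:
                        if line.strip():
                            rec = json.loads(line)
                            ts.append(parse_ts(rec["t"]))
                            vs.append(float(rec["v"]))
                sd.ts = np.asarray(ts, dtype=np.int64)
                sd.vs = np.asarray(vs, dtype=np.float64)
                order = np.argsort(sd.ts, kind="stable")
                sd.ts, sd.vs = sd.ts[order], sd.vs[order]
            if not store._load_agg(root, sid, sd):
                store._rebuild_all(sd)
        return store

    def _load_agg(self, root: Path, sid: str, sd: _StreamData) -> bool:
        """Load persisted summaries; False → caller rebuilds from raw."""
        want = sd.checksum()
        for lvl in WindowLevel.aggregated():
            path = root / "agg" / f"{sid}.{lvl.value}.jsonl"
            if not path.exists():
                return False
            with open(path, encoding="utf-8") as fh:
                header = json.loads(fh.readline())
                if header.get("checksum") != want:
                    return False
                for line in fh:
                    if not line.strip():
                        continue
                    rec = json.loads(line)
                    w = WindowStats(
                        count=int(rec["count"]),
                        mean=float(rec["mean"]),
                        m2=float(rec["m2"]),
                        min_value=float(rec["min"]),
                        min_time=parse_ts(rec["min_time"]),
                        max_value=float(rec["max"]),
                        max_time=parse_ts(rec["max_time"]),
                        last_value=float(rec["last"]),
                        last_time=parse_ts(rec["last_time"]),
                    )
                    sd.windows[lvl][parse_ts(rec["start"])] = w
        return True

    def _rebuild_all(self, sd: _StreamData) -> None:
        for lvl in WindowLevel.aggregated():
            sd.windows[lvl].clear()
            sd.invalidate(lvl)
        levels = WindowLevel.aggregated()
        for t, v in zip(sd.ts.tolist(), sd.vs.tolist()):
            for lvl in levels:
                s = window_start(t, lvl)
                w = sd.windows[lvl].get(s)
                if w is None:
                    w = sd.windows[lvl][s] = WindowStats()
                w.add(t, v)
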