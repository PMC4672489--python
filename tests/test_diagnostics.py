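"""Daily QC detectors: planted faults must be found exactly (and nothing else)."""

import numpy as np
import pytest

from fieldstore import (
    DiagnosticConfig,
    DiagnosticReport,
    SensorStore,
    daily_report,
    detect_gaps,
    detect_range_violations,
)
from fieldstore.diagnostics import day_bounds

DAY = "2013-09-14"
T0, T1 = day_bounds(DAY)


def _store_with(streams: dict[str, list[tuple[int, float]]]) -> SensorStore:
    st = SensorStore()
    st.create_entity("user", "diag")
    st.create_entity("experiment", "wsn", "diag")
    st.create_entity("node", "mote", "diag~wsn")
    for name, pts in streams.items():
        st.create_entity("stream", name, "diag~wsn~mote", attrs={"unit": "degC"})
        if pts:
            st.append_points(f"diag~wsn~mote~{name}", pts)
    return st


def _regular(period=900, value=20.0):
    return [(t, value) for t in range(T0, T1, period)]


def test_regular_stream_has_no_gaps():
    st = _store_with({"ok": _regular()})
    assert detect_gaps(st, "diag~wsn~mote~ok", DAY, threshold=1800) == []


def test_one_missing_reading_is_one_gap():
    pts = [p for p in _regular() if p[0] != T0 + 10 * 900]  # drop the 10th slot
    st = _store_with({"s": pts})
    gaps = detect_gaps(st, "diag~wsn~mote~s", DAY, threshold=1200)
    assert len(gaps) == 1
    assert gaps[0].start == T0 + 9 * 900 and gaps[0].length == 1800


def test_day_boundary_gaps_count():
    # sensor silent until 02:00 and dead after 20:00
    pts = [(t, 1.0) for t in range(T0 + 7200, T0 + 72000, 900)]
    st = _store_with({"s": pts})
    gaps = detect_gaps(st, "diag~wsn~mote~s", DAY, threshold=3600)
    starts = {g.start for g in gaps}
    assert T0 in starts  # midnight -> first reading
    assert max(starts) == pts[-1][0]  # last reading -> midnight
    assert len(gaps) == 2


def test_empty_stream_yields_no_gaps():
    st = _store_with({"dead": []})
    assert detect_gaps(st, "diag~wsn~mote~dead", DAY, threshold=900) == []


def test_in_range_day_is_clean_and_touches_no_raw():
    st = _store_with({"s": _regular(value=25.0)})
    st.touch.reset()
    out = detect_range_violations(st, "diag~wsn~mote~s", DAY, -10.0, 60.0)
    assert out == []
    assert st.touch.raw_records_read == 0  # screened entirely from summaries


def test_three_planted_spikes_found_exactly():
    pts = _regular(value=25.0)
    spikes = {T0 + 3 * 900: -40.0, T0 + 40 * 900: 80.0, T0 + 77 * 900: 95.0}
    pts = [(t, spikes.get(t, v)) for t, v in pts]
    st = _store_with({"s": pts})
    out = detect_range_violations(st, "diag~wsn~mote~s", DAY, -10.0, 60.0)
    assert {(r.timestamp, r.value, r.bound) for r in out} == {
        (T0 + 3 * 900, -40.0, "min"),
        (T0 + 40 * 900, 80.0, "max"),
        (T0 + 77 * 900, 95.0, "max"),
    }


def test_bound_equal_to_value_is_not_a_violation():
    st = _store_with({"s": [(T0, 60.0), (T0 + 900, -10.0)]})
    assert detect_range_violations(st, "diag~wsn~mote~s", DAY, -10.0, 60.0) == []


def test_screening_equals_full_scan_with_fewer_touches():
    rng = np.random.default_rng(21)
    pts = [(t, float(v)) for t, v in zip(range(T0, T1, 60), rng.normal(20, 5, 1440))]
    pts[700] = (pts[700][0], 99.0)  # one spike
    st = _store_with({"s": pts})
    st.touch.reset()
    screened = detect_range_violations(st, "diag~wsn~mote~s", DAY, -10.0, 60.0)
    screened_raw = st.touch.raw_records_read
    full = [
        (t, v, "min" if v < -10.0 else "max")
        for t, v in pts
        if v < -10.0 or v > 60.0
    ]
    assert [(r.timestamp, r.value, r.bound) for r in screened] == full
    assert screened_raw <= 15  # only the flagged 15-min window was scanned


def test_daily_report_healthy_fixture_is_empty():
    st = _store_with({f"s{i}": _regular(value=20.0 + i) for i in range(5)})
    cfg = DiagnosticConfig(1800, -10.0, 60.0, DAY)
    rep = daily_report(st, "diag~wsn", cfg)
    assert rep.gap_errors == [] and rep.range_errors == [] and rep.missing_sensors == []


def test_daily_report_one_dead_one_gappy():
    """A 15-min deployment with one silent sensor and one gap: one finding each."""
    gappy = [p for p in _regular() if not (T0 + 36000 <= p[0] < T0 + 36000 + 2700)]
    st = _store_with({"healthy": _regular(), "gappy": gappy, "dead": []})
    cfg = DiagnosticConfig(gap_threshold=2000, min_allowed=-10.0, max_allowed=60.0, report_day=DAY)
    rep = daily_report(st, "diag~wsn", cfg)
    assert rep.missing_sensors == ["diag~wsn~mote~dead"]
    assert len(rep.gap_errors) == 1 and rep.gap_errors[0].stream.endswith("gappy")
    assert rep.range_errors == []
    # disjointness: a missing sensor never also reports a gap
    assert not any(g.stream.endswith("dead") for g in rep.gap_errors)


def test_report_json_round_trip():
    gappy = _regular()[:40]
    st = _store_with({"s": gappy})
    cfg = DiagnosticConfig(1800, -10.0, 60.0, DAY)
    rep = daily_report(st, "diag~wsn", cfg)
    again = DiagnosticReport.from_json(rep.to_json())
    assert again == rep
    assert "Diagnostic report" in rep.to_text()


def test_config_validation():
    with pytest.raises(ValueError):
        DiagnosticConfig(0, -10.0, 60.0, DAY)
    with pytest.raises(ValueError):
        DiagnosticConfig(900, 60.0, -10.0, DAY)


def test_detectors_perfect_precision_recall_on_random_planting():
    """Randomized fixtures with a planting record: precision = recall = 1.0."""
    rng = np.random.default_rng(42)
    streams: dict[str, list[tuple[int, float]]] = {}
    planted_gaps: dict[str, set[int]] = {}
    planted_spikes: dict[str, set[int]] = {}
    planted_dead: set[str] = set()
    for i in range(12):
        name = f"s{i:02d}"
        kind = rng.integers(0, 4)
        pts = _regular(value=20.0)
        if kind == 0:  # healthy
            streams[name] = pts
        elif kind == 1:  # dead
            streams[name] = []
            planted_dead.add(name)
        elif kind == 2:  # gaps
            s1 = int(rng.integers(5, 40))
            slots = [s1, int(rng.integers(s1 + 4, 90))]  # keep gaps disjoint
            drop = set()
            gaps = set()
            for s in slots:
                drop |= {T0 + s * 900, T0 + (s + 1) * 900}
                gaps.add(T0 + (s - 1) * 900)
            streams[name] = [p for p in pts if p[0] not in drop]
            planted_gaps[name] = gaps
        else:  # spikes
            slots = rng.choice(range(96), size=3, replace=False)
            spikes = {T0 + int(s) * 900 for s in slots}
            streams[name] = [
                (t, 200.0 if t in spikes else v) for t, v in pts
            ]
            planted_spikes[name] = spikes
    st = _store_with(streams)
    cfg = DiagnosticConfig(gap_threshold=1000, min_allowed=-10.0, max_allowed=60.0, report_day=DAY)
    rep = daily_report(st, "diag~wsn", cfg)

    got_dead = {s.split("~")[-1] for s in rep.missing_sensors}
    assert got_dead == planted_dead
    got_gaps: dict[str, set[int]] = {}
    for g in rep.gap_errors:
        got_gaps.setdefault(g.stream.split("~")[-1], set()).add(g.start)
    assert got_gaps == planted_gaps
    got_spikes: dict[str, set[int]] = {}
    for r in rep.range_errors:
        got_spikes.setdefault(r.stream.split("~")[-1], set()).add(r.timestamp)
    assert got_spikes == planted_spikes
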