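"""Ingest, window maintenance, query contracts and durability of the store."""

import math

import numpy as np
import pytest

from fieldstore import NoSuchEntityError, SensorStore, WindowLevel, stats_std
from fieldstore.synth import brute_force_aggregate

from conftest import random_points


def _assert_matches_oracle(store, stream, points, levels=None, rel=1e-9):
    ts = np.asarray([p[0] for p in points], dtype=np.int64)
    vs = np.asarray([p[1] for p in points], dtype=np.float64)
    for lvl in levels or WindowLevel.aggregated():
        got = store.get_window_stats(stream, lvl, 0, 2**62)
        want = brute_force_aggregate(ts, vs, lvl)
        assert len(got) == len(want)
        for (s, w), o in zip(got, want):
            assert s == o.start and w.count == o.count
            assert w.min_value == o.min_value and w.min_time == o.min_time
            assert w.max_value == o.max_value and w.max_time == o.max_time
            assert w.last_value == o.last_value and w.last_time == o.last_time
            assert w.mean == pytest.approx(o.mean, rel=rel, abs=1e-12)
            assert stats_std(w) == pytest.approx(o.std, rel=rel, abs=1e-9)


def test_append_updates_every_level(one_stream_store):
    st = one_stream_store
    pts = [(t, math.sin(t / 500.0)) for t in range(0, 100 * 60, 60)]
    rep = st.append_points("u~e~n~s", pts)
    assert rep.accepted == 100 and rep.rejected == 0
    hours = st.get_window_stats("u~e~n~s", WindowLevel.HOUR1, 0, 2**62)
    assert len(hours) == len({t // 3600 for t, _ in pts})
    _assert_matches_oracle(st, "u~e~n~s", pts)


def test_unknown_stream_and_policy_errors(one_stream_store):
    with pytest.raises(NoSuchEntityError):
        one_stream_store.append_points("u~e~n~ghost", [(0, 1.0)])
    with pytest.raises(ValueError, match="duplicate policy"):
        one_stream_store.append_points("u~e~n~s", [(0, 1.0)], duplicate_policy="upsert")


def test_nan_rejected_with_reason(one_stream_store):
    rep = one_stream_store.append_points("u~e~n~s", [(0, float("nan"))])
    assert rep.accepted == 0 and rep.rejected == 1
    assert rep.errors[0][1] == "non-finite value rejected"
    assert one_stream_store.raw_count("u~e~n~s") == 0


def test_replace_reingest_is_idempotent(one_stream_store):
    st = one_stream_store
    rng = np.random.default_rng(11)
    pts = random_points(rng, 400, t_max=40 * 86400)
    st.append_points("u~e~n~s", pts)
    before = {
        lvl: [(s, w.__dict__.copy()) for s, w in st.get_window_stats("u~e~n~s", lvl, 0, 2**62)]
        for lvl in WindowLevel.aggregated()
    }
    rep = st.append_points("u~e~n~s", pts, duplicate_policy="replace")
    assert rep.accepted == 400
    assert st.raw_count("u~e~n~s") == 400
    for lvl in WindowLevel.aggregated():
        after = [(s, w.__dict__.copy()) for s, w in st.get_window_stats("u~e~n~s", lvl, 0, 2**62)]
        assert after == before[lvl]


def test_replace_with_new_values_rebuilds_exactly(one_stream_store):
    st = one_stream_store
    rng = np.random.default_rng(3)
    pts = random_points(rng, 300, t_max=100 * 86400)
    st.append_points("u~e~n~s", pts)
    changed = pts.copy()
    changed[:50, 1] += 100.0  # overwrite 50 stamps with new values
    st.append_points("u~e~n~s", changed[:50], duplicate_policy="replace")
    final = {int(t): float(v) for t, v in pts}
    final.update({int(t): float(v) for t, v in changed[:50]})
    _assert_matches_oracle(st, "u~e~n~s", sorted(final.items()))


def test_reject_policy_reports_duplicates(one_stream_store):
    st = one_stream_store
    st.append_points("u~e~n~s", [(0, 1.0), (60, 2.0)])
    rep = st.append_points("u~e~n~s", [(0, 9.0), (120, 3.0)], duplicate_policy="reject")
    assert rep.accepted == 1 and rep.rejected == 1
    assert any(r == "duplicate timestamp" for _, r in rep.errors)
    # the stored value at t=0 is untouched
    assert st.get_raw("u~e~n~s", 0, 1)[0].value == 1.0


def test_get_raw_half_open_and_sorted(one_stream_store):
    st = one_stream_store
    pts = [(t, float(t)) for t in range(0, 120)]
    rng = np.random.default_rng(5)
    shuffled = np.array(pts)[rng.permutation(len(pts))]
    st.append_points("u~e~n~s", shuffled)
    got = st.get_raw("u~e~n~s", 0, 60)
    assert len(got) == 60
    assert [p.timestamp for p in got] == list(range(60))
    assert st.get_raw("u~e~n~s", 500, 600) == []
    with pytest.raises(ValueError, match="empty range"):
        st.get_raw("u~e~n~s", 10, 5)


def test_out_of_order_ingest_equals_in_order(one_stream_store):
    st = one_stream_store
    pts = [(t, math.cos(t / 100.0)) for t in range(0, 7200, 30)]
    rng = np.random.default_rng(2)
    order = rng.permutation(len(pts))
    st.append_points("u~e~n~s", [pts[i] for i in order[:100]])
    st.append_points("u~e~n~s", [pts[i] for i in order[100:]])
    _assert_matches_oracle(st, "u~e~n~s", pts)
    assert [p.timestamp for p in st.get_raw("u~e~n~s", 0, 2**62)] == sorted(
        t for t, _ in pts
    )


def test_window_query_range_concatenation(one_stream_store):
    st = one_stream_store
    rng = np.random.default_rng(8)
    st.append_points("u~e~n~s", random_points(rng, 500, t_max=3 * 86400))
    mid = 86400
    a = st.get_window_stats("u~e~n~s", WindowLevel.HOUR1, 0, mid)
    b = st.get_window_stats("u~e~n~s", WindowLevel.HOUR1, mid, 3 * 86400)
    whole = st.get_window_stats("u~e~n~s", WindowLevel.HOUR1, 0, 3 * 86400)
    assert [s for s, _ in a] + [s for s, _ in b] == [s for s, _ in whole]


def test_preaggregation_contract_touch_counts(one_stream_store):
    st = one_stream_store
    rng = np.random.default_rng(4)
    st.append_points("u~e~n~s", random_points(rng, 1000, t_max=10 * 86400))
    st.touch.reset()
    wins = st.get_window_stats("u~e~n~s", WindowLevel.DAY1, 0, 10 * 86400)
    assert st.touch.raw_records_read == 0
    assert st.touch.summary_records_read == len(wins)
    st.touch.reset()
    k = len(st.get_raw("u~e~n~s", 0, 2 * 86400))
    assert st.touch.raw_records_read == k


def test_window_coverage_conservation(one_stream_store):
    """Each point lands in exactly one window per level: counts sum to raw count."""
    st = one_stream_store
    rng = np.random.default_rng(9)
    st.append_points("u~e~n~s", random_points(rng, 800))
    for lvl in WindowLevel.aggregated():
        total = sum(w.count for _, w in st.get_window_stats("u~e~n~s", lvl, 0, 2**62))
        assert total == 800


def test_stream_summary_conservation_and_single_point(one_stream_store):
    st = one_stream_store
    st.append_points("u~e~n~s", [(1000, 42.0)])
    rows = st.stream_summary("u~e~n~s")
    for label, w in rows.items():
        assert w.count == 1, label
        assert stats_std(w) == 0.0
        assert w.last_value == 42.0
    rng = np.random.default_rng(6)
    st.append_points("u~e~n~s", random_points(rng, 250))
    rows = st.stream_summary("u~e~n~s")
    assert all(w.count == st.raw_count("u~e~n~s") for w in rows.values())


def test_summary_changes_only_where_affected(one_stream_store):
    st = one_stream_store
    st.append_points("u~e~n~s", [(t, 10.0) for t in range(0, 3600, 60)])
    before = st.stream_summary("u~e~n~s")
    st.append_points("u~e~n~s", [(7200, 99.0)])  # a later, larger point
    after = st.stream_summary("u~e~n~s")
    for label in after:
        assert after[label].count == before[label].count + 1
        assert after[label].max_value == 99.0
        assert after[label].min_value == before[label].min_value


def test_persistence_round_trip(tmp_path, one_stream_store):
    st = one_stream_store
    rng = np.random.default_rng(10)
    pts = random_points(rng, 600)
    st.append_points("u~e~n~s", pts)
    st.save(tmp_path / "store")
    again = SensorStore.load(tmp_path / "store")
    assert again.get_raw("u~e~n~s", 0, 2**62) == st.get_raw("u~e~n~s", 0, 2**62)
    for lvl in WindowLevel.aggregated():
        a = st.get_window_stats("u~e~n~s", lvl, 0, 2**62)
        b = again.get_window_stats("u~e~n~s", lvl, 0, 2**62)
        assert [(s, w.__dict__) for s, w in a] == [(s, w.__dict__) for s, w in b]


def test_tampered_summaries_rebuilt_from_raw(tmp_path, one_stream_store):
    st = one_stream_store
    st.append_points("u~e~n~s", [(t, float(t % 7)) for t in range(0, 1800, 60)])
    root = tmp_path / "store"
    st.save(root)
    agg = root / "agg" / "u~e~n~s.1-hour.jsonl"
    agg.write_text('{"checksum": "bogus"}\n')  # corrupt one summary file
    again = SensorStore.load(root)
    a = st.get_window_stats("u~e~n~s", WindowLevel.HOUR1, 0, 2**62)
    b = again.get_window_stats("u~e~n~s", WindowLevel.HOUR1, 0, 2**62)
    assert [(s, w.__dict__) for s, w in a] == [(s, w.__dict__) for s, w in b]
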