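"""Event detection, per-cell/per-slice summaries, condition contrasts."""

import numpy as np
import pytest

from astroplast import (
    CalciumSimParams,
    PopulationGroup,
    compare_conditions,
    detect_events,
    generate_population,
    summarize_cell,
    summarize_slice,
)
from oracles import brute_force_events


def _random_trace(rng, n=200):
    x = rng.normal(0, 0.01, n)
    for _ in range(rng.integers(0, 6)):
        i = rng.integers(10, n - 10)
        x[i:i + rng.integers(1, 8)] += rng.uniform(0.05, 0.6)
    return x


class TestDetectEvents:
    def test_constant_zero_trace_no_events(self):
        assert detect_events(np.zeros(100), 1.0) == []

    def test_rectangular_pulse_detected(self, rng):
        x = rng.normal(0, 0.01, 60)
        x[20:25] += 0.5
        events = detect_events(x, 1.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_amp == pytest.approx(0.5, abs=0.05)
        assert ev.duration_s >= 5 - 2  # boundary samples may sit in noise
        assert ev.start_s <= 20 <= ev.peak_time_s < ev.end_s

    def test_short_pulse_below_minimum_duration(self, rng):
        x = rng.normal(0, 0.01, 60)
        x[20:22] += 0.5
        assert detect_events(x, 1.0, min_duration_s=3.0) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_scanner_exactly(self, seed):
        rng = np.random.default_rng(seed)
        x = _random_trace(rng)
        events = detect_events(x, 1.0, cell_id="c")
        expected = brute_force_events(x, 1.0)
        assert len(events) == len(expected)
        for ev, (i0, i1, pk, ipk) in zip(events, expected):
            assert ev.start_s == i0
            assert ev.end_s == i1
            assert ev.peak_amp == pk
            assert ev.peak_time_s == ipk

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_threshold_and_duration(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = _random_trace(rng)
        n2 = len(detect_events(x, 1.0, k_event=2.0))
        n3 = len(detect_events(x, 1.0, k_event=3.0))
        assert n3 <= n2
        d3 = len(detect_events(x, 1.0, min_duration_s=3.0))
        d5 = len(detect_events(x, 1.0, min_duration_s=5.0))
        assert d5 <= d3

    def test_event_touching_end_kept(self):
        x = np.concatenate([np.random.default_rng(0).normal(0, 0.01, 50),
                            np.full(4, 0.5)])
        events = detect_events(x, 1.0)
        assert len(events) == 1
        assert events[0].end_s == len(x)

    def test_degenerate_baseline_warns(self):
        x = np.zeros(60)
        x[30:40] = 1.0
        with pytest.warns(RuntimeWarning, match="zero baseline SD"):
            events = detect_events(x, 1.0)
        assert len(events) == 1  # threshold degenerates to baseline mean

    def test_trace_not_longer_than_baseline_rejected(self):
        with pytest.raises(ValueError):
            detect_events(np.zeros(10), 1.0, baseline_window_s=10.0)


class TestSummaries:
    def test_nonresponder_cell(self):
        s = summarize_cell([], {"cell_id": "a", "class_label": "mcherry_pos",
                                "lamina": "I"}, window_s=600.0)
        assert not s.responder
        assert s.n_events == 0
        assert s.event_rate == 0.0
        assert s.mean_peak_amp is None

    def test_rate_and_mean_peak_arithmetic(self, rng):
        x = rng.normal(0, 0.01, 600)
        for i, amp in zip((100, 300, 500), (0.2, 0.4, 0.6)):
            x[i:i + 5] = amp
        events = detect_events(x, 1.0, cell_id="a")
        s = summarize_cell(events, {"cell_id": "a", "class_label": "mcherry_neg",
                                    "lamina": "II"}, window_s=600.0)
        assert s.n_events == 3
        assert s.event_rate == pytest.approx(0.3)
        assert s.mean_peak_amp == pytest.approx(0.4, abs=0.02)
        assert s.responder

    def test_slice_class_means(self):
        from astroplast.events import CellEventSummary
        cells = [
            CellEventSummary(cell_id="a0", class_label="mcherry_pos",
                             lamina="I", n_events=10, event_rate=1.0,
                             mean_peak_amp=0.5, responder=True, window_s=600.0),
            CellEventSummary(cell_id="a1", class_label="mcherry_pos",
                             lamina="I", n_events=30, event_rate=3.0,
                             mean_peak_amp=0.3, responder=True, window_s=600.0),
        ]
        s = summarize_slice(cells, "s1")
        st = s.get("mcherry_pos", "I")
        assert st.mean_event_rate == pytest.approx(2.0)
        assert st.mean_peak_amp == pytest.approx(0.4)
        assert st.n_cells == 2
        assert st.n_responders == 2

    def test_all_nonresponders_peak_is_none(self):
        cells = [summarize_cell([], {"cell_id": f"c{i}",
                                     "class_label": "mcherry_neg",
                                     "lamina": "II"}, window_s=60.0)
                 for i in range(3)]
        s = summarize_slice(cells, "s1")
        st = s.get("mcherry_neg", "II")
        assert st.n_responders == 0
        assert st.mean_peak_amp is None

    def test_event_conservation_across_cells(self):
        groups = [PopulationGroup(
            "mcherry_neg", CalciumSimParams(n_cells=10, event_rate=2.0,
                                            duration=300.0, seed=21))]
        _, _, truth = generate_population(groups)
        assert (sum(c.n_events for c in truth.cells)
                == len([e for c in truth.cells for e in c.events]))

    def test_empty_slice_rejected(self):
        with pytest.raises(ValueError):
            summarize_slice([], "s1")


def _slice_from_rates(slice_id, rates_by_stratum, peak=0.5):
    """Build a SliceSummary from {(class, lamina): rate} via cell summaries."""
    from astroplast.events import CellEventSummary
    cells = []
    for (cls, lam), rate in rates_by_stratum.items():
        n = int(round(rate * 10))
        cells.append(CellEventSummary(
            cell_id=f"{slice_id}_{cls}_{lam}", class_label=cls, lamina=lam,
            n_events=n, event_rate=rate, mean_peak_amp=peak if n else None,
            responder=n > 0, window_s=600.0))
    return summarize_slice(cells, slice_id)


class TestCompareConditions:
    def test_identical_conditions_null_contrast(self):
        slices = [_slice_from_rates(f"s{i}", {("mcherry_neg", "I"): 1.0 + 0.1 * i})
                  for i in range(3)]
        table = compare_conditions(slices, slices, n_boot=200)
        rate = table[table.metric == "event_rate"]
        assert np.allclose(rate["diff"], 0.0)
        assert np.allclose(rate["ratio"], 1.0)

    def test_single_pair_degenerate_flagged(self):
        pre = [_slice_from_rates("s0", {("mcherry_neg", "I"): 1.0})]
        post = [_slice_from_rates("s0", {("mcherry_neg", "I"): 2.0})]
        table = compare_conditions(pre, post, n_boot=50)
        assert table["degenerate"].all()
        row = table[(table.metric == "event_rate")
                    & (table.class_label == "mcherry_neg")
                    & (table.lamina == "I")].iloc[0]
        assert row["ratio"] == pytest.approx(2.0)
        assert row["ratio_lo"] == row["ratio_hi"] == row["ratio"]

    def test_unmatched_slice_ids_rejected(self):
        pre = [_slice_from_rates("s0", {("mcherry_neg", "I"): 1.0})]
        post = [_slice_from_rates("s1", {("mcherry_neg", "I"): 1.0})]
        with pytest.raises(ValueError, match="unmatched"):
            compare_conditions(pre, post)

    def test_targeted_rate_doubling_isolated(self):
        """Doubling the rate only in mcherry_neg lamina I shows up as a
        ratio ~2 in that stratum and ~1 in the untouched stratum."""
        rng = np.random.default_rng(5)
        pre, post = [], []
        for i in range(6):
            base = {("mcherry_neg", "I"): 1.0 + rng.normal(0, 0.05),
                    ("mcherry_pos", "I"): 1.0 + rng.normal(0, 0.05)}
            pre.append(_slice_from_rates(f"s{i}", base))
            bumped = dict(base)
            bumped[("mcherry_neg", "I")] = 2.0 * base[("mcherry_neg", "I")]
            post.append(_slice_from_rates(f"s{i}", bumped))
        table = compare_conditions(pre, post, n_boot=500)
        t = table[table.metric == "event_rate"].set_index(["class_label", "lamina"])
        assert t.loc[("mcherry_neg", "I"), "ratio"] == pytest.approx(2.0, abs=0.05)
        assert t.loc[("mcherry_pos", "I"), "ratio"] == pytest.approx(1.0, abs=0.05)

    def test_bootstrap_seeded(self):
        pre = [_slice_from_rates(f"s{i}", {("mcherry_neg", "I"): 1.0 + 0.2 * i})
               for i in range(4)]
        post = [_slice_from_rates(f"s{i}", {("mcherry_neg", "I"): 1.5 + 0.2 * i})
                for i in range(4)]
        t1 = compare_conditions(pre, post, n_boot=200, seed=3)
        t2 = compare_conditions(pre, post, n_boot=200, seed=3)
        assert t1.equals(t2)
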