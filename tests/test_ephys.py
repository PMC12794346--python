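"""Evoked-response normalization, fiber/synapse classification, QC,
spontaneous-trace binning."""

import numpy as np
import pandas as pd
import pytest

from astroplast import (
    FiberObservation,
    SpontaneousTrace,
    SpontaneousTraceSet,
    SweepSeries,
    SweepSimParams,
    bin_spontaneous,
    classify_fiber,
    classify_monosynaptic,
    generate_sweep_series,
    normalize_evoked,
    normalize_field_auc,
    paired_pulse_ratio,
    qc_series_resistance,
)
from astroplast.ephys import BaselineSpec


def _series(values, kind="evoked_epsc", treatment_time_s=None, interval=15.0,
            baseline_n=None):
    n = len(values)
    df = pd.DataFrame({"sweep_index": np.arange(n),
                       "time_s": np.arange(n) * interval,
                       "value": values})
    spec = BaselineSpec(baseline_n) if baseline_n else None
    if treatment_time_s is None:
        treatment_time_s = (8 - 0.5) * interval
    return SweepSeries(sweeps=df, kind=kind, treatment_time_s=treatment_time_s,
                       baseline_spec=spec)


class TestNormalization:
    def test_step_depression(self):
        s = _series([100.0] * 8 + [70.0] * 4)
        df, stats = normalize_evoked(s)
        assert stats["baseline_mean"] == 100.0
        np.testing.assert_allclose(df["normalized"][:8], 1.0)
        np.testing.assert_allclose(df["normalized"][8:], 0.70)

    def test_identity_series_all_ones(self):
        s = _series([100.0] * 12)
        df, _ = normalize_evoked(s)
        np.testing.assert_allclose(df["normalized"], 1.0)

    def test_baseline_uses_last_8_by_timestamp(self):
        """Earlier pre-treatment sweeps beyond the last 8 do not enter the
        baseline."""
        s = _series([999.0] * 4 + [100.0] * 8 + [50.0] * 4,
                    treatment_time_s=(12 - 0.5) * 15.0)
        df, stats = normalize_evoked(s)
        assert stats["baseline_mean"] == 100.0
        np.testing.assert_allclose(df["normalized"].iloc[-4:], 0.5)

    def test_field_auc_uses_5(self):
        s = _series([1.0] * 5 + [1.5] * 3, kind="field_auc",
                    treatment_time_s=(5 - 0.5) * 15.0)
        df, stats = normalize_field_auc(s)
        assert stats["n_baseline"] == 5
        np.testing.assert_allclose(df["normalized"].iloc[-3:], 1.5)

    def test_too_few_baseline_sweeps_rejected(self):
        s = _series([100.0] * 5 + [70.0] * 4, treatment_time_s=(5 - 0.5) * 15.0)
        with pytest.raises(ValueError, match="pre-treatment"):
            normalize_evoked(s)

    def test_nonpositive_baseline_rejected(self):
        s = _series([0.0] * 8 + [70.0] * 4)
        with pytest.raises(ValueError, match="baseline mean"):
            normalize_evoked(s)

    def test_idempotent(self):
        s = _series([100.0, 90.0, 110.0, 95.0, 105.0, 100.0, 98.0, 102.0,
                     60.0, 65.0])
        df1, _ = normalize_evoked(s)
        s2 = _series(df1["normalized"].tolist())
        df2, stats2 = normalize_evoked(s2)
        assert stats2["baseline_mean"] == pytest.approx(1.0)
        np.testing.assert_allclose(df2["normalized"], df1["normalized"])

    def test_scale_invariance(self):
        vals = [100.0, 90.0, 110.0, 95.0, 105.0, 100.0, 98.0, 102.0, 60.0]
        df1, _ = normalize_evoked(_series(vals))
        df2, _ = normalize_evoked(_series([13.7 * v for v in vals]))
        np.testing.assert_allclose(df2["normalized"], df1["normalized"],
                                   rtol=1e-12)

    def test_recovery_of_effect_ratio(self):
        """Post/baseline normalized mean recovers the injected step within
        3 SEM at noise_cv 0.1 over 50 series."""
        means = []
        for seed in range(50):
            series, _ = generate_sweep_series(SweepSimParams(
                effect_ratio=0.6, noise_cv=0.1, n_post_sweeps=24, seed=seed))
            df, _ = normalize_evoked(series)
            means.append(df["normalized"].iloc[8:].mean())
        means = np.asarray(means)
        sem = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 0.6) <= 3 * sem + 1e-3


class TestClassification:
    @pytest.mark.parametrize("latency,distance,follows,expected", [
        (0.02, 0.005, False, "C"),            # cv 0.25 m/s
        (0.01, 0.005, False, "A"),            # cv exactly 0.5: strict rule
        (0.02, 0.005, True, "excluded_A_follows_10hz"),
        (0.001, 0.005, False, "A"),           # cv 5 m/s
        (None, None, False, "unclassified"),
    ])
    def test_fiber_rules(self, latency, distance, follows, expected):
        obs = FiberObservation(latency_s=latency,
                               conduction_distance_m=distance,
                               follows_10hz=follows)
        assert classify_fiber(obs) == expected

    def test_nonpositive_measurements_rejected(self):
        with pytest.raises(ValueError):
            FiberObservation(latency_s=-0.01, conduction_distance_m=0.005)
        with pytest.raises(ValueError):
            FiberObservation(latency_s=0.01, conduction_distance_m=0.0)

    @pytest.mark.parametrize("jitter,failures,expected", [
        (0.0, 0, True),
        (0.0005, 0, True),
        (0.001, 0, True),    # boundary: tolerance inclusive
        (0.002, 0, False),
        (0.0, 1, False),
    ])
    def test_monosynaptic_rules(self, jitter, failures, expected):
        obs = FiberObservation(latency_s=0.02, conduction_distance_m=0.005,
                               failures_at_1hz=failures)
        assert classify_monosynaptic(obs, latency_jitter_s=jitter) is expected

    def test_ppr(self):
        assert paired_pulse_ratio(100.0, 100.0) == 1.0
        assert paired_pulse_ratio(100.0, 150.0) == 1.5
        with pytest.raises(ValueError):
            paired_pulse_ratio(0.0, 100.0)

    def test_ppr_identity_on_noiseless_pairs(self):
        for r in (0.5, 0.8, 1.2):
            amps1 = np.array([80.0, 100.0, 120.0])
            ratios = [paired_pulse_ratio(a, r * a) for a in amps1]
            assert ratios == pytest.approx([r] * 3)


class TestSeriesResistanceQC:
    def test_constant_passes(self):
        assert qc_series_resistance([15.0] * 10).passed

    def test_limit_breach_fails_with_reason(self):
        res = qc_series_resistance([20.0, 27.0])
        assert not res.passed
        assert "25" in res.reason and "sample 1" in res.reason

    def test_change_just_below_30pct_passes(self):
        assert qc_series_resistance([15.0, 19.0]).passed  # 26.7%

    def test_change_exactly_30pct_passes(self):
        assert qc_series_resistance([10.0, 13.0]).passed  # "more than 30%"

    def test_change_above_30pct_fails(self):
        res = qc_series_resistance([10.0, 13.1])
        assert not res.passed
        assert "%" in res.reason

    def test_running_reference_mode(self):
        res = qc_series_resistance([10.0, 10.2, 10.1, 14.0],
                                   reference="running")
        assert not res.passed
        assert "running" in res.reason

    def test_errors(self):
        with pytest.raises(ValueError):
            qc_series_resistance([15.0])
        with pytest.raises(ValueError):
            qc_series_resistance([15.0, -1.0])


class TestSpontaneousBinning:
    def _tset(self, events_per_trace, n_traces=20, spacing=30.0):
        traces = [SpontaneousTrace(trace_id=f"t{i}", start_s=i * spacing,
                                   events=list(events_per_trace))
                  for i in range(n_traces)]
        return SpontaneousTraceSet(traces)

    def test_events_in_discard_window_dropped(self):
        tset = self._tset([(2.0, 10.0), (4.9, 12.0)])
        out = bin_spontaneous(tset)
        assert (out["rate_hz"] == 0.0).all()
        assert out["mean_amplitude"].isna().all()

    def test_rate_arithmetic(self):
        """One kept event per 10-s analyzed segment, 10 traces per 300-s
        bin -> 0.1 events/s."""
        tset = self._tset([(7.0, 15.0)], n_traces=20, spacing=30.0)
        out = bin_spontaneous(tset)
        assert len(out) == 2
        np.testing.assert_allclose(out["rate_hz"], 0.1)
        np.testing.assert_allclose(out["mean_amplitude"], 15.0)
        np.testing.assert_allclose(out["rate_norm"], 1.0)

    def test_first_bin_is_baseline(self):
        tset = self._tset([(7.0, 15.0)], n_traces=40, spacing=30.0)
        out = bin_spontaneous(tset)
        assert out.loc[0, "is_baseline"]
        assert not out.loc[1:, "is_baseline"].any()

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(8)
        traces = [SpontaneousTrace(trace_id=f"t{i}", start_s=i * 30.0,
                                   events=[(float(rng.uniform(0, 15)), 10.0)
                                           for _ in range(3)])
                  for i in range(30)]
        out1 = bin_spontaneous(SpontaneousTraceSet(list(traces)))
        shuffled = list(traces)
        rng.shuffle(shuffled)
        out2 = bin_spontaneous(SpontaneousTraceSet(shuffled))
        pd.testing.assert_frame_equal(out1, out2)

    def test_short_trace_rejected(self):
        tset = SpontaneousTraceSet(
            [SpontaneousTrace(trace_id="t0", start_s=0.0, duration_s=4.0)])
        with pytest.raises(ValueError, match="discard"):
            bin_spontaneous(tset)
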