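"""Evoked- and spontaneous-response analysis rules for patch-clamp and
in vivo field-potential recordings.

Implements the quantification conventions of dorsal horn synaptic
plasticity experiments around a treatment time point (bath CNO in vitro,
CNO injection or conditioning nerve stimulation in vivo):

* evoked EPSC amplitudes normalized to the mean of the last 8 sweeps
  (2 minutes) before treatment;
* C-fiber-evoked field potential areas normalized to the mean of the 5
  consecutive responses before treatment;
* afferent fiber classification from conduction velocity (C-fiber iff
  cv < 0.5 m/s, strictly), with EPSCs that reliably follow 10-Hz
  stimulation excluded as A-fiber-evoked regardless of velocity;
* monosynaptic identification from constant latency and absence of
  failures at 1-Hz stimulation;
* paired-pulse ratio;
* series-resistance quality control (< 25 MΩ and change <= 30%);
* spontaneous PSC traces (15 s each) with the first 5 s discarded,
  binned at 5 minutes with the first bin as baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import check_finite

EVOKED_EPSC = "evoked_epsc"
FIELD_AUC = "field_auc"

#: baseline length (number of pre-treatment responses) per recording kind
DEFAULT_BASELINE_N = {EVOKED_EPSC: 8, FIELD_AUC: 5}


@dataclass
class BaselineSpec:
    """How many pre-treatment responses define the baseline."""
    n_sweeps: int
    window_s: Optional[float] = None


@dataclass
class SweepSeries:
    """Time-ordered evoked-response measurements around a treatment.

    ``sweeps`` columns: ``sweep_index``, ``time_s``, ``value`` (peak
    amplitude in pA for evoked EPSCs, or field-potential AUC), and
    optionally ``latency_s`` and ``rs_mohm``.
    """

    sweeps: pd.DataFrame
    kind: str
    treatment_time_s: float
    baseline_spec: Optional[BaselineSpec] = None
    series_id: str = "series"

    def __post_init__(self) -> None:
        if self.kind not in (EVOKED_EPSC, FIELD_AUC):
            raise ValueError(f"unknown series kind {self.kind!r}")
        df = self.sweeps
        for col in ("sweep_index", "time_s", "value"):
            if col not in df.columns:
                raise ValueError(f"sweep table missing column {col!r}")
        t = df["time_s"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
            raise ValueError("sweep times must be finite and strictly increasing")
        if np.any(~np.isfinite(df["value"].to_numpy(dtype=float))):
            raise ValueError("sweep values must be finite")
        if self.baseline_spec is None:
            self.baseline_spec = BaselineSpec(DEFAULT_BASELINE_N[self.kind])


@dataclass
class FiberObservation:
    """Measurements used to classify an afferent input.

    ``latency_s`` is the time from the stimulation artefact to the onset
    of the inward current; conduction velocity is
    ``conduction_distance_m / latency_s``.
    """

    latency_s: Optional[float] = None
    conduction_distance_m: Optional[float] = None
    follows_10hz: bool = False
    constant_latency: Optional[bool] = None
    failures_at_1hz: int = 0
    latency_jitter_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.latency_s is not None and self.latency_s <= 0:
            raise ValueError("latency_s must be > 0")
        if self.conduction_distance_m is not None and self.conduction_distance_m <= 0:
            raise ValueError("conduction_distance_m must be > 0")
        if self.failures_at_1hz < 0:
            raise ValueError("failures_at_1hz must be >= 0")

    @property
    def conduction_velocity(self) -> Optional[float]:
        if self.latency_s is None or self.conduction_distance_m is None:
            return None
        return self.conduction_distance_m / self.latency_s


@dataclass
class SpontaneousTrace:
    """One 15-s sweep of spontaneous PSCs with event times within the trace."""
    trace_id: str
    start_s: float
    duration_s: float = 15.0
    events: List[Tuple[float, float]] = field(default_factory=list)  # (t_in_trace, amp)


@dataclass
class SpontaneousTraceSet:
    traces: List[SpontaneousTrace]
    bin_s: float = 300.0


@dataclass
class QCResult:
    passed: bool
    reason: Optional[str] = None


def _normalize(series: SweepSeries, n_baseline: int) -> Tuple[pd.DataFrame, Dict]:
    df = series.sweeps
    t = df["time_s"].to_numpy(dtype=float)
    pre = np.flatnonzero(t < series.treatment_time_s)
    if pre.size < n_baseline:
        raise ValueError(
            f"{series.series_id}: {pre.size} pre-treatment sweeps, "
            f"need at least {n_baseline}"
        )
    base_idx = pre[-n_baseline:]  # the n responses immediately preceding treatment
    base_mean = float(df["value"].to_numpy(dtype=float)[base_idx].mean())
    if base_mean <= 0:
        raise ValueError(f"{series.series_id}: baseline mean {base_mean} <= 0")
    out = df.copy()
    out["normalized"] = out["value"] / base_mean
    stats = {
        "baseline_mean": base_mean,
        "n_baseline": n_baseline,
        "baseline_sweep_indices": df["sweep_index"].to_numpy()[base_idx].tolist(),
    }
    return out, stats


def normalize_evoked(series: SweepSeries) -> Tuple[pd.DataFrame, Dict]:
    """Normalize evoked EPSC amplitudes to the mean of the last 8 sweeps
    (2 minutes) before the treatment time.

    Baseline sweeps are the 8 closest to the treatment by timestamp, not
    by index, so dropped sweeps are tolerated.  The normalized mean over
    the baseline sweeps is 1 by construction.
    """
    n = series.baseline_spec.n_sweeps if series.baseline_spec else 8
    return _normalize(series, n)


def normalize_field_auc(series: SweepSeries) -> Tuple[pd.DataFrame, Dict]:
    """Normalize field-potential AUC to the mean of the 5 consecutive
    responses immediately preceding the treatment time."""
    n = series.baseline_spec.n_sweeps if series.baseline_spec else 5
    return _normalize(series, n)


def classify_fiber(obs: FiberObservation) -> str:
    """Classify an afferent input: ``"C"``, ``"A"``,
    ``"excluded_A_follows_10hz"``, or ``"unclassified"``.

    An EPSC that reliably follows 10-Hz stimulation is A-fiber-evoked and
    excluded regardless of conduction velocity.  Otherwise the fiber is a
    C-fiber iff conduction velocity is strictly below 0.5 m/s; at or above
    0.5 m/s it is an A-fiber.  Missing latency or distance (without the
    10-Hz flag) yields ``"unclassified"``.
    """
    if obs.follows_10hz:
        return "excluded_A_follows_10hz"
    cv = obs.conduction_velocity
    if cv is None:
        return "unclassified"
    return "C" if cv < 0.5 else "A"


def classify_monosynaptic(
    obs: FiberObservation,
    latency_jitter_s: Optional[float] = None,
    jitter_tol_s: float = 0.001,
) -> bool:
    """Monosynaptic iff no failures at 1-Hz stimulation and latency jitter
    within tolerance (default 1 ms, quantifying "constant latency")."""
    jitter = latency_jitter_s if latency_jitter_s is not None else obs.latency_jitter_s
    if jitter is None:
        raise ValueError("latency jitter not supplied")
    if jitter < 0:
        raise ValueError("latency jitter must be >= 0")
    return obs.failures_at_1hz == 0 and jitter <= jitter_tol_s


def paired_pulse_ratio(amp1: float, amp2: float) -> float:
    """Second/first evoked amplitude ratio (presynaptic release-probability
    proxy)."""
    check_finite("amp1", amp1)
    check_finite("amp2", amp2)
    if amp1 <= 0:
        raise ValueError("amp1 must be > 0")
    return amp2 / amp1


def qc_series_resistance(
    rs_series: Sequence[float],
    rs_max: float = 25.0,
    max_change_frac: float = 0.30,
    reference: str = "first",
) -> QCResult:
    """Series-resistance quality control.

    A recording fails if any Rs sample reaches ``rs_max`` (25 MΩ), or if
    Rs changes by more than ``max_change_frac`` (30%).  The change is
    measured as (max − min) relative to the first recorded value
    (``reference="first"``), or, with ``reference="running"``, each sample
    is compared against the running mean of all preceding samples.  The
    failure reason names the violated rule and the sample index.
    """
    rs = np.asarray(rs_series, dtype=float)
    if rs.size < 2:
        raise ValueError("need at least 2 Rs samples")
    if np.any(~np.isfinite(rs)) or np.any(rs <= 0):
        raise ValueError("Rs samples must be finite and positive")
    if reference not in ("first", "running"):
        raise ValueError("reference must be 'first' or 'running'")

    for i, v in enumerate(rs):
        if v >= rs_max:
            return QCResult(False, f"Rs {v:g} MOhm >= {rs_max:g} MOhm at sample {i}")
    if reference == "first":
        change = (rs.max() - rs.min()) / rs[0]
        if change > max_change_frac:
            i = int(np.argmax(rs) if rs.max() - rs[0] >= rs[0] - rs.min()
                    else np.argmin(rs))
            return QCResult(
                False,
                f"Rs change {100 * change:.1f}% > {100 * max_change_frac:g}% "
                f"of first value at sample {i}",
            )
    else:
        for i in range(1, rs.size):
            ref = rs[:i].mean()
            change = abs(rs[i] - ref) / ref
            if change > max_change_frac:
                return QCResult(
                    False,
                    f"Rs change {100 * change:.1f}% > {100 * max_change_frac:g}% "
                    f"of running baseline at sample {i}",
                )
    return QCResult(True, None)


def bin_spontaneous(
    tset: SpontaneousTraceSet,
    discard_s: float = 5.0,
) -> pd.DataFrame:
    """Bin spontaneous PSC traces into 5-minute bins.

    The initial ``discard_s`` (5 s) of every trace is removed, leaving a
    10-s analysis segment; events are assigned to ``bin_s`` (300 s) bins
    by the *start time* of their trace.  Per bin the table reports the
    event rate (events per analyzed second), the mean event amplitude, and
    the rate normalized to the first bin (the baseline).
    """
    if not tset.traces:
        raise ValueError("empty trace set")
    rows = []
    for tr in tset.traces:
        if tr.duration_s <= discard_s:
            raise ValueError(
                f"trace {tr.trace_id}: duration {tr.duration_s} s <= "
                f"discard window {discard_s} s"
            )
        kept = [(t, a) for t, a in tr.events if discard_s <= t < tr.duration_s]
        rows.append({
            "trace_id": tr.trace_id,
            "start_s": tr.start_s,
            "bin_index": int(np.floor(tr.start_s / tset.bin_s)),
            "analyzed_s": tr.duration_s - discard_s,
            "n_events": len(kept),
            "amp_sum": sum(a for _, a in kept),
        })
    df = pd.DataFrame(rows)
    g = df.groupby("bin_index", sort=True)
    out = pd.DataFrame({
        "bin_index": g.size().index,
        "bin_start_s": g.size().index * tset.bin_s,
        "n_traces": g.size().to_numpy(),
        "analyzed_s": g["analyzed_s"].sum().to_numpy(),
        "n_events": g["n_events"].sum().to_numpy(),
    })
    out["rate_hz"] = out["n_events"] / out["analyzed_s"]
    amp_sum = g["amp_sum"].sum().to_numpy()
    with np.errstate(invalid="ignore"):
        out["mean_amplitude"] = np.where(
            out["n_events"] > 0, amp_sum / out["n_events"].to_numpy(), np.nan
        )
    out["is_baseline"] = out["bin_index"] == out["bin_index"].min()
    base_rate = float(out.loc[out["is_baseline"], "rate_hz"].iloc[0])
    out["rate_norm"] = out["rate_hz"] / base_rate if base_rate > 0 else np.nan
    return out.reset_index(drop=True)
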