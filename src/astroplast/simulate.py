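"""Synthetic fluorescence traces and evoked-response sweep series with
exact ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a slowly bleaching baseline fluorescence with an optional linear
drift component, additive Gaussian read noise, and sparse positive calcium
transients that scale the baseline multiplicatively — so that their size
is exactly their ΔF/F0 amplitude.  Evoked-response series get a step-like
multiplicative change at a treatment sweep.  Every generated object is
paired with the injected ground truth so detector sensitivity, rate and
amplitude recovery, and normalization bias can be measured directly.

The trace model is::

    F(t) = f_baseline * exp(-t / bleach_tau) * (1 + drift_slope * t / 60)
           * (1 + sum_i kernel_i(t)) + noise(t)

with each event kernel an instantaneous rise to its peak followed by an
exponential decay (time constant ``event_dur_mean / 3``, truncated below
5% of peak) — at 1-Hz sampling, rise kinetics are unresolvable and
detected events are plateau-like.

Determinism: each cell draws from an independent substream seeded by
``(seed, cell_index)``, so populations are reproducible under reordering
and identical parameters give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import check_finite, round_half_up
from .ephys import (
    EVOKED_EPSC,
    BaselineSpec,
    SweepSeries,
    qc_series_resistance,
)
from .trace import CLASS_LABELS, LAMINAE, FluorescenceTrace

#: fraction of the peak below which the decaying event kernel is truncated
KERNEL_TRUNC_FRAC = 0.05
#: floor applied to fluorescence after adding noise (fraction of f_baseline)
FLUOR_FLOOR_FRAC = 1e-6


@dataclass
class CalciumSimParams:
    """Parameters of the synthetic calcium-trace model.

    Defaults describe a 10-minute recording at 1 Hz with transients of
    0.5 ΔF/F0 mean peak lasting ~5 s, 2% read noise relative to baseline
    fluorescence, and a gentle bleach (tau ~ 33 min).
    """

    n_cells: int = 1
    fs: float = 1.0                 # Hz
    duration: float = 600.0         # s
    event_rate: float = 1.0         # events per minute per cell
    amp_mean: float = 0.5           # event peak, ΔF/F0 units
    amp_sd: float = 0.15
    event_dur_mean: float = 5.0     # s
    bleach_tau: float = 2000.0      # s; may be inf for no bleaching
    drift_slope: float = 0.0        # fraction per minute, linear component
    noise_sd: float = 2.0           # fluorescence units
    f_baseline: float = 100.0       # arbitrary fluorescence units
    quiet_start_s: float = 10.0     # event-free initial baseline period
    seed: int = 0

    def __post_init__(self) -> None:
        check_finite("fs", self.fs)
        check_finite("duration", self.duration)
        check_finite("event_rate", self.event_rate)
        check_finite("amp_mean", self.amp_mean)
        check_finite("amp_sd", self.amp_sd)
        check_finite("event_dur_mean", self.event_dur_mean)
        check_finite("bleach_tau", self.bleach_tau, allow_inf=True)
        check_finite("drift_slope", self.drift_slope)
        check_finite("noise_sd", self.noise_sd)
        check_finite("f_baseline", self.f_baseline)
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be > 0")
        if self.amp_mean <= 0:
            raise ValueError("amp_mean must be > 0")
        if self.noise_sd < 0 or self.event_rate < 0:
            raise ValueError("noise_sd and event_rate must be >= 0")
        if self.f_baseline <= 0:
            raise ValueError("f_baseline must be > 0")
        if self.event_dur_mean <= 0 or self.bleach_tau <= 0:
            raise ValueError("event_dur_mean and bleach_tau must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        check_finite("quiet_start_s", self.quiet_start_s)
        if not (0 <= self.quiet_start_s < self.duration):
            raise ValueError("quiet_start_s must lie in [0, duration)")


@dataclass
class InjectedEvent:
    onset_s: float
    duration_s: float
    peak_dff: float


@dataclass
class CellGroundTruth:
    cell_id: str
    cell_index: int
    class_label: str
    lamina: str
    events: List[InjectedEvent]
    noise_sd: float
    bleach_tau: float
    drift_slope: float

    @property
    def responder(self) -> bool:
        return len(self.events) >= 1

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class SyntheticGroundTruth:
    """Injected events and generator parameters for a whole population."""
    cells: List[CellGroundTruth] = field(default_factory=list)

    def by_id(self) -> Dict[str, CellGroundTruth]:
        return {c.cell_id: c for c in self.cells}


@dataclass
class SweepSimParams:
    """Step-change model for an evoked-response time course.

    ``effect_ratio`` multiplies the mean response from
    ``effect_onset_sweep`` onward (0.7 = depression, 1.4 = potentiation);
    sweep-to-sweep variability is multiplicative Gaussian with coefficient
    of variation ``noise_cv``.  Defaults match a 2-minute, 8-sweep
    baseline at one sweep per 15 s.
    """

    baseline_amplitude: float = 100.0   # pA (or AUC units)
    n_baseline_sweeps: int = 8
    n_post_sweeps: int = 24
    inter_sweep_interval: float = 15.0  # s
    effect_ratio: float = 1.0
    effect_onset_sweep: Optional[int] = None  # default: first post-baseline sweep
    noise_cv: float = 0.1
    rs_series: Optional[Sequence[float]] = None  # MΩ, one per sweep
    kind: str = EVOKED_EPSC
    seed: int = 0

    def __post_init__(self) -> None:
        check_finite("baseline_amplitude", self.baseline_amplitude)
        check_finite("effect_ratio", self.effect_ratio)
        check_finite("noise_cv", self.noise_cv)
        if self.baseline_amplitude <= 0:
            raise ValueError("baseline_amplitude must be > 0")
        if self.effect_ratio <= 0:
            raise ValueError("effect_ratio must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_baseline_sweeps < 1:
            raise ValueError("n_baseline_sweeps must be >= 1")
        if self.n_post_sweeps < 0:
            raise ValueError("n_post_sweeps must be >= 0")
        if self.inter_sweep_interval <= 0:
            raise ValueError("inter_sweep_interval must be > 0")
        if self.effect_onset_sweep is None:
            self.effect_onset_sweep = self.n_baseline_sweeps
        if not (1 <= self.effect_onset_sweep
                <= self.n_baseline_sweeps + self.n_post_sweeps):
            raise ValueError("effect_onset_sweep out of range")


@dataclass
class SweepTruth:
    effect_ratio: float
    baseline_amplitude: float
    effect_onset_sweep: int
    qc_passed: Optional[bool] = None    # None when no Rs trajectory given
    qc_reason: Optional[str] = None


def _draw_events(
    rng: np.random.Generator,
    params: CalciumSimParams,
) -> List[InjectedEvent]:
    """Place separable transients at the requested Poisson rate.

    No event starts before ``quiet_start_s``: the acquisition protocol
    this emulates opens every recording with a designated quiet baseline
    period.  Events may not overlap: after each event a refractory gap of
    one event duration is enforced.  To keep the *realized* rate equal to
    ``event_rate`` despite that dead time, the exponential waits are drawn
    with mean ``1/rate − occupied`` where ``occupied`` is the per-event
    dead time (event plus gap); if the requested rate is too high for that
    compensation the waits are floored at a tenth of the nominal interval
    and the realized rate falls short (only reachable far above realistic
    transient rates).
    """
    if params.event_rate == 0:
        return []
    rate_s = params.event_rate / 60.0
    tau = params.event_dur_mean / 3.0
    trunc_s = tau * math.log(1.0 / KERNEL_TRUNC_FRAC)  # kernel >= 5% of peak
    occupied = 2.0 * trunc_s                            # event + refractory gap
    mean_wait = max(1.0 / rate_s - occupied, 0.1 / rate_s)
    dt = 1.0 / params.fs

    events: List[InjectedEvent] = []
    clock = params.quiet_start_s
    while True:
        onset = clock + rng.exponential(mean_wait)
        onset = round_half_up(onset * params.fs) * dt   # snap to sample grid
        if onset >= params.duration:
            break
        if events and onset <= events[-1].onset_s:
            onset = events[-1].onset_s + dt
            if onset >= params.duration:
                break
        amp = rng.normal(params.amp_mean, params.amp_sd)
        amp = max(amp, 0.05 * params.amp_mean)          # keep peaks positive
        duration = min(trunc_s, params.duration - onset)
        events.append(InjectedEvent(onset_s=onset, duration_s=duration,
                                    peak_dff=amp))
        clock = onset + occupied
    return events


def generate_calcium_trace(
    params: CalciumSimParams,
    cell_index: int,
    cell_id: Optional[str] = None,
    class_label: str = "mcherry_neg",
    lamina: str = "II",
) -> Tuple[FluorescenceTrace, CellGroundTruth]:
    """Generate one cell's fluorescence trace plus its ground truth.

    Identical ``(params.seed, cell_index)`` gives bit-identical output.
    Event onsets are snapped to the sampling grid so the recorded true
    peak is the peak multiplicative deflection actually present in the
    sampled trace.
    """
    if not (0 <= cell_index < params.n_cells):
        raise ValueError(f"cell_index {cell_index} out of range [0, {params.n_cells})")
    if cell_id is None:
        cell_id = f"cell{cell_index:03d}"
    rng = np.random.default_rng([int(params.seed), int(cell_index)])

    n = round_half_up(params.duration * params.fs)
    t = np.arange(n) / params.fs

    events = _draw_events(rng, params)
    event_sig = np.zeros(n)
    tau = params.event_dur_mean / 3.0
    for ev in events:
        i0 = round_half_up(ev.onset_s * params.fs)
        i1 = min(n, i0 + math.ceil(ev.duration_s * params.fs))
        if i1 <= i0:
            i1 = i0 + 1
        rel = t[i0:i1] - ev.onset_s
        event_sig[i0:i1] += ev.peak_dff * np.exp(-rel / tau)

    bleach = np.exp(-t / params.bleach_tau) if np.isfinite(params.bleach_tau) else 1.0
    drift = 1.0 + params.drift_slope * t / 60.0
    f = params.f_baseline * bleach * drift * (1.0 + event_sig)
    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, size=n)
    # fluorescence is an intensity: clip at a tiny positive floor
    np.clip(f, FLUOR_FLOOR_FRAC * params.f_baseline, None, out=f)

    trace = FluorescenceTrace(cell_id=cell_id, class_label=class_label,
                              lamina=lamina, fs=params.fs, f=f)
    truth = CellGroundTruth(
        cell_id=cell_id, cell_index=cell_index, class_label=class_label,
        lamina=lamina, events=events, noise_sd=params.noise_sd,
        bleach_tau=params.bleach_tau, drift_slope=params.drift_slope,
    )
    return trace, truth


@dataclass
class PopulationGroup:
    """One homogeneous cell group in a simulated slice.

    ``lamina_probs`` gives the probability of each lamina label for cells
    of this group; a single-lamina group uses e.g. ``{"I": 1.0}``.
    """

    class_label: str
    params: CalciumSimParams
    lamina_probs: Dict[str, float] = field(
        default_factory=lambda: {"I": 0.3, "II": 0.4, "III_IV": 0.3})

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        for lam in self.lamina_probs:
            if lam not in LAMINAE:
                raise ValueError(f"unknown lamina {lam!r}")
        tot = sum(self.lamina_probs.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError(f"lamina_probs must sum to 1, got {tot}")


def generate_population(
    groups: Sequence[PopulationGroup],
    seed: Optional[int] = None,
    slice_id: str = "slice01",
) -> Tuple[List[FluorescenceTrace], pd.DataFrame, SyntheticGroundTruth]:
    """Generate one slice's worth of cells across class/lamina groups.

    Returns the traces, a metadata table (cell_id, class, lamina,
    slice_id) and the paired ground truth.  Cell indices run globally
    across groups so each cell keeps its own random substream; ``seed``
    overrides each group's ``params.seed`` when given.
    """
    if not groups:
        raise ValueError("need at least one population group")
    traces: List[FluorescenceTrace] = []
    meta_rows = []
    truth = SyntheticGroundTruth()
    seen_ids = set()
    idx = 0
    for g in groups:
        p = g.params if seed is None else replace(g.params, seed=seed)
        lam_names = sorted(g.lamina_probs)
        lam_p = np.array([g.lamina_probs[k] for k in lam_names])
        for _ in range(p.n_cells):
            # lamina from a separate substream so trace draws are unaffected
            lam_rng = np.random.default_rng([int(p.seed), int(idx), 1])
            lamina = lam_names[int(lam_rng.choice(len(lam_names), p=lam_p))]
            cid = f"{slice_id}_{g.class_label}_{idx:03d}"
            if cid in seen_ids:
                raise ValueError(f"duplicate cell id {cid}")
            seen_ids.add(cid)
            # per-cell n_cells bound: the global index must stay addressable
            p_cell = replace(p, n_cells=idx + 1)
            tr, gt = generate_calcium_trace(
                p_cell, idx, cell_id=cid, class_label=g.class_label,
                lamina=lamina)
            traces.append(tr)
            truth.cells.append(gt)
            meta_rows.append({"cell_id": cid, "class": g.class_label,
                              "lamina": lamina, "slice_id": slice_id})
            idx += 1
    meta = pd.DataFrame(meta_rows)
    return traces, meta, truth


def generate_sweep_series(params: SweepSimParams) -> Tuple[SweepSeries, SweepTruth]:
    """Generate an evoked-response sweep series with a step change.

    Sweeps before ``effect_onset_sweep`` have mean ``baseline_amplitude``;
    from the onset sweep on, the mean is multiplied by ``effect_ratio``.
    The treatment time falls halfway between the last pre-onset and the
    first post-onset sweep.  If an Rs trajectory is supplied, the truth
    record carries the outcome of the 25 MΩ / 30%-change QC rule.
    """
    n_total = params.n_baseline_sweeps + params.n_post_sweeps
    rng = np.random.default_rng(int(params.seed))
    idx = np.arange(n_total)
    times = idx * params.inter_sweep_interval
    mean = np.where(idx < params.effect_onset_sweep, 1.0, params.effect_ratio)
    mean = mean * params.baseline_amplitude
    values = mean * (1.0 + params.noise_cv * rng.standard_normal(n_total))

    df = pd.DataFrame({"sweep_index": idx, "time_s": times, "value": values})
    qc_passed = qc_reason = None
    if params.rs_series is not None:
        rs = np.asarray(params.rs_series, dtype=float)
        if rs.size != n_total:
            raise ValueError(
                f"rs_series has {rs.size} entries, expected {n_total}")
        df["rs_mohm"] = rs
        qc = qc_series_resistance(rs)
        qc_passed, qc_reason = qc.passed, qc.reason

    treatment_time = (params.effect_onset_sweep - 0.5) * params.inter_sweep_interval
    series = SweepSeries(
        sweeps=df,
        kind=params.kind,
        treatment_time_s=treatment_time,
        baseline_spec=BaselineSpec(
            n_sweeps=min(8 if params.kind == EVOKED_EPSC else 5,
                         params.n_baseline_sweeps)),
    )
    truth = SweepTruth(
        effect_ratio=params.effect_ratio,
        baseline_amplitude=params.baseline_amplitude,
        effect_onset_sweep=params.effect_onset_sweep,
        qc_passed=qc_passed,
        qc_reason=qc_reason,
    )
    return series, truth
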