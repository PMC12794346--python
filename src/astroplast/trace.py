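"""Raw fluorescence to drift-corrected ΔF/F0.

The processing chain mirrors the offline analysis used for 1-Hz confocal
calcium imaging of spinal dorsal horn cells:

1. A local baseline F0 is estimated with a sliding buffer of the most
   recent *subthreshold* raw samples (:func:`compute_local_f0`).  Because
   suprathreshold samples never enter the buffer, calcium transients do not
   inflate the baseline, while slow photobleaching and drift are tracked.
2. Each point is normalized as ΔF/F0 = (F(t) − F0(t)) / F0(t)
   (:func:`normalize_dff`).
3. Residual slow drift is removed with a zero-phase Butterworth high-pass
   filter at 0.001 Hz (:func:`highpass_residual_drift`).

:func:`process_trace` runs the full chain and records every parameter in
the returned :class:`NormalizedTrace` for provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from ._util import check_finite, round_half_up

CLASS_LABELS = ("mcherry_pos", "mcherry_neg")
LAMINAE = ("I", "II", "III_IV")


@dataclass
class FluorescenceTrace:
    """Raw fluorescence samples for one ROI (single cell).

    Parameters
    ----------
    cell_id : str
        Unique ROI identifier.
    class_label : str
        ``"mcherry_pos"`` (DREADD-expressing astrocyte) or ``"mcherry_neg"``
        (neuron).
    lamina : str
        Dorsal horn lamina of the ROI: ``"I"``, ``"II"`` or ``"III_IV"``.
    fs : float
        Sampling rate in Hz (1.0 for the acquisition this models).
    f : numpy.ndarray
        Fluorescence samples in arbitrary units; must be finite.
    t0 : float
        Time of the first sample in seconds.
    """

    cell_id: str
    class_label: str
    lamina: str
    fs: float
    f: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.lamina not in LAMINAE:
            raise ValueError(f"unknown lamina {self.lamina!r}")
        check_finite("fs", self.fs)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 1 or self.f.size == 0:
            raise ValueError("f must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.f)):
            raise ValueError(f"trace {self.cell_id}: non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.f.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds; sample i is at t0 + i/fs."""
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class NormalizedTrace:
    """ΔF/F0 series with its local baseline and full parameter provenance."""

    cell_id: str
    fs: float
    dff: np.ndarray            # final (high-pass filtered) ΔF/F0
    f0: np.ndarray             # per-sample local baseline
    baseline_window_s: float = 10.0
    window_n: int = 30
    k_sub: float = 2.0
    filter_cutoff_hz: float = 0.001
    filter_order: int = 2
    filter_applied: bool = True
    class_label: Optional[str] = None
    lamina: Optional[str] = None
    t0: float = 0.0
    dff_unfiltered: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.dff.shape != self.f0.shape:
            raise ValueError("dff and f0 must have the same length")
        if np.any(self.f0 <= 0):
            raise ValueError("f0 must be strictly positive")

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.dff.size) / self.fs


def compute_local_f0(
    trace: FluorescenceTrace,
    window_n: int = 30,
    k_sub: float = 2.0,
    baseline_window_s: float = 10.0,
) -> np.ndarray:
    """Per-sample local baseline from a sliding subthreshold buffer.

    The buffer is initialized with all samples of the first
    ``baseline_window_s`` of the recording (the designated baseline period;
    if that exceeds ``window_n`` samples only the most recent ``window_n``
    are kept).  From then on, for each sample t:

    * ``F0(t)`` = mean of the current buffer (before any insertion);
    * the raw sample enters the buffer — evicting the oldest entry once the
      buffer holds ``window_n`` points — iff it is *subthreshold*, i.e.
      ``F(t) < mean(buffer) + k_sub * SD(buffer)`` with the sample SD
      (ddof=1) of the pre-insertion buffer.

    Suprathreshold excursions (calcium transients) therefore never
    contaminate F0, while bleaching ramps are followed with a lag of at
    most one buffer span.  Samples inside the starting window get the
    starting buffer's mean as F0.

    Note: a perfectly constant starting buffer has SD 0, so the first
    excursion of any size is excluded; measurement noise makes this a
    non-issue on real data.
    """
    if window_n < 1:
        raise ValueError("window_n must be >= 1")
    check_finite("k_sub", k_sub)
    f = trace.f
    n = f.size
    n_base = round_half_up(baseline_window_s * trace.fs)
    if n_base < 1:
        raise ValueError("baseline window shorter than one sample")
    if n < n_base:
        raise ValueError(
            f"trace {trace.cell_id}: {n} samples, need at least {n_base} "
            f"({baseline_window_s} s at {trace.fs} Hz) for the starting window"
        )

    # Ring buffer over the most recent subthreshold samples.  Mean and SD
    # use exactly-rounded summation (math.fsum) so F0 is bit-reproducible
    # regardless of summation order.
    buf = [float(v) for v in f[max(0, n_base - window_n):n_base]]
    f0 = np.empty(n)
    f0[:n_base] = math.fsum(buf) / len(buf)
    for t in range(n_base, n):
        m = math.fsum(buf) / len(buf)
        if len(buf) > 1:
            s = math.sqrt(math.fsum((v - m) ** 2 for v in buf) / (len(buf) - 1))
        else:
            s = 0.0
        f0[t] = m
        if f[t] < m + k_sub * s:
            buf.append(float(f[t]))
            if len(buf) > window_n:
                buf.pop(0)
    return f0


def normalize_dff(trace: FluorescenceTrace, f0: np.ndarray) -> np.ndarray:
    """Pointwise ΔF/F0 = (F(t) − F0(t)) / F0(t).

    Raises if any F0 value is non-positive — that signals a pathological
    baseline estimate, not a recoverable condition.
    """
    f = trace.f
    f0 = np.asarray(f0, dtype=float)
    if f0.shape != f.shape:
        raise ValueError("f0 must have the same length as the trace")
    if np.any(f0 <= 0):
        bad = int(np.argmax(f0 <= 0))
        raise ValueError(f"F0 <= 0 at sample {bad}: pathological baseline")
    return (f - f0) / f0


def highpass_residual_drift(
    dff: np.ndarray,
    fs: float,
    cutoff_hz: float = 0.001,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth high-pass to remove residual slow drift.

    Applied forward-backward (``sosfiltfilt``) so event onsets are not
    shifted, with reflective padding of one filter warm-up length — taken
    as 2/cutoff seconds, ample for the filter's slowest pole to settle —
    capped at the trace length.  Output has the input's length.  The DC
    component of a long constant input is attenuated below 1% of the
    offset.
    """
    x = np.asarray(dff, dtype=float)
    check_finite("cutoff_hz", cutoff_hz)
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be > 0")
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist ({fs / 2} Hz)")
    min_len = 3 * (order + 1)
    if x.size <= min_len:
        raise ValueError(f"need more than {min_len} samples to filter")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    padlen = min(x.size - 1, int(round(2.0 * fs / cutoff_hz)))
    # mirror reflection: keeps constants/slow trends continuous at the edges
    # without amplifying endpoint noise into low-frequency edge lobes
    return signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def process_trace(
    trace: FluorescenceTrace,
    window_n: int = 30,
    k_sub: float = 2.0,
    baseline_window_s: float = 10.0,
    filter_cutoff_hz: float = 0.001,
    filter_order: int = 2,
    apply_filter: bool = True,
) -> NormalizedTrace:
    """Full chain: local F0 → ΔF/F0 → zero-phase high-pass."""
    f0 = compute_local_f0(trace, window_n=window_n, k_sub=k_sub,
                          baseline_window_s=baseline_window_s)
    dff = normalize_dff(trace, f0)
    dff_filt = (
        highpass_residual_drift(dff, trace.fs, cutoff_hz=filter_cutoff_hz,
                                order=filter_order)
        if apply_filter else dff
    )
    return NormalizedTrace(
        cell_id=trace.cell_id,
        fs=trace.fs,
        dff=dff_filt,
        f0=f0,
        baseline_window_s=baseline_window_s,
        window_n=window_n,
        k_sub=k_sub,
        filter_cutoff_hz=filter_cutoff_hz,
        filter_order=filter_order,
        filter_applied=apply_filter,
        class_label=trace.class_label,
        lamina=trace.lamina,
        t0=trace.t0,
        dff_unfiltered=dff,
    )
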