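"""Calcium event detection and aggregation.

A calcium event is a maximal run of consecutive filtered ΔF/F0 samples at
least ``k_event`` standard deviations above the baseline mean that lasts at
least ``min_duration_s`` (3 s by default — three samples at 1 Hz).  The
baseline statistics come from the first ``baseline_window_s`` of the
filtered trace.  Per-cell summaries report event rate and, for responders
only (cells with at least one event), mean peak amplitude; per-slice
summaries average cells within mCherry class and lamina strata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import check_finite, round_half_up
from .trace import CLASS_LABELS, LAMINAE, NormalizedTrace

ALL = "all"  # marginal stratum key


@dataclass
class CalciumEvent:
    """One suprathreshold episode; the interval is half-open [start_s, end_s)."""

    cell_id: str
    start_s: float
    end_s: float
    duration_s: float
    peak_amp: float
    peak_time_s: float

    def __post_init__(self) -> None:
        if not (self.start_s <= self.peak_time_s < self.end_s):
            raise ValueError("peak_time_s must lie in [start_s, end_s)")
        if abs(self.duration_s - (self.end_s - self.start_s)) > 1e-9:
            raise ValueError("duration_s must equal end_s - start_s")


@dataclass
class CellEventSummary:
    cell_id: str
    class_label: Optional[str]
    lamina: Optional[str]
    n_events: int
    event_rate: float               # events per minute
    mean_peak_amp: Optional[float]  # None for non-responders
    responder: bool
    window_s: float


@dataclass
class StratumStats:
    n_cells: int
    n_responders: int
    mean_event_rate: float
    mean_peak_amp: Optional[float]  # responder-only pool; None if no responders


@dataclass
class SliceSummary:
    """Per-slice means over cells, stratified by mCherry class and lamina.

    ``strata`` is keyed by ``(class_label, lamina)`` where either element
    may be ``"all"`` for the marginal; ``("all", "all")`` is the whole
    slice.
    """

    slice_id: str
    strata: Dict[Tuple[str, str], StratumStats]

    def get(self, class_label: str = ALL, lamina: str = ALL) -> Optional[StratumStats]:
        return self.strata.get((class_label, lamina))


def detect_events(
    dff_filtered: Sequence[float],
    fs: float,
    baseline_window_s: float = 10.0,
    k_event: float = 2.0,
    min_duration_s: float = 3.0,
    cell_id: str = "",
    t0: float = 0.0,
) -> List[CalciumEvent]:
    """Threshold-and-duration event detection on a filtered ΔF/F0 trace.

    The threshold is ``mean + k_event * SD`` of the first
    ``baseline_window_s`` of the trace (sample SD, ddof=1).  Maximal runs
    of samples ``>= threshold`` lasting at least
    ``ceil(min_duration_s * fs)`` samples become events; ties at the
    threshold count as suprathreshold.  Each event reports its maximum
    value and the time of the first maximum.  Events are disjoint and
    returned in time order; an event touching the trace end is kept if it
    already meets the duration minimum, and events may begin inside the
    baseline window (the baseline defines the threshold, not an exclusion
    zone).

    If the baseline SD is zero on a non-constant trace, a warning is
    issued and the threshold degenerates to the baseline mean; in that
    degenerate case the suprathreshold test is strict (``>``) so that a
    constant trace yields no events.
    """
    x = np.asarray(dff_filtered, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be > 0")
    check_finite("k_event", k_event)
    n_base = round_half_up(baseline_window_s * fs)
    if x.size <= n_base:
        raise ValueError("trace must be longer than the baseline window")
    min_len = math.ceil(min_duration_s * fs)
    if min_len < 1:
        raise ValueError("min_duration_s * fs must be >= 1")

    base = x[:n_base]
    mu = float(base.mean())
    sd = float(base.std(ddof=1)) if n_base > 1 else 0.0
    if sd == 0.0:
        if k_event > 0 and np.ptp(x) > 0:
            warnings.warn(
                "zero baseline SD on a non-constant trace; "
                "threshold degenerates to the baseline mean",
                RuntimeWarning,
                stacklevel=2,
            )
        above = x > mu           # strict: a flat trace is not one long event
    else:
        above = x >= mu + k_event * sd

    events: List[CalciumEvent] = []
    # run-length scan over the boolean mask
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    for i0, i1 in zip(starts, ends):
        if i1 - i0 < min_len:
            continue
        seg = x[i0:i1]
        pk = int(np.argmax(seg))
        events.append(CalciumEvent(
            cell_id=cell_id,
            start_s=t0 + i0 / fs,
            end_s=t0 + i1 / fs,
            duration_s=(i1 - i0) / fs,
            peak_amp=float(seg[pk]),
            peak_time_s=t0 + (i0 + pk) / fs,
        ))
    return events


def detect_events_trace(
    norm: NormalizedTrace,
    baseline_window_s: float = 10.0,
    k_event: float = 2.0,
    min_duration_s: float = 3.0,
) -> List[CalciumEvent]:
    """Convenience wrapper running :func:`detect_events` on a NormalizedTrace."""
    return detect_events(
        norm.dff, norm.fs,
        baseline_window_s=baseline_window_s,
        k_event=k_event,
        min_duration_s=min_duration_s,
        cell_id=norm.cell_id,
        t0=norm.t0,
    )


def summarize_cell(
    events: Sequence[CalciumEvent],
    meta,
    window_s: float,
) -> CellEventSummary:
    """Per-cell event rate, responder flag and responder-only mean peak.

    ``meta`` supplies ``cell_id``, ``class_label`` and ``lamina`` — it may
    be any object with those attributes (e.g. a trace) or a mapping.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")

    def _get(key):
        if isinstance(meta, dict):
            return meta.get(key)
        return getattr(meta, key, None)

    n = len(events)
    responder = n >= 1
    return CellEventSummary(
        cell_id=_get("cell_id"),
        class_label=_get("class_label"),
        lamina=_get("lamina"),
        n_events=n,
        event_rate=n / (window_s / 60.0),
        mean_peak_amp=(float(np.mean([e.peak_amp for e in events]))
                       if responder else None),
        responder=responder,
        window_s=window_s,
    )


def _pool(cells: List[CellEventSummary]) -> StratumStats:
    responders = [c for c in cells if c.responder]
    return StratumStats(
        n_cells=len(cells),
        n_responders=len(responders),
        mean_event_rate=float(np.mean([c.event_rate for c in cells])),
        mean_peak_amp=(float(np.mean([c.mean_peak_amp for c in responders]))
                       if responders else None),
    )


def summarize_slice(cells: Sequence[CellEventSummary], slice_id: str) -> SliceSummary:
    """Slice-level means over cells, by class, by lamina, and crossed.

    Peak amplitudes pool responders only; a stratum with zero responders
    gets a ``None`` peak mean, never 0.  Strata with no cells are absent.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("summarize_slice needs at least one cell")
    strata: Dict[Tuple[str, str], StratumStats] = {}
    for cls in (*CLASS_LABELS, ALL):
        for lam in (*LAMINAE, ALL):
            sub = [c for c in cells
                   if (cls == ALL or c.class_label == cls)
                   and (lam == ALL or c.lamina == lam)]
            if sub:
                strata[(cls, lam)] = _pool(sub)
    return SliceSummary(slice_id=slice_id, strata=strata)


def compare_conditions(
    pre: Sequence[SliceSummary],
    post: Sequence[SliceSummary],
    n_boot: int = 2000,
    seed: int = 1,
) -> pd.DataFrame:
    """Descriptive pre/post contrast per class × lamina stratum.

    Slices are matched by id across conditions.  For each stratum and each
    metric (event rate; responder-only mean peak amplitude) the table
    reports the mean paired difference (post − pre), the ratio of
    condition means, and seeded bootstrap percentile intervals obtained by
    resampling slices (the experimental unit) with replacement.  With a
    single slice pair the intervals collapse to the point estimates and
    the row is flagged ``degenerate``.
    """
    pre_by_id = {s.slice_id: s for s in pre}
    post_by_id = {s.slice_id: s for s in post}
    if len(pre_by_id) != len(pre) or len(post_by_id) != len(post):
        raise ValueError("duplicate slice ids within a condition")
    if set(pre_by_id) != set(post_by_id):
        missing = set(pre_by_id) ^ set(post_by_id)
        raise ValueError(f"unmatched slice ids across conditions: {sorted(missing)}")
    ids = sorted(pre_by_id)
    n_slices = len(ids)
    rng = np.random.default_rng(seed)

    keys = sorted({k for s in list(pre) + list(post) for k in s.strata})
    rows = []
    for cls, lam in keys:
        for metric in ("event_rate", "peak_amp"):
            pre_v = np.full(n_slices, np.nan)
            post_v = np.full(n_slices, np.nan)
            for i, sid in enumerate(ids):
                for vec, summ in ((pre_v, pre_by_id[sid]), (post_v, post_by_id[sid])):
                    st = summ.strata.get((cls, lam))
                    if st is None:
                        continue
                    v = st.mean_event_rate if metric == "event_rate" else st.mean_peak_amp
                    vec[i] = np.nan if v is None else v
            ok = np.isfinite(pre_v) & np.isfinite(post_v)
            if not ok.any():
                continue
            pv, qv = pre_v[ok], post_v[ok]

            def stat(p, q):
                diff = float(np.mean(q - p))
                pm = float(np.mean(p))
                ratio = float(np.mean(q) / pm) if pm != 0 else np.nan
                return diff, ratio

            diff, ratio = stat(pv, qv)
            m = pv.size
            if m > 1:
                boots = np.empty((n_boot, 2))
                for b in range(n_boot):
                    idx = rng.integers(0, m, size=m)
                    boots[b] = stat(pv[idx], qv[idx])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    diff_lo, diff_hi = np.nanpercentile(boots[:, 0], [2.5, 97.5])
                    ratio_lo, ratio_hi = np.nanpercentile(boots[:, 1], [2.5, 97.5])
                degenerate = False
            else:
                diff_lo = diff_hi = diff
                ratio_lo = ratio_hi = ratio
                degenerate = True
            rows.append({
                "class_label": cls, "lamina": lam, "metric": metric,
                "pre_mean": float(np.mean(pv)), "post_mean": float(np.mean(qv)),
                "diff": diff, "diff_lo": diff_lo, "diff_hi": diff_hi,
                "ratio": ratio, "ratio_lo": ratio_lo, "ratio_hi": ratio_hi,
                "n_pairs": int(m), "degenerate": degenerate,
            })
    return pd.DataFrame(rows)
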