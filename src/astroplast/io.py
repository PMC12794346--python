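"""Delimited-text readers/writers with provenance headers.

All tabular outputs are plain CSV with floats printed at 9 significant
digits, preceded by ``#``-prefixed provenance lines (package version and,
where applicable, a config hash); readers skip those lines.  Ground truth
and summaries are written as JSON.  The trace reader validates the file
against the metadata table before anything downstream runs: every trace
column must have a metadata row, times must be non-negative and strictly
increasing, and no value may be NaN.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._util import FLOAT_FMT
from .ephys import BaselineSpec, SweepSeries
from .events import CalciumEvent, CellEventSummary, SliceSummary, StratumStats
from .simulate import SyntheticGroundTruth
from .trace import FluorescenceTrace, NormalizedTrace

PathLike = Union[str, Path]


def _version() -> str:
    from . import __version__
    return __version__


def _header_lines(extra: Optional[Dict[str, str]] = None) -> str:
    items = {"astroplast_version": _version()}
    if extra:
        items.update(extra)
    return "".join(f"# {k}: {v}\n" for k, v in items.items())


def _write_csv(df: pd.DataFrame, path: PathLike,
               extra: Optional[Dict[str, str]] = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(extra))
        df.to_csv(fh, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def _read_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------- traces

def write_traces(traces: Sequence[FluorescenceTrace], path: PathLike,
                 extra: Optional[Dict[str, str]] = None) -> None:
    """Wide table: first column time_s, one column per cell id."""
    if not traces:
        raise ValueError("no traces to write")
    n = traces[0].n_samples
    fs = traces[0].fs
    for tr in traces:
        if tr.n_samples != n or tr.fs != fs:
            raise ValueError("all traces must share length and sampling rate")
    df = pd.DataFrame({"time_s": traces[0].times()})
    for tr in traces:
        if tr.cell_id in df.columns:
            raise ValueError(f"duplicate cell id {tr.cell_id}")
        df[tr.cell_id] = tr.f
    _write_csv(df, path, extra)


def write_metadata(meta: pd.DataFrame, path: PathLike,
                   extra: Optional[Dict[str, str]] = None) -> None:
    _write_csv(meta, path, extra)


def read_metadata(path: PathLike) -> pd.DataFrame:
    meta = _read_csv(path)
    for col in ("cell_id", "class", "lamina"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
    if meta["cell_id"].duplicated().any():
        dup = meta.loc[meta["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell id in metadata: {dup}")
    return meta


def read_traces(traces_path: PathLike, meta: Union[PathLike, pd.DataFrame],
                fs: Optional[float] = None) -> List[FluorescenceTrace]:
    """Read a wide trace table plus metadata into FluorescenceTrace objects.

    ``fs`` is inferred from the time column when not given.  A trace
    column without a metadata row is a hard error naming the cell id.
    """
    df = _read_csv(traces_path)
    if "time_s" not in df.columns:
        raise ValueError("trace table must have a time_s first column")
    if isinstance(meta, (str, Path)):
        meta = read_metadata(meta)
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("time_s contains NaN or negative values")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time_s must be strictly increasing")
    if fs is None:
        if t.size < 2:
            raise ValueError("cannot infer fs from fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    meta_by_id = meta.set_index("cell_id")
    traces = []
    for col in df.columns:
        if col == "time_s":
            continue
        if col not in meta_by_id.index:
            raise ValueError(f"trace column {col!r} has no metadata row")
        vals = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError(f"trace {col!r} contains NaN/non-finite values")
        row = meta_by_id.loc[col]
        traces.append(FluorescenceTrace(
            cell_id=col, class_label=str(row["class"]),
            lamina=str(row["lamina"]), fs=fs, f=vals, t0=float(t[0])))
    return traces


# ---------------------------------------------- normalized traces + sidecar

def write_normalized(norms: Sequence[NormalizedTrace], out_dir: PathLike,
                     stem: str = "dff",
                     extra: Optional[Dict[str, str]] = None) -> Tuple[Path, Path]:
    """Write ΔF/F0 (and F0) tables plus a JSON provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n0 = norms[0]
    dff = pd.DataFrame({"time_s": n0.times()})
    f0 = pd.DataFrame({"time_s": n0.times()})
    for nt in norms:
        dff[nt.cell_id] = nt.dff
        f0[nt.cell_id] = nt.f0
    dff_path = out_dir / f"{stem}.csv"
    _write_csv(dff, dff_path, extra)
    _write_csv(f0, out_dir / f"{stem}_f0.csv", extra)
    sidecar = out_dir / f"{stem}_provenance.json"
    prov = {
        "astroplast_version": _version(),
        "fs": n0.fs,
        "baseline_window_s": n0.baseline_window_s,
        "window_n": n0.window_n,
        "k_sub": n0.k_sub,
        "filter_cutoff_hz": n0.filter_cutoff_hz,
        "filter_order": n0.filter_order,
        "filter_applied": n0.filter_applied,
        "n_cells": len(norms),
    }
    sidecar.write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    return dff_path, sidecar


# ----------------------------------------------------------------- events

def events_to_frame(events: Sequence[CalciumEvent]) -> pd.DataFrame:
    cols = ["cell_id", "start_s", "end_s", "duration_s", "peak_amp", "peak_time_s"]
    return pd.DataFrame([dataclasses.asdict(e) for e in events], columns=cols)


def write_events(events: Sequence[CalciumEvent], path: PathLike,
                 extra: Optional[Dict[str, str]] = None) -> None:
    _write_csv(events_to_frame(events), path, extra)


def read_events(path: PathLike) -> List[CalciumEvent]:
    df = _read_csv(path)
    return [CalciumEvent(**{k: (str(v) if k == "cell_id" else float(v))
                            for k, v in row.items()})
            for row in df.to_dict("records")]


# -------------------------------------------------------------- summaries

def slice_summary_to_dict(s: SliceSummary) -> Dict:
    return {
        "slice_id": s.slice_id,
        "strata": {
            f"{cls}|{lam}": dataclasses.asdict(st)
            for (cls, lam), st in sorted(s.strata.items())
        },
    }


def slice_summary_from_dict(d: Dict) -> SliceSummary:
    strata = {}
    for key, st in d["strata"].items():
        cls, lam = key.split("|")
        strata[(cls, lam)] = StratumStats(**st)
    return SliceSummary(slice_id=d["slice_id"], strata=strata)


def write_summaries(cells: Sequence[CellEventSummary],
                    slices: Sequence[SliceSummary],
                    out_dir: PathLike) -> None:
    out_dir = Path(out_dir)
    cell_df = pd.DataFrame([dataclasses.asdict(c) for c in cells])
    _write_csv(cell_df, out_dir / "cell_summaries.csv")
    payload = {
        "astroplast_version": _version(),
        "slices": [slice_summary_to_dict(s) for s in slices],
    }
    (out_dir / "slice_summaries.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ------------------------------------------------------------ ground truth

def ground_truth_to_dict(gt: SyntheticGroundTruth) -> Dict:
    return {"cells": [
        {
            "cell_id": c.cell_id, "cell_index": c.cell_index,
            "class_label": c.class_label, "lamina": c.lamina,
            "noise_sd": c.noise_sd, "bleach_tau": c.bleach_tau,
            "drift_slope": c.drift_slope, "responder": c.responder,
            "events": [dataclasses.asdict(e) for e in c.events],
        } for c in gt.cells
    ]}


def write_ground_truth(gt: SyntheticGroundTruth, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(ground_truth_to_dict(gt), indent=2, sort_keys=True) + "\n")


# ------------------------------------------------------------------ sweeps

def write_sweeps(series: SweepSeries, path: PathLike,
                 extra: Optional[Dict[str, str]] = None) -> None:
    hdr = {"kind": series.kind,
           "treatment_time_s": FLOAT_FMT % series.treatment_time_s,
           "baseline_n_sweeps": str(series.baseline_spec.n_sweeps)}
    if extra:
        hdr.update(extra)
    _write_csv(series.sweeps, path, hdr)


def read_sweeps(path: PathLike, kind: str, treatment_time_s: float,
                baseline_n: Optional[int] = None) -> SweepSeries:
    df = _read_csv(path)
    spec = BaselineSpec(baseline_n) if baseline_n is not None else None
    return SweepSeries(sweeps=df, kind=kind,
                       treatment_time_s=treatment_time_s, baseline_spec=spec)
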