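"""End-to-end runner: simulation → ΔF/F0 processing → event detection →
per-cell and per-slice summaries (→ optional pre/post contrast).

Every run writes its fully resolved configuration next to its outputs, all
numeric files use fixed 9-significant-digit formatting, and nothing in the
output depends on wall-clock time — so two runs with the same seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import io as apio
from .events import (
    compare_conditions,
    detect_events_trace,
    summarize_cell,
    summarize_slice,
)
from .simulate import CalciumSimParams, PopulationGroup, generate_population
from .trace import process_trace


class PipelineError(RuntimeError):
    """Raised for invalid inputs or stage failures; maps to CLI exit 1."""


@dataclass
class GroupConfig:
    """Serializable description of one simulated cell group."""
    class_label: str = "mcherry_neg"
    n_cells: int = 10
    lamina_probs: Dict[str, float] = field(
        default_factory=lambda: {"I": 0.3, "II": 0.4, "III_IV": 0.3})
    event_rate: float = 1.0
    amp_mean: float = 0.5
    amp_sd: float = 0.15
    event_dur_mean: float = 5.0
    bleach_tau: float = 2000.0
    drift_slope: float = 0.0
    noise_sd: float = 2.0
    f_baseline: float = 100.0


@dataclass
class ProcessingConfig:
    fs: float = 1.0
    window_n: int = 30
    k_sub: float = 2.0
    baseline_window_s: float = 10.0
    filter_cutoff_hz: float = 0.001
    filter_order: int = 2


@dataclass
class DetectionConfig:
    k_event: float = 2.0
    min_duration_s: float = 3.0
    baseline_window_s: float = 10.0


@dataclass
class PipelineConfig:
    """All stage parameters plus the run seed.

    Defaults are the analysis constants of the study this models: 30-point
    subthreshold window with a mean+2SD criterion, 10-s starting baseline,
    0.001-Hz Butterworth high-pass, mean+2SD event threshold with a 3-s
    minimum duration, 1-Hz sampling.
    """

    seed: int = 1
    duration_s: float = 600.0
    n_slices: int = 3
    groups: List[GroupConfig] = field(default_factory=lambda: [
        GroupConfig(class_label="mcherry_pos", n_cells=10, event_rate=0.5),
        GroupConfig(class_label="mcherry_neg", n_cells=10, event_rate=1.0),
    ])
    post_groups: Optional[List[GroupConfig]] = None  # enables pre/post contrast
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        d = dict(d)
        d["groups"] = [GroupConfig(**g) for g in d.get("groups", [])]
        if d.get("post_groups") is not None:
            d["post_groups"] = [GroupConfig(**g) for g in d["post_groups"]]
        if "processing" in d:
            d["processing"] = ProcessingConfig(**d["processing"])
        if "detection" in d:
            d["detection"] = DetectionConfig(**d["detection"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _sim_params(g: GroupConfig, cfg: PipelineConfig, seed: int) -> CalciumSimParams:
    return CalciumSimParams(
        n_cells=g.n_cells, fs=cfg.processing.fs, duration=cfg.duration_s,
        event_rate=g.event_rate, amp_mean=g.amp_mean, amp_sd=g.amp_sd,
        event_dur_mean=g.event_dur_mean, bleach_tau=g.bleach_tau,
        drift_slope=g.drift_slope, noise_sd=g.noise_sd,
        f_baseline=g.f_baseline, seed=seed,
    )


def slice_seed(base_seed: int, slice_index: int, condition: int = 0) -> int:
    """Stable per-slice substream seed (< 2**31)."""
    ss = np.random.SeedSequence([int(base_seed), int(condition), int(slice_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_condition(
    cfg: PipelineConfig,
    groups: List[GroupConfig],
    condition: int,
) -> Tuple[list, list, list, list, list]:
    """Simulate, process, detect and summarize all slices of one condition."""
    all_traces, all_truth, all_events, all_cells, slices = [], [], [], [], []
    for s in range(cfg.n_slices):
        sid = f"slice{s:02d}"
        pgroups = [
            PopulationGroup(
                class_label=g.class_label,
                params=_sim_params(g, cfg, slice_seed(cfg.seed, s, condition)),
                lamina_probs=g.lamina_probs,
            ) for g in groups
        ]
        traces, meta, truth = generate_population(pgroups, slice_id=sid)
        cell_summaries = []
        for tr in traces:
            norm = process_trace(
                tr,
                window_n=cfg.processing.window_n,
                k_sub=cfg.processing.k_sub,
                baseline_window_s=cfg.processing.baseline_window_s,
                filter_cutoff_hz=cfg.processing.filter_cutoff_hz,
                filter_order=cfg.processing.filter_order,
            )
            evts = detect_events_trace(
                norm,
                baseline_window_s=cfg.detection.baseline_window_s,
                k_event=cfg.detection.k_event,
                min_duration_s=cfg.detection.min_duration_s,
            )
            all_events.extend(evts)
            cell_summaries.append(summarize_cell(evts, tr, window_s=cfg.duration_s))
        slices.append(summarize_slice(cell_summaries, sid))
        all_traces.extend(traces)
        all_truth.append((meta, truth))
        all_cells.extend(cell_summaries)
    return all_traces, all_truth, all_events, all_cells, slices


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Run the full pipeline into ``out_dir``; returns the run directory.

    Outputs: resolved config, trace/metadata/ground-truth files, ΔF/F0
    tables, event table, per-cell and per-slice summaries, a pre/post
    contrast table when ``post_groups`` is configured, and a stage log
    with counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: List[str] = []
    chash = cfg.config_hash()
    extra = {"config_hash": chash}

    (out / "config_resolved.json").write_text(cfg.to_json() + "\n")

    try:
        traces, truth_parts, events, cells, slices = run_condition(
            cfg, cfg.groups, condition=0)
    except ValueError as exc:
        raise PipelineError(str(exc)) from exc
    log.append(f"simulate: {len(traces)} cells across {cfg.n_slices} slices")

    apio.write_traces(traces, out / "traces.csv", extra)
    import pandas as pd
    meta = pd.concat([m for m, _ in truth_parts], ignore_index=True)
    apio.write_metadata(meta, out / "metadata.csv", extra)
    from .simulate import SyntheticGroundTruth
    gt = SyntheticGroundTruth(
        cells=[c for _, t in truth_parts for c in t.cells])
    apio.write_ground_truth(gt, out / "ground_truth.json")
    n_injected = sum(c.n_events for c in gt.cells)
    log.append(f"ground truth: {n_injected} injected events")

    norms = [process_trace(
        tr, window_n=cfg.processing.window_n, k_sub=cfg.processing.k_sub,
        baseline_window_s=cfg.processing.baseline_window_s,
        filter_cutoff_hz=cfg.processing.filter_cutoff_hz,
        filter_order=cfg.processing.filter_order) for tr in traces]
    apio.write_normalized(norms, out, stem="dff", extra=extra)
    log.append(f"process: {len(norms)} traces normalized and filtered")

    apio.write_events(events, out / "events.csv", extra)
    log.append(f"detect: {len(events)} events detected")

    apio.write_summaries(cells, slices, out)
    n_resp = sum(1 for c in cells if c.responder)
    log.append(f"summarize: {len(cells)} cells, {n_resp} responders, "
               f"{len(slices)} slices")

    if cfg.post_groups is not None:
        # the post condition is an independent recording of the same slices:
        # same slice ids, distinct random substreams (condition=1)
        _, _, _, _, post_slices = run_condition(cfg, cfg.post_groups, condition=1)
        contrast = compare_conditions(slices, post_slices, seed=cfg.seed)
        with open(out / "contrast.csv", "w") as fh:
            fh.write(f"# astroplast config_hash: {chash}\n")
            contrast.to_csv(fh, index=False, float_format="%.9g",
                            lineterminator="\n")
        log.append(f"contrast: {len(contrast)} stratum/metric rows")

    (out / "log.txt").write_text("".join(
        f"{line}\n" for line in [f"astroplast run (config {chash})"] + log))
    return out
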