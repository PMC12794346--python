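# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## ΔF/F0 normalization with a sliding subthreshold baseline

Slow calcium imaging of slice preparations fights two slow nuisances —
photobleaching and drift — while the signal of interest is a sparse,
positive, multiplicative transient. The baseline estimator therefore has
to follow the slow decay of resting fluorescence but must not be dragged
upward by the transients themselves. The estimator used here maintains an
ordered buffer of the most recent *subthreshold* raw samples:

* the buffer is seeded with all samples of the first 10 s of the
  recording (the acquisition protocol's designated baseline period); if
  the sampling rate makes that more than `window_n` samples, only the
  most recent `window_n` are kept;
* for each later sample, `F0(t)` is the buffer mean *before* any
  insertion, and the sample joins the buffer (evicting the oldest beyond
  `window_n = 30`) only if it is below the buffer mean + `k_sub = 2`
  sample standard deviations (ddof = 1).

The subthreshold test precedes inclusion and `F0(t)` uses the
pre-insertion buffer, keeping the estimator causal. On an event-free
ramp, F0 is a trailing moving average and lags by about half a buffer
span ((window_n + 1)/2 samples); during a suprathreshold excursion the
buffer freezes, so F0 holds its pre-excursion value exactly. Two
documented edge behaviors: a perfectly constant starting buffer has SD 0,
so the first excursion of any size is rejected (noise in real data makes
this moot), and buffer statistics use exactly-rounded summation
(`math.fsum`), which makes F0 bit-reproducible regardless of summation
order.

Normalization is pointwise `ΔF/F0 = (F − F0)/F0`; any non-positive F0 is
treated as a hard error (a pathological baseline, not a recoverable
state). The subthreshold criterion is evaluated on raw F, since baseline
estimation precedes normalization.

## Residual-drift high-pass filter

A Butterworth high-pass at 0.001 Hz removes residual drift that the
sliding baseline leaves behind. Only the cutoff and family are dictated
by the convention this implements; the rest is this package's choice,
recorded in the output provenance and overridable:

* **order 2** — limits edge transients on recordings whose length is
  comparable to the cutoff period;
* **zero-phase** application (forward–backward, `sosfiltfilt`) so event
  onsets are not shifted;
* **mirror ("even") reflective padding** of one warm-up length (2/cutoff
  seconds, capped at the trace length). Mirror reflection keeps constants
  and slow trends continuous across the edges, so a DC offset is
  attenuated essentially to zero and, unlike point ("odd") reflection, it
  does not anti-correlate the extension with endpoint noise — point
  reflection injects low-frequency edge lobes roughly three times the
  sample-mean noise, which can corrupt the 10-s baseline statistics used
  for event detection. scipy's Gustafsson edge method was also evaluated
  and rejected: it leaves a large fraction of a DC offset at the record
  edges.

A caveat inherent to the method, not the implementation: the cutoff
period (1000 s) exceeds many recording lengths, so the first and last
~200–300 samples of any record carry filter transients. Quantities that
probe the filter itself (passband amplitude, bleach tracking) are
measured on hour-long traces and away from the edges.

## Event detection and aggregation

The detection threshold is mean + `k_event = 2` sample SD of the first
10 s of the *filtered* ΔF/F0 trace ("baseline" read as the baseline
period; the alternative reading — sliding-window statistics — is exposed
through the function's parameters but is not the default). Maximal runs
of samples `>=` threshold lasting at least `ceil(3 s × fs)` samples
(3 samples at 1 Hz) become events; ties at the threshold count as
suprathreshold. One deliberate asymmetry: if the baseline SD is exactly
zero, the threshold degenerates to the baseline mean and the test becomes
strict (`>`) — otherwise an all-constant trace would be one giant
"event". Events touching the trace end are kept if they already meet the
duration minimum; events may begin inside the baseline window; no
gap-merging is performed.

A responder is a cell with at least one detected event in the analysis
window. Event rates average over all cells; peak amplitudes pool
responders only, and a stratum with zero responders reports a null peak
mean, never 0. Slice summaries hold per-class, per-lamina and
class × lamina strata. `compare_conditions` matches slices by id across
conditions and reports, per stratum and metric, the mean paired
difference, the ratio of condition means, and 2.5/97.5 bootstrap
percentile intervals from 2000 seeded resamples of slices (the
experimental unit). A single slice pair collapses the intervals to the
point estimate and flags the row.

## Electrophysiological quantification rules

* **Evoked normalization** divides every sweep by the mean of the
  `n` pre-treatment responses closest to the treatment time by
  *timestamp* (8 for evoked EPSCs ≙ 2 min of sweeps; 5 for in vivo field
  AUC), tolerating dropped sweeps. The normalized baseline mean is 1 by
  construction.
* **Fiber classification**: conduction velocity = electrode–root distance
  / artefact-to-onset latency. C-fiber iff cv < 0.5 m/s, strictly; an
  EPSC reliably following 10-Hz stimulation is A-fiber-evoked and
  excluded regardless of cv (the exclusion precedes the velocity rule).
* **Monosynaptic identification**: zero failures at 1-Hz stimulation and
  latency jitter within a tolerance, default 1 ms — the quantitative
  stand-in this package adopts for "constant latency".
* **Series-resistance QC** fails a recording if any sample reaches
  25 MΩ, or if Rs changes by *more than* 30% (a change of exactly 30%
  passes). The change is (max − min) relative to the first recorded
  value by default; a running-baseline reference (each sample against the
  mean of its predecessors) is available as an option.
* **Paired-pulse ratio** is simply amp2/amp1 of caller-supplied peak
  amplitudes; inter-pulse baseline recovery is assumed upstream.
* **Spontaneous binning** discards the first 5 s of each 15-s sweep,
  assigns events to 300-s bins keyed on sweep start time, reports events
  per analyzed second and the mean kept-event amplitude per bin, and
  normalizes rates to the first bin (the baseline).

## Synthetic-data generator

The generator produces the statistical structure the analysis assumes,
paired with exact ground truth:

    F(t) = f_baseline · exp(−t/bleach_tau) · (1 + drift_slope·t/60)
           · (1 + Σ events(t)) + noise(t)

Transients combine multiplicatively with bleaching/drift, so an injected
peak *is* its ΔF/F0 amplitude. Each event is an instantaneous rise to its
peak followed by an exponential decay with time constant
`event_dur_mean/3`, truncated below 5% of peak (≈ `event_dur_mean` long):
at 1-Hz sampling rise kinetics are unresolvable and events present as
plateau-like. Onsets are snapped to the sampling grid so the recorded
true peak is exactly the deflection present in the sampled trace.

Placement is Poisson with two deliberate departures from a bare
homogeneous process:

* **Quiet start** (`quiet_start_s = 10`): no event begins inside the
  initial baseline period, emulating protocols that open each recording
  with a quiet pre-stimulation baseline. The realized count expectation
  is therefore `rate · (duration − quiet_start)`.
* **Separability with rate compensation**: after each event a refractory
  gap of one event duration is enforced so ground-truth events never
  overlap; to keep the realized rate equal to `event_rate` despite that
  dead time, exponential waits are drawn with mean `1/rate − occupied`
  (floored at a tenth of the nominal interval, only reachable far above
  realistic transient rates).

Default conditions: 1 Hz sampling, 600-s recordings, baseline
fluorescence 100 a.u. with additive Gaussian read noise of SD 2 (2% →
ΔF/F0 noise ≈ 0.02), transient peaks 0.5 ± 0.15 ΔF/F0 lasting ~5 s,
bleach time constant 2000 s. These give a peak-to-noise ratio of ~25;
recovery performance is also exercised down to low-amplitude events by
the amplitude spread. Fluorescence is clipped at a tiny positive floor
(10⁻⁶ of baseline) — with noise up to 10% of baseline the clip never
triggers in practice. Each cell draws from an independent substream
seeded by `(seed, cell_index)`, so populations are reproducible under
reordering; lamina labels use a separate substream so they do not perturb
trace noise.

Sweep-series simulation is a step model: means at `baseline_amplitude`
before the onset sweep and `baseline_amplitude · effect_ratio` after,
with multiplicative Gaussian noise of CV `noise_cv` (default 0.1) and one
sweep per 15 s (so 8 baseline sweeps span 2 min). The treatment time sits
halfway between the last pre-onset and first post-onset sweep.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: pixel-level imaging, ROI segmentation
and motion; correlated or non-Gaussian noise; overlapping or compound
calcium events; event-amplitude/duration distributions of real dorsal
horn cells (no such distributions are claimed — the defaults are
realistic orders of magnitude for recovery testing, not biology);
stimulus artefacts; slow non-exponential bleach; Rs drift dynamics.

## Determinism and I/O

All randomness flows from integer seeds through
`numpy.random.SeedSequence`; the pipeline runner derives per-slice,
per-condition substreams from the run seed. Outputs are plain delimited
text and JSON with floats printed at 9 significant digits and no
wall-clock timestamps, so two runs with the same seed are byte-identical.
Every table carries `#`-prefixed provenance (package version, config
hash), and the resolved config is written beside the outputs. Readers
validate before computation: traces without metadata rows, NaN values and
non-increasing time stamps are hard errors naming the offending cell or
row.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: 1000 random traces for detector/oracle agreement, 100 cells ×
600 s for rate recovery, 50 quiet cells for the false-positive rate,
hour-long traces for filter and bleach-tracking measurements, 6 slices ×
24 cells per condition for the contrast recovery, and 200 sweep series
per effect ratio for normalization bias. These sizes give stable
estimates (Monte-Carlo SEs well inside the asserted bounds) while keeping
a full run in the tens of seconds.

## Known limitations

* The 10-sample baseline (10 s at 1 Hz) makes the detection threshold a
  noisy statistic; the method inherits this from the convention it
  implements. Longer baselines can be passed explicitly.
* Filter edge transients are unavoidable at a 0.001-Hz cutoff on records
  shorter than ~1000 s; detection near record edges is correspondingly
  less reliable.
* `compare_conditions` is descriptive (estimates with bootstrap
  intervals); inferential statistics are deliberately out of scope.
* The latency-jitter tolerance for monosynaptic identification and the
  first-value reference for the Rs change rule are conventions chosen
  here; both are parameters.
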