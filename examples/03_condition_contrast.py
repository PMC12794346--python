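"""Pre/post condition contrast with a targeted manipulation.

Doubles the event rate only in mCherry- lamina-I cells of the "post"
condition and shows that the slice-level contrast isolates exactly that
stratum (rate ratio ~2; everything else ~1), with seeded bootstrap
percentile intervals from resampling slices.
"""

from astroplast import (
    CalciumSimParams,
    PopulationGroup,
    compare_conditions,
    detect_events_trace,
    generate_population,
    process_trace,
    summarize_cell,
    summarize_slice,
)


def condition(rates, seed):
    slices = []
    for s in range(6):
        groups = [PopulationGroup(cls, CalciumSimParams(
            n_cells=8, event_rate=rate, duration=600.0, seed=seed + s),
            lamina_probs={lam: 1.0})
            for (cls, lam), rate in rates.items()]
        traces, _, _ = generate_population(groups, slice_id=f"slice{s}")
        cells = [summarize_cell(detect_events_trace(process_trace(tr)), tr,
                                window_s=600.0) for tr in traces]
        slices.append(summarize_slice(cells, f"slice{s}"))
    return slices


base = {("mcherry_neg", "I"): 1.0, ("mcherry_neg", "II"): 1.0,
        ("mcherry_pos", "I"): 1.0}
bumped = dict(base)
bumped[("mcherry_neg", "I")] = 2.0

pre = condition(base, seed=100)
post = condition(bumped, seed=900)
table = compare_conditions(pre, post, seed=1)

rows = table[(table.metric == "event_rate")
             & (table.class_label != "all") & (table.lamina != "all")]
print(rows[["class_label", "lamina", "pre_mean", "post_mean",
            "ratio", "ratio_lo", "ratio_hi"]].to_string(index=False))

# The doubled stratum's ratio interval should bracket 2 and exclude 1;
# untouched strata hover around 1.  Intervals come from resampling the 6
# slices (the experimental unit) with replacement.
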