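"""Fiber classification, monosynaptic identification, PPR and Rs QC.

Walks the classification rules on a few observations: conduction velocity
below 0.5 m/s marks a C-fiber; reliably following 10-Hz stimulation marks
an A-fiber-evoked EPSC (excluded); zero failures plus constant latency at
1 Hz marks a monosynaptic input; series resistance must stay below 25 MΩ
and change by no more than 30%.
"""

from astroplast import (
    FiberObservation,
    classify_fiber,
    classify_monosynaptic,
    paired_pulse_ratio,
    qc_series_resistance,
)

obs = FiberObservation(latency_s=0.02, conduction_distance_m=0.005,
                       failures_at_1hz=0)
print(f"cv = {obs.conduction_velocity:.2f} m/s -> {classify_fiber(obs)}")
print("monosynaptic (jitter 0.5 ms):",
      classify_monosynaptic(obs, latency_jitter_s=0.0005))

fast = FiberObservation(latency_s=0.01, conduction_distance_m=0.005)
print(f"cv = {fast.conduction_velocity:.2f} m/s -> {classify_fiber(fast)} "
      "(boundary: 0.5 m/s is not a C-fiber)")

follows = FiberObservation(latency_s=0.02, conduction_distance_m=0.005,
                           follows_10hz=True)
print("follows 10 Hz ->", classify_fiber(follows))

print("PPR (100 pA, 150 pA):", paired_pulse_ratio(100.0, 150.0))

for rs in ([15.0, 16.0, 17.0], [20.0, 27.0], [10.0, 13.5]):
    res = qc_series_resistance(rs)
    print(f"Rs {rs} -> {'pass' if res.passed else 'FAIL: ' + res.reason}")

# The 10-Hz rule overrides conduction velocity; the Rs change rule is
# strict "more than 30%", measured against the first recorded value.
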