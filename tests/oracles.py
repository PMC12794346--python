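"""Independent reference implementations used as oracles.

Deliberately naive: plain-Python loops and the statistics module, sharing
no code path with the package. They exist so the vectorized/stateful
implementations can be checked for exact agreement.
"""

from __future__ import annotations

import math
import statistics
from typing import List, Tuple


def naive_local_f0(
    f,
    fs: float,
    window_n: int = 30,
    k_sub: float = 2.0,
    baseline_window_s: float = 10.0,
) -> List[float]:
    """Hand-stepped sliding subthreshold-buffer baseline rule."""
    n_base = int(math.floor(baseline_window_s * fs + 0.5))
    buf = [float(v) for v in f[:n_base]][-window_n:]
    f0 = [statistics.fmean(buf)] * n_base
    for t in range(n_base, len(f)):
        m = statistics.fmean(buf)
        s = (math.sqrt(math.fsum((v - m) ** 2 for v in buf) / (len(buf) - 1))
             if len(buf) > 1 else 0.0)
        f0.append(m)
        if f[t] < m + k_sub * s:
            buf.append(float(f[t]))
            if len(buf) > window_n:
                del buf[0]
    return f0


def brute_force_events(
    x,
    fs: float,
    baseline_window_s: float = 10.0,
    k_event: float = 2.0,
    min_duration_s: float = 3.0,
) -> List[Tuple[int, int, float, int]]:
    """Scan every suprathreshold run; returns (start, end_excl, peak, peak_idx).

    Same contract as the detector: threshold = baseline mean + k * sample
    SD of the first baseline_window_s; inclusive >= test (strict > when
    the baseline SD is exactly zero); runs shorter than
    ceil(min_duration_s * fs) samples are dropped.
    """
    n_base = int(math.floor(baseline_window_s * fs + 0.5))
    base = [float(v) for v in x[:n_base]]
    mu = statistics.fmean(base)
    sd = statistics.stdev(base) if len(base) > 1 else 0.0
    if sd == 0.0:
        def above(v):
            return v > mu
    else:
        theta = mu + k_event * sd

        def above(v):
            return v >= theta
    min_len = math.ceil(min_duration_s * fs)

    runs = []
    i = 0
    n = len(x)
    while i < n:
        if above(x[i]):
            j = i
            while j < n and above(x[j]):
                j += 1
            if j - i >= min_len:
                seg = [float(v) for v in x[i:j]]
                pk = max(seg)
                runs.append((i, j, pk, i + seg.index(pk)))
            i = j
        else:
            i += 1
    return runs
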