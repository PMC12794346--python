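import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from astroplast import CalciumSimParams, FluorescenceTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def quiet_params():
    """No events, no noise, no drift: constant trace at f_baseline."""
    return CalciumSimParams(
        n_cells=1, event_rate=0.0, noise_sd=0.0, drift_slope=0.0,
        bleach_tau=np.inf, duration=120.0, seed=0)


def make_trace(f, fs=1.0, cell_id="c0", class_label="mcherry_neg", lamina="II"):
    return FluorescenceTrace(cell_id=cell_id, class_label=class_label,
                             lamina=lamina, fs=fs, f=np.asarray(f, dtype=float))


@pytest.fixture
def trace_factory():
    return make_trace
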