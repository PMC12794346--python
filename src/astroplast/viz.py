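"""Basic per-trace diagnostic figure."""

from __future__ import annotations

from typing import Optional, Sequence

from .events import CalciumEvent
from .trace import FluorescenceTrace, NormalizedTrace


def plot_trace(
    raw: Optional[FluorescenceTrace],
    norm: NormalizedTrace,
    events: Sequence[CalciumEvent] = (),
    path=None,
):
    """Raw F with its local F0 (top) and filtered ΔF/F0 with detected
    events shaded (bottom).  Saves to ``path`` if given, else returns the
    figure."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(9, 5))
    t = norm.times()
    if raw is not None:
        axes[0].plot(raw.times(), raw.f, lw=0.8, label="F")
    axes[0].plot(t, norm.f0, lw=1.2, label="local F0")
    axes[0].set_ylabel("fluorescence (a.u.)")
    axes[0].legend(loc="upper right", fontsize=8)

    axes[1].plot(t, norm.dff, lw=0.8, color="k")
    for ev in events:
        axes[1].axvspan(ev.start_s, ev.end_s, color="tab:orange", alpha=0.3)
        axes[1].plot([ev.peak_time_s], [ev.peak_amp], "v", color="tab:red", ms=4)
    axes[1].set_xlabel("time (s)")
    axes[1].set_ylabel("ΔF/F0 (filtered)")
    fig.suptitle(norm.cell_id)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
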