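"""Static figure export for switching traces, fatigue curves and populations."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .experiment import SwitchingExperiment  # noqa: E402
from .kinetics import CycleAmplitudes  # noqa: E402
from .populations import FatigueReport  # noqa: E402

__all__ = ["plot_switching_trace", "plot_fatigue", "plot_populations"]


def plot_switching_trace(
    experiment: SwitchingExperiment, path: str | Path, max_frames: int | None = 500
) -> Path:
    """Normalized mean trace vs time; the first cycles show the on/off toggling."""
    y = experiment.normalized_mean_trace
    t = experiment.protocol.frame_times()
    if max_frames:
        t, y = t[:max_frames], y[:max_frames]
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(t, y, lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fluorescence (norm.)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_fatigue(report: FatigueReport, path: str | Path) -> Path:
    """On-level and baseline per cycle, both scaled to the initial on-state."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(report.cycle, report.on_level, label="on-level")
    ax.plot(report.cycle, report.baseline, label="baseline")
    ax.set_xlabel("switching cycle")
    ax.set_ylabel("fraction of initial on-state")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_populations(amplitudes: CycleAmplitudes, path: str | Path) -> Path:
    """Per-cycle contribution of the fast (A) and slow (B) species."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(amplitudes.cycle, amplitudes.a, color="tab:red", label="species A (fast)")
    ax.plot(amplitudes.cycle, amplitudes.b, color="tab:blue", label="species B (slow)")
    ax.set_xlabel("switching cycle")
    ax.set_ylabel("amplitude")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
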