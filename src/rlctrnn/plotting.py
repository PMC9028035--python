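"""Basic learning-curve and trajectory plots for trial traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .learners import TrialTrace

__all__ = ["plot_learning_curve", "plot_weight_trajectory"]


def plot_learning_curve(trace: TrialTrace, path) -> None:
    """Instantaneous + running-average performance and mean amplitude vs time."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(trace.t, trace.perf_now, color="tab:blue", alpha=0.3, label="P(t)")
    ax.plot(trace.t, trace.perf_avg, color="tab:blue", label="running avg $P_r$")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("performance (1/s)")
    ax2 = ax.twinx()
    ax2.plot(trace.t, trace.weight_amplitudes.mean(axis=(1, 2)), color="tab:red",
             label="mean amplitude")
    ax2.set_ylabel("fluctuation amplitude")
    ax.legend(loc="upper left")
    ax2.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_weight_trajectory(trace: TrialTrace, path, dims=((0, 0), (1, 1))) -> None:
    """Trajectory of two weight centers (thick) and effective values (thin)."""
    (j1, i1), (j2, i2) = dims
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(trace.weight_values[:, j1, i1], trace.weight_values[:, j2, i2],
            color="tab:red", lw=0.3, alpha=0.5)
    ax.plot(trace.weight_centers[:, j1, i1], trace.weight_centers[:, j2, i2],
            color="tab:red", lw=2)
    ax.scatter([trace.weight_centers[0, j1, i1]], [trace.weight_centers[0, j2, i2]],
               marker="o", color="k", zorder=3)
    ax.scatter([trace.weight_centers[-1, j1, i1]], [trace.weight_centers[-1, j2, i2]],
               marker="o", facecolor="none", edgecolor="k", zorder=3)
    ax.set_xlabel(f"w[{j1},{i1}]")
    ax.set_ylabel(f"w[{j2},{i2}]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
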