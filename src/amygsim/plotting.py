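"""Figure-style plots: per-channel heatmaps and single-cell time courses.

Plotting is a convenience layer over recorded traces; nothing in the
metrics or tests depends on it.
"""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .runner import SimulationResult

__all__ = ["plot_activity_figure", "plot_weight_figure"]


def _concat_traces(result: SimulationResult):
    if not result.traces:
        raise ValueError("run with record_trace=True to plot traces")
    times, blocks, t0 = [], [], 0.0
    boundaries = []
    for (tt, X) in result.traces:
        times.append(tt + t0)
        blocks.append(X)
        t0 += float(tt[-1]) + (tt[1] - tt[0] if len(tt) > 1 else 0.0)
        boundaries.append(t0)
    return np.concatenate(times), np.vstack(blocks), boundaries


def plot_activity_figure(result: SimulationResult, path) -> None:
    """Heatmaps for the CTX/LA/BA arrays plus ITCd/ITCv/CeM line plots."""
    t, X, _ = _concat_traces(result)
    n = result.params.n_channels
    fig, axes = plt.subplots(6, 1, figsize=(10, 12), sharex=True)
    arrays = (("CTX", X[:, 0:n]), ("LA", X[:, n:2 * n]),
              ("BA", X[:, 2 * n:3 * n]))
    for ax, (label, block) in zip(axes[:3], arrays):
        ax.imshow(block.T, aspect="auto", origin="lower",
                  extent=(t[0], t[-1], 0, n), cmap="jet",
                  vmin=0.0, vmax=result.params.B)
        ax.set_ylabel(f"{label}\ncell index")
    for ax, (label, col) in zip(
            axes[3:], (("ITCd", 3 * n), ("ITCv", 3 * n + 1),
                       ("CeM", 3 * n + 2))):
        ax.plot(t, X[:, col], lw=0.8)
        if label == "CeM":
            ax.axhline(result.params.theta_response, color="r", ls=":",
                       lw=0.8, label="response threshold")
            ax.legend(loc="upper right", fontsize=8)
        ax.set_ylabel(label)
        ax.set_ylim(0, result.params.B)
    axes[-1].set_xlabel("time (model units, CS-on intervals concatenated)")
    fig.suptitle(f"preset: {result.protocol.name}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_weight_figure(result: SimulationResult, path) -> None:
    """Per-trial heatmaps of the four plastic weight vectors."""
    n = result.params.n_channels
    mats = {"CTX→LA": np.array([r.weights.w_cl for r in result.records]),
            "LA→BA": np.array([r.weights.w_lb for r in result.records]),
            "LA→ITCd": np.array([r.weights.w_ld for r in result.records]),
            "BA→ITCv": np.array([r.weights.w_bv for r in result.records])}
    fig, axes = plt.subplots(4, 1, figsize=(10, 9), sharex=True)
    for ax, (label, M) in zip(axes, mats.items()):
        im = ax.imshow(M.T, aspect="auto", origin="lower",
                       extent=(0, len(result.records), 0, n), cmap="jet",
                       vmin=0.0, vmax=result.params.w_max)
        ax.set_ylabel(f"{label}\nchannel")
        fig.colorbar(im, ax=ax, fraction=0.02)
    axes[-1].set_xlabel("trial")
    fig.suptitle(f"synaptic weights, preset: {result.protocol.name}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
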