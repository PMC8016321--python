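"""Report figures: accuracy bars, relevance heat maps, ablation curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .channels import CHANNELS, N_CHANNELS, N_SAMPLES
from .classifier import AccuracyReport
from .reduction import AccuracyCurve
from .relevance import AggregatedRelevance


def plot_participant_accuracy(report: AccuracyReport, path=None):
    """Per-participant classification accuracy bars."""
    per = report.per_participant
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.bar([str(p) for p in per], list(per.values()), color="#4472a8")
    ax.axhline(report.mean_accuracy, color="k", ls="--", lw=1,
               label=f"mean {report.mean_accuracy:.1f}%")
    ax.set_xlabel("participant")
    ax.set_ylabel("accuracy [%]")
    ax.set_ylim(0, 105)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_relevance_map(agg: AggregatedRelevance, path=None, top_k: int | None = None):
    """12 x 100 relevance heat map with marginal sums.

    With ``top_k`` set, only the k most relevant variables are shown
    (all others blanked), mirroring a top-200 style map.
    """
    grid = agg.values.reshape(N_CHANNELS, N_SAMPLES).copy()
    if top_k is not None:
        thresh = np.sort(agg.values)[-top_k]
        grid[grid < thresh] = np.nan
    fig, axes = plt.subplots(
        2, 2, figsize=(9, 5),
        gridspec_kw={"height_ratios": [1, 3], "width_ratios": [4, 1]},
    )
    axes[0, 1].axis("off")
    axes[0, 0].plot(np.nansum(grid, axis=0), color="#4472a8")
    axes[0, 0].set_ylabel("sum over channels")
    im = axes[1, 0].imshow(grid, aspect="auto", cmap="Greys", interpolation="nearest")
    axes[1, 0].set_yticks(range(N_CHANNELS), CHANNELS, fontsize=7)
    axes[1, 0].set_xlabel("% of stance")
    axes[1, 1].barh(range(N_CHANNELS), np.nansum(grid, axis=1), color="#4472a8")
    axes[1, 1].invert_yaxis()
    axes[1, 1].set_xlabel("sum over time")
    fig.colorbar(im, ax=axes[1, 0], shrink=0.8, label="relevance")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_accuracy_curve(curve: AccuracyCurve, path=None):
    """Mean accuracy as a function of the number of retained variables."""
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.plot(curve.k_values, curve.accuracies, "o-", color="#4472a8")
    ax.axhline(curve.baseline_full, color="k", ls="--", lw=1,
               label=f"all variables: {curve.baseline_full:.1f}%")
    ax.set_xlabel("number of highest-relevance variables retained")
    ax.set_ylabel("mean accuracy [%]")
    ax.set_ylim(0, 105)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
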