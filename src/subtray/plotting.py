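"""Accuracy- and richness-versus-effort plots with 95% CI error bars."""

from __future__ import annotations

import numpy as np

from .evaluation import EvaluationSummary

__all__ = ["plot_accuracy_curve", "plot_richness_curve"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots(figsize=(5, 3.5))
    return ax


def plot_accuracy_curve(summary: EvaluationSummary, category: str | None = None,
                        ax=None):
    """Percent accuracy vs number of subsampled cells, with a 100% line."""
    ax = _get_ax(ax)
    df = summary.curves
    for cat, block in df.groupby("category", sort=False):
        if category is not None and cat != category:
            continue
        err = 1.96 * block["accuracy_se"]
        ax.errorbar(block["k"], block["accuracy_mean"], yerr=err,
                    marker="o", ms=3, capsize=2, label=cat)
    ax.axhline(100.0, color="k", lw=0.8)
    ax.set_xlabel("number of subsampled cells")
    ax.set_ylabel("percent accuracy")
    ax.set_title(f"{summary.preset}: abundance accuracy")
    ax.legend(fontsize=8)
    return ax


def plot_richness_curve(summary: EvaluationSummary, category: str | None = None,
                        ax=None):
    """Percent taxa richness vs cells, with the quick-scan point at k_max."""
    ax = _get_ax(ax)
    df = summary.curves
    for cat, block in df.groupby("category", sort=False):
        if category is not None and cat != category:
            continue
        err = 1.96 * block["richness_se"]
        ax.errorbar(block["k"], block["richness_mean"], yerr=err,
                    marker="o", ms=3, capsize=2, label=cat)
        last = block[block["k"] == summary.k_max]
        if len(last) and np.isfinite(last["richness_with_scan_mean"].iloc[0]):
            ax.plot(summary.k_max + 0.5,
                    last["richness_with_scan_mean"].iloc[0],
                    marker="*", ms=9, ls="none", label=f"{cat} + scan")
    ax.axhline(100.0, color="k", lw=0.8)
    ax.set_xlabel("number of subsampled cells")
    ax.set_ylabel("percent taxa richness")
    ax.set_title(f"{summary.preset}: taxa richness")
    ax.legend(fontsize=8)
    return ax
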