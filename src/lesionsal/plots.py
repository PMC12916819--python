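"""Figure helpers for the validation experiments.

Matplotlib with the Agg backend; each function writes a file and returns
the path, so headless pipeline runs can produce figures without a display.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .experiments import CATEGORIES, ContextProbeResult, PeakStats  # noqa: E402


def plot_peak_violins(stats: PeakStats, path, channel_name: str = "channel 1"):
    """Violin plots of per-example maximum and minimum saliency by category."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
    for ax, which, title in zip(axes, ("max", "min"), ("maximum", "minimum")):
        data, labels = [], []
        for cat in CATEGORIES:
            vals = stats.category_values(cat, which)
            if len(vals) >= 2:
                data.append(vals)
                labels.append(f"{cat}\n(n={len(vals)})")
        if data:
            ax.violinplot(data, showmedians=True)
            ax.set_xticks(range(1, len(labels) + 1), labels)
        ax.set_title(f"{title} saliency ({channel_name})")
        ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_context_curves(result: ContextProbeResult, path):
    """Mean Softmax score (±1 sd band) and detected-lesion count per dilation."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    it = result.iterations
    axes[0].plot(it, result.mean, lw=2)
    axes[0].fill_between(it, result.mean - result.std, result.mean + result.std,
                         alpha=0.25)
    axes[0].axhline(result.threshold, ls="--", color="grey", lw=1)
    axes[0].set_xlabel("dilation iteration (~mm of context)")
    axes[0].set_ylabel("mean Softmax score in $\\Omega$")
    axes[1].plot(it, result.detected_count, lw=2, drawstyle="steps-post")
    axes[1].set_xlabel("dilation iteration (~mm of context)")
    axes[1].set_ylabel(f"detected lesions (of {result.n_lesions})")
    for ax in axes:
        ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
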