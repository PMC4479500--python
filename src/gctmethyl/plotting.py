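"""Optional figures: per-group β density (violin-style) and PCA scatter.

matplotlib is imported lazily so the analysis stack works without it.
"""

from __future__ import annotations

import pandas as pd

from .summaries import GroupDistributionSummary


def _pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (install the 'plots' extra)") from exc
    return plt


def plot_distributions(summaries: list[GroupDistributionSummary], path) -> None:
    """Horizontal density silhouettes per group, one panel per probe subset."""
    plt = _pyplot()
    subsets = sorted({s.subset for s in summaries})
    fig, axes = plt.subplots(1, len(subsets), figsize=(3 * len(subsets), 4), squeeze=False)
    for ax, subset in zip(axes[0], subsets):
        group_summaries = [s for s in summaries if s.subset == subset]
        for i, s in enumerate(group_summaries):
            dens = s.density / max(s.density.max(), 1e-12) * 0.4
            ax.fill_betweenx(s.density_grid, i - dens, i + dens, alpha=0.6)
            ax.plot([i - 0.2, i + 0.2], [s.median] * 2, color="black", lw=1.5)
        ax.set_xticks(range(len(group_summaries)))
        ax.set_xticklabels([s.group for s in group_summaries], rotation=45, ha="right")
        ax.set_ylim(0, 1)
        ax.set_title(subset)
        ax.set_ylabel("β")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca(scores: pd.DataFrame, path) -> None:
    """PC1 vs PC2 sample scatter coloured by group (expects a 'group' column)."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, sub in scores.groupby("group"):
        ax.scatter(sub["PC1"], sub["PC2"], label=str(group), s=25, alpha=0.8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
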