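"""Figure renderers: correlation-coloured segment maps, region abundance
bars with significance stars, and PCA score plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .phantom import REGION_NAMES

__all__ = ["render_segment_map", "abundance_bars", "pca_score_plot"]

# continuous white->red->green->black scale, matching the published
# convention that the two least-correlated segments sit at the ends
SEGMENT_CMAP = matplotlib.colors.LinearSegmentedColormap.from_list(
    "lipidseg", ["white", "red", "green", "black"])


def render_segment_map(smap, path=None, ax=None):
    """Colour-rendered segment map using the continuous correlation bar."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    else:
        fig = ax.figure
    img = smap.color_raster()
    masked = np.ma.masked_invalid(img)
    cmap = SEGMENT_CMAP.copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(masked, cmap=cmap, vmin=0, vmax=1, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="fingerprint correlation scale")
    ax.set_xticks([])
    ax.set_yticks([])
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def abundance_bars(table, comparisons=None, species=None, path=None):
    """Grouped bars of mean region abundance (+/- SD over samples) per
    species, star-annotated when a comparison table is supplied."""
    regions = list(table.index.get_level_values("region").unique())
    species = list(species) if species is not None else list(table.columns)
    means = table.groupby(level="region").mean().loc[regions, species]
    sds = table.groupby(level="region").std().loc[regions, species]
    x = np.arange(len(species))
    w = 0.8 / len(regions)
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(species)), 4))
    for i, r in enumerate(regions):
        ax.bar(x + i * w, means.loc[r], w, yerr=sds.loc[r], capsize=2, label=r)
    if comparisons is not None:
        for j, sp in enumerate(species):
            sub = comparisons[comparisons["species"] == sp]
            stars = "".join(sorted(set(s for s in sub["stars"] if s), key=len)[-1:])
            if stars:
                ax.text(x[j] + 0.4, means[sp].max() * 1.05, stars, ha="center")
    ax.set_xticks(x + 0.4 - w / 2)
    ax.set_xticklabels(species, rotation=90, fontsize=7)
    ax.set_ylabel("relative abundance")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


def pca_score_plot(pca_result, path=None):
    """PC1/PC2 score plot coloured by region."""
    scores = pca_result.scores
    evr = pca_result.explained_variance_ratio
    fig, ax = plt.subplots(figsize=(5, 4))
    for region, sub in scores.groupby(level="region"):
        ax.scatter(sub["PC1"], sub["PC2"], label=region, s=30)
    ax.set_xlabel(f"PC1 ({evr[0]*100:.0f}% of variance)")
    ax.set_ylabel(f"PC2 ({evr[1]*100:.0f}% of variance)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
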