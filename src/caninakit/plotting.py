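"""Simple static figures: SCO bubble map, coverage densities, metaplots.

All plots are cosmetic; no quantitative output depends on them.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def bubble_map(long_df: pd.DataFrame, path=None, ax=None):
    """Bubble map of per-chromosome SCO hit counts (one row per taxon)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    taxa = list(long_df["taxon"].unique())
    chroms = list(long_df["chrom"].unique())
    for _, row in long_df.iterrows():
        x = chroms.index(row["chrom"])
        y = taxa.index(row["taxon"])
        if row["count"] > 0:
            ax.scatter(x, y, s=10 + 3 * row["count"], alpha=0.6, color="tab:purple")
    ax.set_xticks(range(len(chroms)))
    ax.set_xticklabels(chroms, rotation=90, fontsize=6)
    ax.set_yticks(range(len(taxa)))
    ax.set_yticklabels(taxa)
    if path:
        plt.tight_layout()
        plt.savefig(path, dpi=120)
        plt.close()
    return ax


def coverage_density(track_df: pd.DataFrame, genome_map, path=None, ax=None,
                     bandwidth: float | None = None):
    """Per-subgenome kernel-density view of window depths (bandwidth is
    a display choice only)."""
    from scipy.stats import gaussian_kde

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    df = track_df.assign(
        subgenome=track_df["chrom"].map(lambda c: genome_map.chrom(c).subgenome))
    for sub, grp in df.groupby("subgenome"):
        depths = grp["depth" if "depth" in grp.columns else "value"].to_numpy()
        if len(depths) < 3 or depths.std() == 0:
            continue
        kde = gaussian_kde(depths, bw_method=bandwidth)
        xs = np.linspace(0, depths.max() * 1.2, 200)
        ax.plot(xs, kde(xs), label=sub)
    ax.set_xlabel("window depth")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    if path:
        plt.tight_layout()
        plt.savefig(path, dpi=120)
        plt.close()
    return ax


def metaplot_figure(metaplot_df: pd.DataFrame, path=None):
    """One panel per signal kind, lines per subgenome, telomere (0) to
    centromere (1)."""
    kinds = list(metaplot_df["kind"].unique())
    fig, axes = plt.subplots(1, len(kinds), figsize=(3 * len(kinds), 2.5),
                             squeeze=False)
    for ax, kind in zip(axes[0], kinds):
        sub_df = metaplot_df[metaplot_df["kind"] == kind]
        for sub, grp in sub_df.groupby("subgenome"):
            ax.plot(grp["scaled_coord"], grp["value"], label=sub, lw=1)
        ax.set_title(kind, fontsize=8)
        ax.set_xlabel("telomere -> centromere")
    axes[0][0].legend(fontsize=6)
    if path:
        plt.tight_layout()
        plt.savefig(path, dpi=120)
        plt.close(fig)
    return fig
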