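"""Minimal figure helpers: volcano plot and clustered heatmap.

These are conveniences for eyeballing results, not publication graphics.
All functions accept an optional matplotlib Axes and return it.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .profile_qc import ClusterResult

__all__ = ["volcano", "cluster_heatmap"]


def volcano(result: pd.DataFrame, ax=None, title: str | None = None):
    """Scatter diff (log2) vs -log10 permutation p, colouring significant
    enriched/depleted proteins."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = {"enriched": "#7a3fb5", "depleted": "#2b6cb0", "ns": "0.7"}
    for label, sub in result.groupby("label"):
        ax.scatter(
            sub["diff"], sub["neg_log10_p"], s=8, c=colors.get(label, "0.7"), label=label
        )
    ax.axvline(0, lw=0.5, color="0.4")
    ax.set_xlabel("difference (log2)")
    ax.set_ylabel(r"$-\log_{10}$ p")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def cluster_heatmap(cluster: ClusterResult, ax=None, cmap: str = "RdBu_r"):
    """Heatmap of the row/column-ordered Z-scored matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(3, 0.1 * len(cluster.row_order))))
    data = cluster.ordered.to_numpy()
    vmax = float(np.nanmax(np.abs(data))) or 1.0
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(cluster.col_order)))
    ax.set_xticklabels(cluster.col_order, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("sample")
    ax.set_ylabel(f"{len(cluster.row_order)} proteins (Z-scored)")
    ax.figure.colorbar(im, ax=ax, shrink=0.6, label="Z")
    return ax
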