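"""Heatmap rendering of parameter-space maps.

Renders replicate-averaged cell summaries (mean neighbor counts,
advantage ratio, chi-squared compatibility) as (phi, rho) heatmaps.
Unavailable cells — no converged replicate — are drawn in white.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["heatmap"]


def heatmap(
    df: pd.DataFrame,
    value: str,
    out_path=None,
    title: str | None = None,
    mask_unavailable: bool = True,
):
    """Pivot a long-format cell table into a (rho, phi) heatmap.

    ``df`` must carry columns ``phi``, ``rho`` and ``value``; if a
    boolean ``available`` column exists, unavailable cells are masked
    white.  Returns the matplotlib figure.
    """
    pivot = df.pivot(index="rho", columns="phi", values=value)
    data = pivot.to_numpy(float)
    if mask_unavailable and "available" in df.columns:
        avail = df.pivot(index="rho", columns="phi", values="available").to_numpy(bool)
        data = np.where(avail, data, np.nan)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("white")
    im = ax.pcolormesh(
        pivot.columns.to_numpy(float),
        pivot.index.to_numpy(float),
        np.ma.masked_invalid(data),
        cmap=cmap,
        shading="nearest",
    )
    ax.set_xlabel(r"fraction of low-ranking males  $\phi$")
    ax.set_ylabel(r"weight ratio  $\rho$")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label=value)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
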