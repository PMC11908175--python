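"""Figure helpers: marker/Jaccard/coefficient heatmaps.

Thin matplotlib wrappers; every function returns the Axes and optionally
saves to a path. Figure aesthetics are deliberately minimal.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _heatmap(frame: pd.DataFrame, title: str, cmap: str, out: str | Path | None,
             vmin=None, vmax=None):
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * frame.shape[1]), max(3, 0.25 * frame.shape[0]))
    )
    im = ax.imshow(frame.to_numpy(), aspect="auto", cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(frame.shape[1]))
    ax.set_xticklabels(frame.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(frame.shape[0]))
    ax.set_yticklabels(frame.index, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return ax


def plot_scaled_marker_heatmap(scaled_avg: pd.DataFrame,
                               genes: list[str] | None = None,
                               out: str | Path | None = None):
    """Scaled-average-expression heatmap (clusters x selected genes)."""
    frame = scaled_avg[genes] if genes else scaled_avg
    return _heatmap(frame, "scaled average expression", "RdBu_r", out,
                    vmin=-2.5, vmax=2.5)


def plot_jaccard_heatmap(similarity: pd.DataFrame, order: list[str],
                         out: str | Path | None = None):
    """Jaccard similarity heatmap in most-to-least-similar leaf order."""
    frame = similarity.loc[order, order]
    return _heatmap(frame, "Jaccard similarity", "viridis", out, vmin=0, vmax=1)


def plot_binary_code_heatmap(matrix: pd.DataFrame, order: list[str] | None = None,
                             out: str | Path | None = None):
    """Binarised TF-code heatmap, optionally in a given cluster order."""
    frame = matrix.loc[order] if order else matrix
    return _heatmap(frame, "binary TF codes", "Greys", out, vmin=0, vmax=1)


def plot_coefficient_heatmap(coeff: pd.DataFrame, out: str | Path | None = None):
    """Bulk-mapping coefficient heatmap (cell types x clusters)."""
    return _heatmap(coeff.T, "bulk correlation coefficients", "magma", out)
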