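"""PNG figures: FIM heatmaps, importance maps, and disconnection maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_fim_heatmap", "plot_importance_map", "plot_disconnection_map"]


def plot_fim_heatmap(f: np.ndarray, path, title: str = "Fisher information matrix"):
    """Save the (typically sparse) FIM of a small model as a heatmap."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(f, cmap="magma", interpolation="nearest")
    ax.set_xlabel("parameter index")
    ax.set_ylabel("parameter index")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_importance_map(values: np.ndarray, path,
                        bias_pre=None, bias_post=None,
                        title: str = "weight importance"):
    """Visible-by-hidden importance map, optionally flanked by bias importances."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    vals = np.where(np.isnan(values), 0.0, values)
    im = ax.imshow(vals, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xlabel("hidden unit")
    ax.set_ylabel("visible unit")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_disconnection_map(prob: np.ndarray, layout: tuple[int, int], path,
                           title: str = "visible disconnection probability"):
    """Per-pixel probability (across seeds) of ending up disconnected."""
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.asarray(prob, dtype=float).reshape(layout),
                   cmap="gray_r", vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
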