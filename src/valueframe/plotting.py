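"""Plotting helpers for effect maps and cluster results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .cluster import ClusterResult
from .tfr import EffectMap

__all__ = ["plot_effect_map", "plot_tmap_with_clusters"]


def _pcolor(ax, values, freqs, times_ms, vmax=None):
    vmax = vmax or np.nanmax(np.abs(values)) or 1.0
    mesh = ax.pcolormesh(times_ms, freqs, values, cmap="RdBu_r",
                         vmin=-vmax, vmax=vmax, shading="nearest")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("frequency (Hz)")
    return mesh


def plot_effect_map(effect: EffectMap, ax=None, vmax=None):
    """Heat map of one subject's variance-normalized effect; edges greyed."""
    if ax is None:
        _, ax = plt.subplots()
    shown = np.where(effect.valid, effect.values, np.nan)
    mesh = _pcolor(ax, shown, effect.freqs, effect.times_ms, vmax)
    ax.set_title(effect.name)
    plt.colorbar(mesh, ax=ax, label=r"$\hat\beta$ / SE")
    return ax


def plot_tmap_with_clusters(result: ClusterResult, freqs, times_ms, ax=None,
                            alpha: float | None = None):
    """Group T-map with significant clusters outlined."""
    if ax is None:
        _, ax = plt.subplots()
    mesh = _pcolor(ax, result.tmap, freqs, times_ms)
    plt.colorbar(mesh, ax=ax, label=f"T({result.df})")
    alpha = alpha if alpha is not None else result.config.alpha
    for c in result.clusters:
        if c.p is None or c.p >= alpha:
            continue
        mask = np.zeros_like(result.tmap, dtype=float)
        mask[c.bins[:, 0], c.bins[:, 1]] = 1.0
        ax.contour(times_ms, freqs, mask, levels=[0.5], colors="k",
                   linewidths=1.2)
    ax.set_title(f"{len(result.significant)} significant cluster(s)")
    return ax
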