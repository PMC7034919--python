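"""Basic matplotlib renders: paths, sweep heatmaps, condition boxplots.

Matplotlib is an optional dependency; it is imported lazily so the rest
of the package works without it.
"""

from __future__ import annotations

import math

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_path(path, ax=None, success_radius: float = 1.0):
    """Draw one trajectory, coloured by homing success."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ok = path.arrival_distance <= success_radius
    xy = path.positions
    ax.plot(xy[:, 0], xy[:, 1], color="tab:green" if ok else "tab:red", lw=0.8)
    ax.plot(*path.release, marker="o", color="tab:orange", ms=5)
    ax.plot(*path.nest, marker="+", color="grey", ms=10, mew=2)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax

def plot_sweep_heatmap(result, ax=None, vmax: float | None = None):
    """Median-arrival heatmap over the (gain, baseline) grid."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(result.median_arrival, origin="lower", aspect="auto",
                   cmap="viridis_r", vmax=vmax)
    ax.set_xticks(range(len(result.spec.baseline_values)),
                  [f"{b:g}" for b in result.spec.baseline_values])
    ax.set_yticks(range(len(result.spec.gain_values)),
                  ["inf" if math.isinf(g) else f"{g:g}"
                   for g in result.spec.gain_values])
    ax.set_xlabel("baseline (deg)")
    ax.set_ylabel("gain")
    plt.colorbar(im, ax=ax, label="median arrival distance (m)")
    ax.set_title(result.memory_mode)
    return ax

def plot_condition_boxplots(results, ax=None):
    """Boxplots of arrival distances, one per robustness condition."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(results) + 2, 4))
    ax.boxplot([r.arrival_distances for r in results],
               tick_labels=[r.name for r in results])
    ax.set_ylabel("arrival distance (m)")
    ax.tick_params(axis="x", rotation=45)
    return ax

def plot_familiarity_map(fmap, heading: float, mode: str, ax=None):
    """Single-heading familiarity map as an image over the lattice."""
    plt = _plt()
    from .mapping import single_heading_map
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    n = fmap.grid.n_side
    vals = single_heading_map(fmap, heading, mode).reshape(n, n)
    half = fmap.grid.extent / 2
    cx, cy = fmap.grid.centre
    lim = (0.0, 1.0) if mode != "opponent" else (-np.nanmax(np.abs(vals)),
                                                 np.nanmax(np.abs(vals)))
    im = ax.imshow(vals.T, origin="lower", cmap="RdBu_r" if mode == "opponent"
                   else "viridis", vmin=lim[0], vmax=lim[1],
                   extent=(cx - half, cx + half, cy - half, cy + half))
    ax.plot(*fmap.nest, marker="+", color="k", ms=10, mew=2)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    plt.colorbar(im, ax=ax, label=f"{mode} familiarity")
    return ax
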