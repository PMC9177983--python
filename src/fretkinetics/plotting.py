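"""Matplotlib figure helpers for trajectories, heat maps, TDPs and fits.

These are convenience views of the analysis containers; numerical content
always comes from the analysis modules themselves.
"""

from __future__ import annotations

import numpy as np


def plot_trajectory(traj, ideal=None, ax=None):
    """FRET trajectory with an optional idealized path overlaid in red."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    t = np.arange(len(traj.efficiency)) * traj.frame_interval
    ax.plot(t, traj.efficiency, color="0.2", lw=0.7, label="FRET")
    if ideal is not None and ideal.segments:
        for s in ideal.segments:
            ax.hlines(s.level, s.start_frame * traj.frame_interval,
                      s.end_frame * traj.frame_interval, color="crimson", lw=1.8)
    ax.axvline(traj.valid_until * traj.frame_interval, color="0.6", ls="--", lw=0.8)
    ax.set(xlabel="time (s)", ylabel="FRET", ylim=(-0.1, 1.1))
    return ax


def plot_heatmap(hist, time_edges, fret_edges, ax=None):
    """Temporal ensemble heat map (FRET vs time)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    m = ax.pcolormesh(time_edges, fret_edges, hist, cmap="inferno", shading="auto")
    plt.colorbar(m, ax=ax, label="normalized counts")
    ax.set(xlabel="time (s)", ylabel="FRET")
    return ax


def plot_tdp(tdp, ax=None):
    """Transition density plot with the identity diagonal marked."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    m = ax.pcolormesh(tdp.x, tdp.y, tdp.density, cmap="viridis", shading="auto")
    plt.colorbar(m, ax=ax, label="density")
    ax.plot([0, 1], [0, 1], color="w", lw=0.8, ls="--")
    ax.set(xlabel="FRET before", ylabel="FRET after", xlim=(0, 1), ylim=(0, 1))
    return ax


def plot_mixture(sample, fit, bin_width=0.02, hist_range=(-0.1, 1.1), ax=None):
    """FRET histogram with fitted Gaussian components and their sum."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    edges = np.arange(hist_range[0], hist_range[1] + bin_width / 2, bin_width)
    counts, edges, _ = ax.hist(sample, bins=edges, color="0.8", label="data")
    x = np.linspace(*hist_range, 400)
    total = np.zeros_like(x)
    dx = bin_width
    for comp in fit.components:
        y = (comp.weight * len(sample) * dx / (comp.sd * np.sqrt(2 * np.pi))
             * np.exp(-0.5 * ((x - comp.mean) / comp.sd) ** 2))
        ax.plot(x, y, lw=1.2)
        total += y
    ax.plot(x, total, color="k", lw=1.6, label="sum")
    ax.set(xlabel="FRET", ylabel="count")
    ax.legend()
    return ax
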