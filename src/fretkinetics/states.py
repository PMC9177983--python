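"""Regime classification, transition density plots and ensemble heat maps.

The trajectory taxonomy follows the three-regime convention used for
transcription elongation complexes: FRET in [0.7, 1] is "high"
(catalytically inactive, pre-translocated), [0.4, 0.7) is "mid"
(catalytically poised, post-translocated) and [0, 0.4) is "low" (extended
or terminated).  An idealized trajectory is "static" if it holds exactly one
state; dynamic trajectories are labelled by the set of regimes they visit,
with any trajectory touching both high and low counted as "high-low".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .idealize import IdealizedTrajectory

__all__ = [
    "RegimeBounds",
    "TRAJECTORY_CLASSES",
    "assign_regime",
    "classify_trajectory",
    "class_percentages",
    "extract_transitions",
    "TdpGrid",
    "build_tdp",
    "asymmetry_score",
    "temporal_heatmap",
]

TRAJECTORY_CLASSES = ("static", "high", "mid", "low", "high-mid", "mid-low", "high-low")


@dataclass
class RegimeBounds:
    """FRET regime boundaries: [0, low_max) low, [low_max, mid_max) mid,
    [mid_max, upper] high.  The published ranges overlap at the boundaries
    (0.4-0.7 and 0.7-1); the half-open convention here puts 0.7 in "high"
    and 0.4 in "mid".  Levels outside [0, upper] are clamped and counted in
    ``clamp_count`` (they arise from noise excursions)."""

    low_max: float = 0.4
    mid_max: float = 0.7
    upper: float = 1.0
    clamp_count: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.low_max < self.mid_max < self.upper:
            raise ValueError("require 0 < low_max < mid_max < upper")


def assign_regime(level: float, bounds: RegimeBounds) -> str:
    """Map a fitted FRET level to 'low', 'mid' or 'high'."""
    if level < 0 or level > bounds.upper:
        bounds.clamp_count += 1
        level = min(max(level, 0.0), bounds.upper)
    if level < bounds.low_max:
        return "low"
    if level < bounds.mid_max:
        return "mid"
    return "high"


def classify_trajectory(ideal: IdealizedTrajectory, bounds: RegimeBounds) -> str:
    """Assign one of the seven mutually exclusive trajectory classes.

    Classification uses the fitted mean level of each state, not per-frame
    values.  A trajectory visiting both high and low regimes (with or without
    mid) is "high-low".
    """
    if not ideal.segments:
        raise ValueError("trajectory has no segments")
    levels = set(ideal.levels)
    if len(levels) == 1:
        return "static"
    regimes = {assign_regime(lv, bounds) for lv in levels}
    if regimes == {"high"}:
        return "high"
    if regimes == {"mid"}:
        return "mid"
    if regimes == {"low"}:
        return "low"
    if regimes == {"high", "mid"}:
        return "high-mid"
    if regimes == {"mid", "low"}:
        return "mid-low"
    return "high-low"  # visits both high and low, with or without mid


def class_percentages(
    ideals: list[IdealizedTrajectory], bounds: RegimeBounds | None = None
) -> pd.DataFrame:
    """Per-class counts and percentages over a trajectory ensemble."""
    if not ideals:
        raise ValueError("no trajectories to classify")
    bounds = bounds or RegimeBounds()
    labels = [classify_trajectory(i, bounds) for i in ideals]
    counts = {c: labels.count(c) for c in TRAJECTORY_CLASSES}
    n = len(labels)
    return pd.DataFrame(
        {
            "trajectory_class": list(TRAJECTORY_CLASSES),
            "count": [counts[c] for c in TRAJECTORY_CLASSES],
            "percent": [100.0 * counts[c] / n for c in TRAJECTORY_CLASSES],
        }
    )


def extract_transitions(ideal: IdealizedTrajectory) -> list[tuple[float, float]]:
    """(level before, level after) for every adjacent segment boundary."""
    lv = ideal.levels
    return list(zip(lv[:-1], lv[1:]))


@dataclass
class TdpGrid:
    """Kernel-density transition density plot over [0, 1] x [0, 1].

    ``density[i, j]`` is the density at (before = x[j], after = y[i]);
    it integrates to 1 over the unit square whenever transitions exist.
    """

    x: np.ndarray  # FRET-before grid centers
    y: np.ndarray  # FRET-after grid centers
    density: np.ndarray
    bandwidth: tuple[float, float]
    n_transitions: int

    def integral(self) -> float:
        dx = self.x[1] - self.x[0] if len(self.x) > 1 else 1.0
        dy = self.y[1] - self.y[0] if len(self.y) > 1 else 1.0
        return float(self.density.sum() * dx * dy)


def _silverman_bandwidth(values: np.ndarray) -> float:
    # product-kernel rule-of-thumb in d=2: h = sigma * (4/(d+2))^(1/(d+4)) * n^(-1/(d+4))
    n = len(values)
    sigma = float(np.std(values))
    if sigma == 0 or n < 2:
        return 0.01
    return sigma * (4.0 / 4.0) ** (1.0 / 6.0) * n ** (-1.0 / 6.0)


def build_tdp(
    transitions: list[tuple[float, float]],
    grid_size: int = 100,
    bandwidth: float | str = "auto",
) -> TdpGrid:
    """2-D Gaussian kernel density of (FRET before, FRET after) pairs.

    ``bandwidth="auto"`` applies Silverman's rule per axis.  The density is
    renormalized to integrate to 1 on the unit square; an empty transition
    list yields an all-zero grid.
    """
    centers = (np.arange(grid_size) + 0.5) / grid_size
    if not transitions:
        return TdpGrid(centers, centers, np.zeros((grid_size, grid_size)), (0.0, 0.0), 0)
    before = np.array([t[0] for t in transitions], dtype=float)
    after = np.array([t[1] for t in transitions], dtype=float)
    if bandwidth == "auto":
        hx, hy = _silverman_bandwidth(before), _silverman_bandwidth(after)
    else:
        hx = hy = float(bandwidth)
        if hx <= 0:
            raise ValueError("bandwidth must be > 0")
    hx, hy = max(hx, 1e-3), max(hy, 1e-3)
    kx = np.exp(-0.5 * ((centers[None, :] - before[:, None]) / hx) ** 2)  # n x G
    ky = np.exp(-0.5 * ((centers[None, :] - after[:, None]) / hy) ** 2)
    density = ky.T @ kx  # G_after x G_before
    cell = (1.0 / grid_size) ** 2
    total = density.sum() * cell
    if total > 0:
        density = density / total
    return TdpGrid(centers, centers, density, (hx, hy), len(transitions))


def asymmetry_score(tdp: TdpGrid) -> float:
    """Directionality of transitions: (FRET-decreasing - increasing) mass,
    normalized by total off-diagonal mass.

    +1 means every transition lowers FRET (a fully irreversible cascade),
    0 means mirror symmetry about the diagonal (reversible exchange).
    Raises if there is no off-diagonal mass to compare.
    """
    if tdp.n_transitions == 0:
        raise ValueError("asymmetry undefined for an empty TDP")
    xb = tdp.x[None, :]  # before
    ya = tdp.y[:, None]  # after
    below = tdp.density[ya < xb].sum()  # FRET decreased
    above = tdp.density[ya > xb].sum()
    off = below + above
    if off <= 0:
        raise ValueError("zero off-diagonal mass; asymmetry undefined")
    return float((below - above) / off)


def temporal_heatmap(
    trajectories,
    n_time_bins: int | None = None,
    fret_bins: int = 50,
    fret_range: tuple[float, float] = (-0.1, 1.1),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble 2-D histogram of FRET vs time over usable frames.

    Returns ``(hist, time_edges, fret_edges)`` with ``hist`` of shape
    (fret_bins, time_bins), column-normalized to the number of molecules
    contributing at each time.  Default time binning is one bin per frame.
    """
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("no trajectories")
    dt = trajs[0].frame_interval
    n_frames = max(len(t) for t in trajs)
    n_time_bins = n_time_bins or n_frames
    t_edges = np.linspace(0, n_frames * dt, n_time_bins + 1)
    f_edges = np.linspace(fret_range[0], fret_range[1], fret_bins + 1)
    hist = np.zeros((fret_bins, n_time_bins))
    counts = np.zeros(n_time_bins)
    for traj in trajs:
        e = traj.efficiency[: traj.valid_until]
        frames = np.arange(len(e))
        ok = np.isfinite(e)
        h, _, _ = np.histogram2d(e[ok], frames[ok] * dt, bins=(f_edges, t_edges))
        hist += h
        cnt, _ = np.histogram(frames[ok] * dt, bins=t_edges)
        counts += cnt > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        hist = np.where(counts[None, :] > 0, hist / np.clip(counts[None, :], 1, None), 0.0)
    return hist, t_edges, f_edges
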