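"""Intensity-to-FRET conversion, photobleach detection, Förster prediction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityTrace",
    "FretTrajectory",
    "compute_fret",
    "detect_photobleach",
    "forster_efficiency",
]


@dataclass
class IntensityTrace:
    """Per-molecule donor/acceptor intensity time series (arbitrary units)."""

    molecule_id: str
    frame_interval: float
    donor: np.ndarray
    acceptor: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be 1-D arrays of equal length")
        if len(self.donor) < 1:
            raise ValueError("trace must contain at least one frame")

    def __len__(self) -> int:
        return len(self.donor)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.donor)) * self.frame_interval


@dataclass
class FretTrajectory:
    """Proximity-ratio FRET efficiency series with an analysis horizon.

    ``efficiency`` holds one value per frame (NaN where the corrected total
    intensity was too low to form a meaningful ratio); downstream analyses use
    only frames before ``valid_until``, the first detected photobleach event.
    """

    molecule_id: str
    frame_interval: float
    efficiency: np.ndarray
    valid_until: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if not 0 <= self.valid_until <= len(self.efficiency):
            raise ValueError("valid_until must lie within the trace")

    def __len__(self) -> int:
        return len(self.efficiency)

    @property
    def usable(self) -> np.ndarray:
        """Efficiency values before the bleach horizon, masked frames dropped."""
        e = self.efficiency[: self.valid_until]
        return e[np.isfinite(e)]


def detect_photobleach(
    trace: IntensityTrace,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
    drop_fraction: float = 0.5,
    persistence: int = 5,
) -> int:
    """First frame of a persistent collapse of the total corrected intensity.

    The baseline is the median corrected total over the first 10 frames.  The
    bleach frame is the start of the first run of at least ``persistence``
    consecutive frames below ``drop_fraction`` of baseline (a below-threshold
    run extending to the trace end also counts, so late bleaches are not
    missed).  Returns the trace length if no such run exists, and 0 for a
    trace that is dark from the start.
    """
    total = (trace.donor - background_donor) + (trace.acceptor - background_acceptor)
    n = len(total)
    baseline = float(np.median(total[: min(10, n)]))
    if baseline <= 0:
        return 0
    below = total < drop_fraction * baseline
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if (j - i) >= persistence or j == n:
                return i
            i = j
        else:
            i += 1
    return n


def compute_fret(
    trace: IntensityTrace,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
    denominator_floor: float = 0.1,
    bleach_kwargs: dict | None = None,
) -> FretTrajectory:
    """Background-corrected proximity-ratio FRET efficiency.

    E_t = (A_t - bg_A) / ((A_t - bg_A) + (D_t - bg_D)).  Frames whose
    corrected total falls below ``denominator_floor`` times the initial
    10-frame median are masked NaN (post-bleach ratios are meaningless).
    No gamma, donor-leakage or direct-excitation corrections are applied:
    simulator and analyzer share the same proximity-ratio convention.
    """
    if not (np.isfinite(background_donor) and np.isfinite(background_acceptor)):
        raise ValueError("backgrounds must be finite")
    d = trace.donor - background_donor
    a = trace.acceptor - background_acceptor
    total = d + a
    baseline = float(np.median(total[: min(10, len(total))]))
    floor = denominator_floor * max(baseline, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(total > floor, a / total, np.nan)
    valid_until = detect_photobleach(
        trace, background_donor, background_acceptor, **(bleach_kwargs or {})
    )
    meta = dict(trace.metadata)
    return FretTrajectory(
        molecule_id=trace.molecule_id,
        frame_interval=trace.frame_interval,
        efficiency=eff,
        valid_until=valid_until,
        metadata=meta,
    )


def forster_efficiency(r: float, r0: float) -> float:
    """Predicted FRET efficiency E = 1 / (1 + (r/r0)^6) for dye separation r.

    ``r`` and the Förster radius ``r0`` must share units; for Cy3-Cy5,
    r0 is about 5.4 nm.
    """
    if r0 <= 0:
        raise ValueError("Förster radius must be > 0")
    if r < 0:
        raise ValueError("distance must be >= 0")
    return 1.0 / (1.0 + (r / r0) ** 6)
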