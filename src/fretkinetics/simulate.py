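"""Synthetic single-molecule FRET data generation.

Everything the analysis pipeline consumes can be generated here with known
ground truth: donor/acceptor intensity trajectories driven by a continuous-time
Markov chain over discrete FRET states, single-step photobleaching of either
dye, ensemble fluorescence-decay curves, dwell-time samples with right
censoring, steady-state binding isotherms and Gaussian-mixture FRET samples.

The default acquisition settings mirror a typical TIRF experiment on
surface-immobilized transcription elongation complexes: 200 ms frames,
120 s movies, Cy5 photobleaching lifetime near 11 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fret import IntensityTrace

__all__ = [
    "StateSpec",
    "KineticScheme",
    "PhotophysicsModel",
    "SimConfig",
    "simulate_state_path",
    "simulate_intensity_trace",
    "simulate_molecule",
    "simulate_ensemble_decay",
    "simulate_dwells",
    "simulate_binding_series",
    "simulate_fret_sample",
]


@dataclass(frozen=True)
class StateSpec:
    """One discrete kinetic state with its FRET level and emission noise."""

    label: str
    fret_level: float
    emission_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fret_level <= 1.0:
            raise ValueError(f"fret_level must lie in [0, 1], got {self.fret_level}")
        if self.emission_sd < 0:
            raise ValueError("emission_sd must be >= 0")


@dataclass
class KineticScheme:
    """Continuous-time Markov chain over discrete FRET states.

    ``rates[i, j]`` is the transition rate i -> j in s^-1; the diagonal is
    zero by convention.  A state whose row sums to zero is absorbing.
    """

    states: list[StateSpec]
    rates: np.ndarray
    initial_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        k = len(self.states)
        if self.rates.shape != (k, k):
            raise ValueError(f"rates must be {k}x{k}, got {self.rates.shape}")
        if np.any(np.diag(self.rates) != 0):
            raise ValueError("rates diagonal must be zero by convention")
        off = self.rates[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if self.initial_probs is None:
            self.initial_probs = np.full(k, 1.0 / k)
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        if abs(self.initial_probs.sum() - 1.0) > 1e-12:
            raise ValueError("initial_probs must sum to 1 within 1e-12")
        levels = [s.fret_level for s in self.states]
        if len(set(levels)) != len(levels):
            raise ValueError("fret_level values must be distinct")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def fret_levels(self) -> np.ndarray:
        return np.array([s.fret_level for s in self.states])

    def exit_rates(self) -> np.ndarray:
        """Total exit rate per state (row sums); zero marks an absorbing state."""
        return self.rates.sum(axis=1)


@dataclass
class PhotophysicsModel:
    """Dye photophysics for a two-channel donor-excitation measurement.

    Bleaching of each dye is an irreversible single exponential-time event;
    the default acceptor rate corresponds to a mean Cy5 survival of 11.3 s.
    Blinking is not modeled (suppressed experimentally with Trolox).
    """

    total_intensity: float = 1000.0
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 1.0 / 11.3
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")
        for name in ("donor_bleach_rate", "acceptor_bleach_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimConfig:
    """Acquisition settings: 200 ms frames, 120 s (600-frame) movies."""

    frame_interval: float = 0.2
    n_frames: int = 600
    n_molecules: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_state_path(
    scheme: KineticScheme,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample a continuous-time Markov path and discretize it to frames.

    The chain is simulated by Gillespie jumps (exponential holding times with
    rate equal to the state's total exit rate); the recorded state of frame
    ``i`` is the state occupying the chain at the frame midpoint
    ``(i + 0.5) * frame_interval``.  Dwells shorter than a frame can therefore
    be lost, just as in real sampled data.

    Returns an int array of state indices of length ``n_frames``.
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    exit_rates = scheme.exit_rates()
    t_end = config.n_frames * config.frame_interval
    midpoints = (np.arange(config.n_frames) + 0.5) * config.frame_interval

    state = int(rng.choice(scheme.n_states, p=scheme.initial_probs))
    path = np.empty(config.n_frames, dtype=np.intp)
    t = 0.0
    i = 0  # next frame midpoint to fill
    while i < config.n_frames:
        rate = exit_rates[state]
        t_next = t + rng.exponential(1.0 / rate) if rate > 0 else t_end + 1.0
        while i < config.n_frames and midpoints[i] < t_next:
            path[i] = state
            i += 1
        if t_next > t_end:
            break
        probs = scheme.rates[state] / rate
        state = int(rng.choice(scheme.n_states, p=probs))
        t = t_next
    return path


def simulate_intensity_trace(
    path: np.ndarray,
    scheme: KineticScheme,
    phot: PhotophysicsModel,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    molecule_id: str = "mol0",
) -> IntensityTrace:
    """Render a state path into donor/acceptor intensity channels.

    Pre-bleach, acceptor = I_tot * E + bg_A and donor = I_tot * (1 - E) + bg_D
    plus per-channel additive Gaussian noise.  After the sampled acceptor
    bleach frame FRET is lost: the acceptor falls to background and the full
    intensity appears in the donor channel.  After the donor bleach frame both
    channels fall to background.  Sampled bleach frames (or None) are recorded
    in the trace metadata as ground truth.
    """
    path = np.asarray(path)
    if len(path) != config.n_frames:
        raise ValueError("path length must equal n_frames")
    rng = _as_rng(rng if rng is not None else config.seed)

    def _bleach_frame(rate: float) -> int | None:
        if rate <= 0:
            return None
        t = rng.exponential(1.0 / rate)
        frame = int(math.floor(t / config.frame_interval))
        return frame if frame < config.n_frames else None

    acc_bleach = _bleach_frame(phot.acceptor_bleach_rate)
    don_bleach = _bleach_frame(phot.donor_bleach_rate)

    e = scheme.fret_levels[path]
    # per-state extra emission noise enters as efficiency jitter
    sds = np.array([s.emission_sd for s in scheme.states])[path]
    if np.any(sds > 0):
        e = e + rng.normal(0.0, 1.0, size=len(e)) * sds

    acceptor = phot.total_intensity * e
    donor = phot.total_intensity * (1.0 - e)
    if acc_bleach is not None:
        acceptor[acc_bleach:] = 0.0
        donor[acc_bleach:] = phot.total_intensity
    if don_bleach is not None:
        acceptor[don_bleach:] = 0.0
        donor[don_bleach:] = 0.0
    donor = donor + phot.background_donor
    acceptor = acceptor + phot.background_acceptor
    if phot.noise_sd > 0:
        donor = donor + rng.normal(0.0, phot.noise_sd, size=len(donor))
        acceptor = acceptor + rng.normal(0.0, phot.noise_sd, size=len(acceptor))

    meta = {
        "acceptor_bleach_frame": acc_bleach,
        "donor_bleach_frame": don_bleach,
    }
    return IntensityTrace(
        molecule_id=molecule_id,
        frame_interval=config.frame_interval,
        donor=donor,
        acceptor=acceptor,
        metadata=meta,
    )


def simulate_molecule(
    scheme: KineticScheme,
    phot: PhotophysicsModel,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    molecule_id: str = "mol0",
) -> tuple[IntensityTrace, np.ndarray]:
    """Convenience: sample a state path and its intensity trace together."""
    rng = _as_rng(rng if rng is not None else config.seed)
    path = simulate_state_path(scheme, config, rng)
    trace = simulate_intensity_trace(path, scheme, phot, config, rng, molecule_id)
    return trace, path


def simulate_ensemble_decay(
    amplitudes,
    lifetimes,
    tgrid,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
):
    """Multi-exponential ensemble decay y(t) = sum_j A_j exp(-t / tau_j) + noise.

    Returns ``(tgrid, y)`` as float arrays.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    lifetimes = np.asarray(lifetimes, dtype=float)
    if amplitudes.shape != lifetimes.shape:
        raise ValueError("amplitudes and lifetimes must have equal length")
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be > 0")
    t = np.asarray(tgrid, dtype=float)
    y = np.sum(amplitudes[:, None] * np.exp(-t[None, :] / lifetimes[:, None]), axis=0)
    if noise_sd > 0:
        y = y + _as_rng(rng).normal(0.0, noise_sd, size=len(t))
    return t, y


def simulate_dwells(
    dist: tuple,
    n: int,
    censor_at: float | None = None,
    rng: np.random.Generator | int | None = None,
    molecule_prefix: str = "sim",
    state_level: float = 0.5,
):
    """I.i.d. dwell-time sample from an exponential or gamma distribution.

    ``dist`` is ``("exponential", tau)`` or ``("gamma", shape, scale)``.
    Dwells exceeding ``censor_at`` are truncated there and flagged
    right-censored.  Returns a list of :class:`~fretkinetics.dwells.DwellRecord`.
    """
    from .dwells import DwellRecord

    rng = _as_rng(rng)
    kind = dist[0]
    if kind == "exponential":
        (tau,) = dist[1:]
        if tau <= 0:
            raise ValueError("tau must be > 0")
        draws = rng.exponential(tau, size=n)
    elif kind == "gamma":
        shape, scale = dist[1:]
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        draws = rng.gamma(shape, scale, size=n)
    else:
        raise ValueError(f"unknown dwell distribution {kind!r}")

    records = []
    for i, d in enumerate(draws):
        censored = censor_at is not None and d > censor_at
        records.append(
            DwellRecord(
                molecule_id=f"{molecule_prefix}{i}",
                state_level=state_level,
                start_s=0.0,
                duration_s=float(min(d, censor_at) if censored else d),
                left_censored=False,
                right_censored=bool(censored),
            )
        )
    return records


# the eight-point Mfd titration grid used throughout the SPR experiments, in M
DEFAULT_TITRATION_M = tuple(c * 1e-9 for c in (0, 10, 20, 40, 80, 160, 320, 640))


def simulate_binding_series(
    kd: float,
    rmax: float,
    concentrations=DEFAULT_TITRATION_M,
    noise_frac: float = 0.0,
    rng: np.random.Generator | int | None = None,
    ligand: str = "synthetic",
):
    """Steady-state 1:1 binding isotherm R_eq = R_max [A] / ([A] + K_D).

    Multiplicative Gaussian noise of relative sd ``noise_frac`` is applied.
    Returns a :class:`~fretkinetics.ensemble.BindingSeries`.
    """
    from .ensemble import BindingSeries

    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    req = rmax * conc / (conc + kd)
    if noise_frac > 0:
        req = req * (1.0 + _as_rng(rng).normal(0.0, noise_frac, size=len(conc)))
    return BindingSeries(concentration=conc, response=req, ligand=ligand)


def simulate_fret_sample(
    mixture,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` FRET values from a Gaussian mixture [(weight, mean, sd), ...].

    Values are returned unclipped; downstream histogram fits bin over
    [-0.1, 1.1] to accommodate noise excursions outside [0, 1].
    """
    mixture = [(float(w), float(m), float(s)) for (w, m, s) in mixture]
    weights = np.array([w for w, _, _ in mixture])
    if np.any(weights < 0):
        raise ValueError("mixture weights must be >= 0")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    if n == 0:
        return np.empty(0)
    rng = _as_rng(rng)
    comps = rng.choice(len(mixture), size=n, p=weights)
    means = np.array([m for _, m, _ in mixture])[comps]
    sds = np.array([s for _, _, s in mixture])[comps]
    return rng.normal(means, sds)
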