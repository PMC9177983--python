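"""Discrete-state idealization of FRET trajectories.

A maximum-likelihood Gaussian-emission hidden Markov model is fit per
trajectory by expectation-maximization with multiple restarts; the number of
states is chosen by BIC and the idealized piecewise-constant path is the
Viterbi decoding.  This fills the role that variational-Bayes idealizers
(vbFRET and kin) play in single-molecule pipelines, with a fully specified
frequentist model-selection rule instead of a variational posterior.

Frames masked as undefined by the FRET conversion (NaN efficiency) stay in
the chain but contribute no emission term to the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .fret import FretTrajectory

__all__ = [
    "HmmModel",
    "Segment",
    "IdealizedTrajectory",
    "InsufficientDataError",
    "fit_hmm",
    "select_states",
    "viterbi_path",
    "idealize_trajectory",
    "forward_loglik",
    "backward_loglik",
    "posterior_probs",
]

# Emission sd floor (FRET units).  Keeps EM away from zero-variance collapse:
# states with sd below real shot noise (~0.01) are always spurious splits.
_MIN_SD = 0.01


class InsufficientDataError(ValueError):
    """Raised when a trajectory is too short to support the requested model."""


@dataclass
class HmmModel:
    """Gaussian-emission HMM with states ordered by ascending mean."""

    means: np.ndarray
    sds: np.ndarray
    transition_matrix: np.ndarray
    initial_probs: np.ndarray
    log_likelihood: float = np.nan
    n_obs: int = 0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        k = len(self.means)
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition_matrix shape mismatch")
        if np.any(np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("transition_matrix rows must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("emission sds must be > 0")

    @property
    def n_states(self) -> int:
        return len(self.means)

    @property
    def n_parameters(self) -> int:
        # K means + K sds + K(K-1) transition + (K-1) initial = K^2 + 2K - 1
        k = self.n_states
        return k * k + 2 * k - 1

    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_parameters * np.log(max(self.n_obs, 1))


@dataclass(frozen=True)
class Segment:
    """Half-open frame interval [start_frame, end_frame) at one fitted level."""

    start_frame: int
    end_frame: int
    level: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class IdealizedTrajectory:
    """Piecewise-constant idealization of one FRET trajectory."""

    molecule_id: str
    frame_interval: float
    segments: list[Segment]
    n_states: int = 0
    log_likelihood: float = np.nan
    bic: float = np.nan
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end_frame != b.start_frame:
                raise ValueError("segments must tile the trajectory without gaps")
            if a.level == b.level:
                raise ValueError("adjacent segments must differ in level")

    @property
    def levels(self) -> list[float]:
        return [s.level for s in self.segments]

    @property
    def n_frames(self) -> int:
        return self.segments[-1].end_frame if self.segments else 0

    def frame_levels(self) -> np.ndarray:
        """Per-frame fitted level over [0, n_frames)."""
        out = np.empty(self.n_frames)
        for s in self.segments:
            out[s.start_frame : s.end_frame] = s.level
        return out


def _emission_loglik(obs: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """T x K frame emission log-densities; NaN observations contribute 0."""
    x = obs[:, None]
    with np.errstate(invalid="ignore"):
        ll = -0.5 * ((x - means[None, :]) / sds[None, :]) ** 2 - np.log(
            sds[None, :] * np.sqrt(2.0 * np.pi)
        )
    ll[~np.isfinite(obs), :] = 0.0
    return ll


def forward_loglik(obs, means, sds, transmat, initial_probs):
    """Log-likelihood of the observation sequence via the forward algorithm.

    Returns ``(loglik, log_alpha)`` with ``log_alpha`` of shape T x K.
    """
    frame_ll = _emission_loglik(np.asarray(obs, float), np.asarray(means), np.asarray(sds))
    log_a = np.log(np.clip(transmat, 1e-300, None))
    t_len, k = frame_ll.shape
    log_alpha = np.empty((t_len, k))
    log_alpha[0] = np.log(np.clip(initial_probs, 1e-300, None)) + frame_ll[0]
    for t in range(1, t_len):
        log_alpha[t] = frame_ll[t] + logsumexp(log_alpha[t - 1][:, None] + log_a, axis=0)
    return float(logsumexp(log_alpha[-1])), log_alpha


def backward_loglik(obs, means, sds, transmat, initial_probs):
    """Log-likelihood via the backward recursion; returns ``(loglik, log_beta)``."""
    frame_ll = _emission_loglik(np.asarray(obs, float), np.asarray(means), np.asarray(sds))
    log_a = np.log(np.clip(transmat, 1e-300, None))
    t_len, k = frame_ll.shape
    log_beta = np.zeros((t_len, k))
    for t in range(t_len - 2, -1, -1):
        log_beta[t] = logsumexp(log_a + (frame_ll[t + 1] + log_beta[t + 1])[None, :], axis=1)
    ll = float(
        logsumexp(np.log(np.clip(initial_probs, 1e-300, None)) + frame_ll[0] + log_beta[0])
    )
    return ll, log_beta


def posterior_probs(obs, model: HmmModel) -> np.ndarray:
    """Per-frame posterior state probabilities (T x K, rows sum to 1)."""
    ll, log_alpha = forward_loglik(
        obs, model.means, model.sds, model.transition_matrix, model.initial_probs
    )
    _, log_beta = backward_loglik(
        obs, model.means, model.sds, model.transition_matrix, model.initial_probs
    )
    log_gamma = log_alpha + log_beta - ll
    return np.exp(log_gamma)


def _scaled_forward_backward(obs, means, sds, transmat, initial_probs):
    """Scaled linear-space Baum-Welch pass.

    Emission densities are normalized per frame by their maximum (the shifts
    accumulate into the log-likelihood exactly), then the classic scaling
    recursion runs in linear space — orders of magnitude faster than per-frame
    logsumexp for the long traces this package fits.

    Returns ``(loglik, gamma, xi_sum)``.
    """
    frame_ll = _emission_loglik(obs, means, sds)
    shift = frame_ll.max(axis=1)
    emis = np.exp(frame_ll - shift[:, None])  # in (0, 1], max 1 per frame
    t_len, k = emis.shape
    alpha = np.empty((t_len, k))
    c = np.empty(t_len)  # scaling factors
    a0 = initial_probs * emis[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, t_len):
        a = (alpha[t - 1] @ transmat) * emis[t]
        c[t] = a.sum()
        if c[t] <= 0:  # numerically dead row; re-seed uniformly
            a = np.full(k, 1.0 / k)
            c[t] = 1.0
        alpha[t] = a / c[t]
    ll = float(np.log(c).sum() + shift.sum())

    beta = np.empty((t_len, k))
    beta[-1] = 1.0
    xi_sum = np.zeros((k, k))
    for t in range(t_len - 2, -1, -1):
        be = beta[t + 1] * emis[t + 1]
        beta[t] = (transmat @ be) / c[t + 1]
        xi_sum += np.outer(alpha[t], be / c[t + 1]) * transmat
    gamma = alpha * beta
    gamma /= np.clip(gamma.sum(axis=1, keepdims=True), 1e-300, None)
    return ll, gamma, xi_sum


def _em_once(obs, means, sds, transmat, initial_probs, max_iter, tol):
    """One EM run from the given start; returns (loglik, params)."""
    means, sds = means.copy(), sds.copy()
    transmat, initial_probs = transmat.copy(), initial_probs.copy()
    k = len(means)
    prev_ll = -np.inf
    finite = np.isfinite(obs)
    for _ in range(max_iter):
        ll, gamma, xi_sum = _scaled_forward_backward(
            obs, means, sds, transmat, initial_probs
        )

        initial_probs = gamma[0] / gamma[0].sum()
        denom = xi_sum.sum(axis=1, keepdims=True)
        transmat = np.where(denom > 0, xi_sum / np.clip(denom, 1e-300, None), 1.0 / k)
        transmat /= transmat.sum(axis=1, keepdims=True)
        # Gaussian M-step over observed (unmasked) frames only
        w = gamma[finite]
        x = obs[finite]
        wsum = np.clip(w.sum(axis=0), 1e-12, None)
        means = (w * x[:, None]).sum(axis=0) / wsum
        var = (w * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / wsum
        sds = np.sqrt(np.clip(var, _MIN_SD**2, None))

        if ll - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
    return prev_ll, means, sds, transmat, initial_probs


def fit_hmm(
    traj: FretTrajectory,
    n_states: int,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> HmmModel:
    """Maximum-likelihood Gaussian HMM for one trajectory.

    Restarts EM ``n_restarts`` times from quantile-based means perturbed by
    the seeded generator and keeps the best run by log-likelihood.  States in
    the returned model are sorted by ascending mean.  Raises
    :class:`InsufficientDataError` when fewer than ``5 * n_states`` usable
    (pre-bleach, unmasked) frames are available.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = np.asarray(traj.efficiency[: traj.valid_until], dtype=float)
    usable = obs[np.isfinite(obs)]
    if len(usable) < 5 * n_states:
        raise InsufficientDataError(
            f"need >= {5 * n_states} usable frames for K={n_states}, got {len(usable)}"
        )
    k = n_states
    q = np.quantile(usable, (np.arange(k) + 0.5) / k)
    spread = max(float(usable.std()), 0.02)

    lo, hi = float(usable.min()), float(usable.max())
    best = None
    for r in range(n_restarts):
        # restart 0 starts at the quantiles; later restarts perturb them hard
        # enough to reach rarely-visited levels anywhere in the data range
        means0 = q if r == 0 else np.clip(q + rng.normal(0.0, spread, k), lo, hi)
        means0 = np.sort(means0)
        sds0 = np.full(k, max(spread / max(k, 1), _MIN_SD))
        transmat0 = np.full((k, k), 0.05 / max(k - 1, 1))
        np.fill_diagonal(transmat0, 0.95 if k > 1 else 1.0)
        init0 = np.full(k, 1.0 / k)
        ll, means, sds, transmat, init = _em_once(
            obs, means0, sds0, transmat0, init0, max_iter, tol
        )
        if best is None or ll > best[0]:
            best = (ll, means, sds, transmat, init)

    ll, means, sds, transmat, init = best
    order = np.argsort(means)
    model = HmmModel(
        means=means[order],
        sds=sds[order],
        transition_matrix=transmat[np.ix_(order, order)],
        initial_probs=init[order],
        log_likelihood=ll,
        n_obs=len(usable),
    )
    return model


def select_states(
    traj: FretTrajectory,
    k_max: int = 6,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 10,
    **fit_kwargs,
) -> tuple[HmmModel, int]:
    """Fit K = 1..k_max and pick the model minimizing BIC (ties -> smaller K)."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best_model, best_k, best_bic = None, None, np.inf
    for k in range(1, k_max + 1):
        try:
            model = fit_hmm(traj, k, seed=rng, n_restarts=n_restarts, **fit_kwargs)
        except InsufficientDataError:
            break
        bic = model.bic()
        if bic < best_bic - 1e-12:  # strict improvement; ties keep smaller K
            best_model, best_k, best_bic = model, k, bic
    if best_model is None:
        raise InsufficientDataError("trajectory too short for any model")
    return best_model, best_k


def _merge_close_states(model: HmmModel, min_separation: float = 0.05) -> np.ndarray:
    """Map state index -> merged level; near-degenerate states share a level.

    Two states are merged when their means differ by less than
    ``min_separation`` and their +/-1 sd intervals overlap, since downstream
    classification needs distinct levels.
    """
    k = model.n_states
    group = np.arange(k)
    for i in range(1, k):  # means sorted ascending
        j = group[i - 1]
        close = abs(model.means[i] - model.means[j]) < min_separation
        overlap = (model.means[i] - model.sds[i]) <= (model.means[j] + model.sds[j])
        if close and overlap:
            group[i] = j
    levels = np.empty(k)
    for g in np.unique(group):
        members = group == g
        levels[members] = model.means[members].mean()
    return levels


def viterbi_path(traj: FretTrajectory, model: HmmModel) -> IdealizedTrajectory:
    """Most-probable state path, merged into segments.

    Dynamic-program ties are broken toward the lower state index.  States
    whose fitted means are nearly degenerate (|delta mean| < 0.05 with
    overlapping +/-1 sd) are merged to one level before segments are built.
    """
    obs = np.asarray(traj.efficiency[: traj.valid_until], dtype=float)
    t_len = len(obs)
    if t_len == 0:
        return IdealizedTrajectory(
            molecule_id=traj.molecule_id,
            frame_interval=traj.frame_interval,
            segments=[],
            n_states=model.n_states,
            log_likelihood=model.log_likelihood,
        )
    frame_ll = _emission_loglik(obs, model.means, model.sds)
    log_a = np.log(np.clip(model.transition_matrix, 1e-300, None))
    k = model.n_states
    delta = np.empty((t_len, k))
    psi = np.zeros((t_len, k), dtype=np.intp)
    delta[0] = np.log(np.clip(model.initial_probs, 1e-300, None)) + frame_ll[0]
    for t in range(1, t_len):
        cand = delta[t - 1][:, None] + log_a  # K_prev x K_cur
        psi[t] = np.argmax(cand, axis=0)  # argmax takes the first (lowest) index on ties
        delta[t] = cand[psi[t], np.arange(k)] + frame_ll[t]
    states = np.empty(t_len, dtype=np.intp)
    states[-1] = int(np.argmax(delta[-1]))
    for t in range(t_len - 2, -1, -1):
        states[t] = psi[t + 1][states[t + 1]]

    merged_levels = _merge_close_states(model)
    levels = merged_levels[states]
    segments: list[Segment] = []
    start = 0
    for t in range(1, t_len + 1):
        if t == t_len or levels[t] != levels[start]:
            segments.append(Segment(start, t, float(levels[start])))
            start = t
    ll, _ = forward_loglik(
        obs, model.means, model.sds, model.transition_matrix, model.initial_probs
    )
    return IdealizedTrajectory(
        molecule_id=traj.molecule_id,
        frame_interval=traj.frame_interval,
        segments=segments,
        n_states=model.n_states,
        log_likelihood=ll,
        bic=model.bic(),
        metadata={"state_path": states},
    )


def idealize_trajectory(
    traj: FretTrajectory,
    k_max: int = 6,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 10,
    **fit_kwargs,
) -> IdealizedTrajectory:
    """Model-select, fit and decode one trajectory in a single call."""
    model, _ = select_states(traj, k_max=k_max, seed=seed, n_restarts=n_restarts, **fit_kwargs)
    return viterbi_path(traj, model)
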