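"""Dwell-time extraction and censored lifetime fits.

Residence times in a FRET window are collected from idealized trajectories
and fit with a single-exponential model (one rate-limiting step) or a gamma
model (several sequential steps of comparable rate).  First-observed dwells
are left-censored and excluded from fitting by default; dwells truncated by
the end of observation or by photobleaching are right-censored and enter the
likelihood through survival terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .idealize import IdealizedTrajectory

__all__ = [
    "DwellRecord",
    "ExpFit",
    "GammaFit",
    "InestimableError",
    "extract_dwells",
    "fit_exponential",
    "fit_gamma",
    "compare_dwell_models",
]

GAMMA_SHAPE_CAP = 100.0


class InestimableError(ValueError):
    """Raised when the data cannot identify the requested lifetime."""


@dataclass
class DwellRecord:
    """One residence interval in a FRET window."""

    molecule_id: str
    state_level: float
    start_s: float
    duration_s: float
    left_censored: bool = False
    right_censored: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")


@dataclass
class ExpFit:
    """Censored single-exponential MLE: tau is the mean lifetime."""

    tau: float
    se_tau: float
    n_events: int
    n_censored: int
    log_likelihood: float

    @property
    def n_parameters(self) -> int:
        return 1

    def aic(self) -> float:
        return 2.0 * self.n_parameters - 2.0 * self.log_likelihood

    def bic(self) -> float:
        n = self.n_events + self.n_censored
        return self.n_parameters * np.log(n) - 2.0 * self.log_likelihood


@dataclass
class GammaFit:
    """Censored gamma MLE.  ``scale`` is the characteristic lifetime of each
    of ``shape`` sequential sub-steps; the mean dwell is shape * scale."""

    shape: float
    scale: float
    se_shape: float
    se_scale: float
    n_events: int
    n_censored: int
    log_likelihood: float
    shape_capped: bool = False

    @property
    def characteristic_lifetime(self) -> float:
        return self.scale

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def n_parameters(self) -> int:
        return 2

    def aic(self) -> float:
        return 2.0 * self.n_parameters - 2.0 * self.log_likelihood

    def bic(self) -> float:
        n = self.n_events + self.n_censored
        return self.n_parameters * np.log(n) - 2.0 * self.log_likelihood


def extract_dwells(
    ideal: IdealizedTrajectory, window: tuple[float, float]
) -> list[DwellRecord]:
    """Dwells in ``window``: maximal runs of consecutive segments whose levels
    fall inside the (inclusive) FRET window.

    The first segment of a trajectory starts before observation did, so a run
    containing it is left-censored; a run ending at the analysis horizon
    (trace end or photobleach) is right-censored.
    """
    lo, hi = window
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("window must be a non-empty interval within [0, 1]")
    records: list[DwellRecord] = []
    segs = ideal.segments
    i = 0
    while i < len(segs):
        if lo <= segs[i].level <= hi:
            j = i
            while j < len(segs) and lo <= segs[j].level <= hi:
                j += 1
            start = segs[i].start_frame
            end = segs[j - 1].end_frame
            mean_level = float(
                np.average(
                    [s.level for s in segs[i:j]],
                    weights=[s.n_frames for s in segs[i:j]],
                )
            )
            records.append(
                DwellRecord(
                    molecule_id=ideal.molecule_id,
                    state_level=mean_level,
                    start_s=start * ideal.frame_interval,
                    duration_s=(end - start) * ideal.frame_interval,
                    left_censored=(i == 0),
                    right_censored=(end == ideal.n_frames),
                )
            )
            i = j
        else:
            i += 1
    return records


def _split_durations(dwells, include_left_censored):
    kept = [d for d in dwells if include_left_censored or not d.left_censored]
    events = np.array([d.duration_s for d in kept if not d.right_censored])
    censored = np.array([d.duration_s for d in kept if d.right_censored])
    return events, censored


def fit_exponential(
    dwells: list[DwellRecord], include_left_censored: bool = False
) -> ExpFit:
    """Censored single-exponential MLE.

    The closed form is tau-hat = (sum of all durations, censored included) /
    (number of uncensored events); SE = tau-hat / sqrt(n_uncensored).
    """
    events, censored = _split_durations(dwells, include_left_censored)
    if len(events) == 0:
        raise InestimableError("no uncensored dwell events; tau is inestimable")
    total = events.sum() + censored.sum()
    tau = float(total / len(events))
    ll = float(-len(events) * np.log(tau) - total / tau)
    return ExpFit(
        tau=tau,
        se_tau=tau / np.sqrt(len(events)),
        n_events=len(events),
        n_censored=len(censored),
        log_likelihood=ll,
    )


def _gamma_negloglik(params, events, censored):
    log_shape, log_scale = params
    shape, scale = np.exp(log_shape), np.exp(log_scale)
    ll = np.sum(
        (shape - 1.0) * np.log(events)
        - events / scale
        - special.gammaln(shape)
        - shape * np.log(scale)
    )
    if len(censored):
        surv = special.gammaincc(shape, censored / scale)
        ll += np.sum(np.log(np.clip(surv, 1e-300, None)))
    return -ll


def fit_gamma(dwells: list[DwellRecord], include_left_censored: bool = False) -> GammaFit:
    """Censored gamma MLE via numerical optimization in log-parameters.

    Initialization is the method of moments on the uncensored events;
    right-censored dwells contribute survival terms.  Standard errors come
    from the inverse observed information (finite-difference Hessian).  The
    shape is capped at 100 (with a warning) to guard degenerate samples with
    vanishing spread.
    """
    events, censored = _split_durations(dwells, include_left_censored)
    if len(events) < 5:
        raise InestimableError("need >= 5 uncensored events for a gamma fit")
    m, v = events.mean(), events.var()
    shape0 = min(max(m * m / v, 0.05), GAMMA_SHAPE_CAP) if v > 0 else GAMMA_SHAPE_CAP
    scale0 = m / shape0
    x0 = np.log([shape0, scale0])
    res = optimize.minimize(
        _gamma_negloglik, x0, args=(events, censored), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success:
        raise RuntimeError(f"gamma MLE did not converge: {res.message}; best {np.exp(res.x)}")
    shape, scale = np.exp(res.x)
    capped = False
    if shape > GAMMA_SHAPE_CAP:
        warnings.warn("gamma shape capped at 100 (degenerate, near-constant dwells)")
        shape, capped = GAMMA_SHAPE_CAP, True
        scale = m / shape
    # observed information in (shape, scale) by central differences
    def nll_nat(p):
        return _gamma_negloglik(np.log(p), events, censored)

    p_hat = np.array([shape, scale])
    h = 1e-4 * p_hat
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            pp = p_hat.copy(); pp[i] += h[i]; pp[j] += h[j]; fpp = nll_nat(pp)
            pm = p_hat.copy(); pm[i] += h[i]; pm[j] -= h[j]; fpm = nll_nat(pm)
            mp = p_hat.copy(); mp[i] -= h[i]; mp[j] += h[j]; fmp = nll_nat(mp)
            mm = p_hat.copy(); mm[i] -= h[i]; mm[j] -= h[j]; fmm = nll_nat(mm)
            hess[i, j] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
        se_shape, se_scale = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_shape = se_scale = np.nan
    return GammaFit(
        shape=float(shape),
        scale=float(scale),
        se_shape=float(se_shape),
        se_scale=float(se_scale),
        n_events=len(events),
        n_censored=len(censored),
        log_likelihood=float(-_gamma_negloglik(np.log([shape, scale]), events, censored)),
        shape_capped=capped,
    )


def compare_dwell_models(
    dwells: list[DwellRecord], include_left_censored: bool = False
) -> dict:
    """Fit both dwell models and report AIC/BIC; preference = lower BIC.

    A BIC difference below 2 is flagged indeterminate.
    """
    exp_fit = fit_exponential(dwells, include_left_censored)
    gam_fit = fit_gamma(dwells, include_left_censored)
    delta_aic = exp_fit.aic() - gam_fit.aic()
    delta_bic = exp_fit.bic() - gam_fit.bic()
    preferred = "gamma" if delta_bic > 0 else "exponential"
    return {
        "exponential": exp_fit,
        "gamma": gam_fit,
        "delta_aic": float(delta_aic),
        "delta_bic": float(delta_bic),
        "preferred": preferred,
        "indeterminate": bool(abs(delta_bic) < 2.0),
    }
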