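"""Ensemble-level model fits.

Four fits live here:

* a global two-exponential decay, y_i(t) = A_1,i exp(-t/tau) + A_2,i
  exp(-t/tau_2,i), fit jointly across conditions with the photobleaching
  lifetime tau shared and selected conditions constrained to a single
  component (A_2,i = 0);
* a three-Gaussian decomposition of a FRET-state histogram;
* the 1:1 steady-state affinity model R_eq = R_max [A]/([A] + K_D);
* 2-aminopurine difference-spectrum helpers (subtraction, moving average).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import optimize

__all__ = [
    "DecayCurve",
    "GlobalDecayFit",
    "global_decay_fit",
    "MixtureComponent",
    "MixtureFit",
    "fit_three_gaussians",
    "BindingSeries",
    "SsaFit",
    "fit_ssa",
    "extract_req",
    "overhang_trend",
    "Spectrum",
    "difference_spectrum",
    "moving_average",
]


# --------------------------------------------------------------------------
# global multi-exponential decay


@dataclass
class DecayCurve:
    """One condition's normalized ensemble fluorescence decay."""

    condition_id: str
    time_s: np.ndarray
    intensity: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time and intensity must align")


@dataclass
class GlobalDecayFit:
    """Result of the shared-lifetime global decay fit."""

    tau: float  # shared (photobleaching) lifetime, s
    se_tau: float
    amplitudes_1: dict  # condition -> A_1
    amplitudes_2: dict  # condition -> A_2 (0 when constrained)
    tau_2: dict  # condition -> second lifetime, s (None when constrained)
    se: dict  # parameter name -> standard error
    chi_square: float
    n_obs: int
    success: bool


def global_decay_fit(
    curves: list[DecayCurve],
    single_component: tuple[str, ...] = (),
    normalize: bool = True,
) -> GlobalDecayFit:
    """Fit all decay curves jointly with a shared slow lifetime.

    Conditions named in ``single_component`` have their second amplitude
    fixed at zero (pure photobleaching).  Curves are normalized to their
    first point before fitting.  Levenberg-Marquardt least squares on the
    summed residuals; convergence tolerance on chi-square 1e-9.
    """
    if not curves:
        raise ValueError("need at least one decay curve")
    ids = [c.condition_id for c in curves]
    if len(set(ids)) != len(ids):
        raise ValueError("condition_id values must be unique")

    data = {}
    for c in curves:
        y = c.intensity / c.intensity[0] if normalize else c.intensity
        data[c.condition_id] = (c.time_s, y)

    params = lmfit.Parameters()
    params.add("tau", value=10.0, min=1e-6)
    for cid in ids:
        safe = cid.replace("-", "_")
        _, y = data[cid]
        params.add(f"a1_{safe}", value=float(y[0]) * 0.8)
        if cid in single_component:
            params.add(f"a2_{safe}", value=0.0, vary=False)
            params.add(f"tau2_{safe}", value=1.0, vary=False)
        else:
            params.add(f"a2_{safe}", value=float(y[0]) * 0.4, min=0.0)
            params.add(f"tau2_{safe}", value=2.0, min=1e-6)

    def residuals(p):
        res = []
        for cid in ids:
            safe = cid.replace("-", "_")
            t, y = data[cid]
            model = p[f"a1_{safe}"].value * np.exp(-t / p["tau"].value)
            if cid not in single_component:
                model = model + p[f"a2_{safe}"].value * np.exp(
                    -t / p[f"tau2_{safe}"].value
                )
            res.append(y - model)
        return np.concatenate(res)

    out = lmfit.minimize(
        residuals, params, method="leastsq", ftol=1e-9, xtol=1e-12, max_nfev=10000
    )
    if not out.success:
        warnings.warn(f"global decay fit did not fully converge: {out.message}")

    p = out.params

    def _se(name):
        err = p[name].stderr
        return float(err) if err is not None else np.nan

    a1 = {cid: float(p[f"a1_{cid.replace('-', '_')}"].value) for cid in ids}
    a2 = {
        cid: (0.0 if cid in single_component else float(p[f"a2_{cid.replace('-', '_')}"].value))
        for cid in ids
    }
    tau2 = {
        cid: (None if cid in single_component else float(p[f"tau2_{cid.replace('-', '_')}"].value))
        for cid in ids
    }
    ses = {"tau": _se("tau")}
    for cid in ids:
        safe = cid.replace("-", "_")
        ses[f"a1_{cid}"] = _se(f"a1_{safe}")
        if cid not in single_component:
            ses[f"a2_{cid}"] = _se(f"a2_{safe}")
            ses[f"tau2_{cid}"] = _se(f"tau2_{safe}")
    return GlobalDecayFit(
        tau=float(p["tau"].value),
        se_tau=_se("tau"),
        amplitudes_1=a1,
        amplitudes_2=a2,
        tau_2=tau2,
        se=ses,
        chi_square=float(out.chisqr),
        n_obs=int(out.ndata),
        success=bool(out.success),
    )


# --------------------------------------------------------------------------
# three-Gaussian FRET-histogram decomposition


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: float
    sd: float
    mean_ci95: tuple[float, float] = (np.nan, np.nan)
    collapsed: bool = False


@dataclass
class MixtureFit:
    components: list[MixtureComponent]  # sorted by ascending mean
    chi_square: float
    n_obs: int
    method: str = "histogram-ls"

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])


def _histogram(sample, bin_width, hist_range):
    edges = np.arange(hist_range[0], hist_range[1] + bin_width / 2, bin_width)
    counts, edges = np.histogram(sample, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def fit_three_gaussians(
    sample=None,
    histogram: tuple[np.ndarray, np.ndarray] | None = None,
    bin_width: float = 0.02,
    hist_range: tuple[float, float] = (-0.1, 1.1),
    n_components: int = 3,
    method: str = "histogram-ls",
    random_state: int = 0,
) -> MixtureFit:
    """Decompose a FRET histogram into three Gaussian populations.

    Default backend bins the sample (width 0.02 over [-0.1, 1.1]) and
    least-squares fits the sum of three Gaussian curves, initialized at the
    three largest modes of a lightly smoothed histogram; 95% CIs on the
    means come from the parameter covariance.  ``method="em"`` instead fits
    a Gaussian mixture by EM on the raw sample (scikit-learn backend).
    Components with weight < 0.02 are flagged as collapsed.
    """
    if sample is not None:
        sample = np.asarray(sample, dtype=float)
        if len(sample) < 100:
            raise ValueError("need >= 100 observations for a mixture fit")
        n_obs = len(sample)
    elif histogram is not None:
        n_obs = int(np.sum(histogram[1]))
    else:
        raise ValueError("provide a sample or a histogram")

    if method == "em":
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(
            n_components=n_components, n_init=5, random_state=random_state
        ).fit(sample.reshape(-1, 1))
        order = np.argsort(gm.means_.ravel())
        comps = [
            MixtureComponent(
                weight=float(gm.weights_[i]),
                mean=float(gm.means_[i, 0]),
                sd=float(np.sqrt(gm.covariances_[i].ravel()[0])),
                collapsed=bool(gm.weights_[i] < 0.02),
            )
            for i in order
        ]
        return MixtureFit(comps, chi_square=np.nan, n_obs=n_obs, method="em")

    if histogram is not None:
        centers, counts = histogram
        centers = np.asarray(centers, float)
        counts = np.asarray(counts, float)
    else:
        centers, counts = _histogram(sample, bin_width, hist_range)

    # initialize at the three largest modes of a smoothed histogram
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smooth = np.convolve(counts, kernel / kernel.sum(), mode="same")
    is_peak = np.r_[False, (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] > smooth[2:]), False]
    peak_idx = np.where(is_peak)[0]
    peak_idx = peak_idx[np.argsort(smooth[peak_idx])[::-1]][:n_components]
    init_means = list(centers[peak_idx])
    # pad with quantile spread if fewer than three resolvable modes
    while len(init_means) < n_components:
        init_means.append(centers[np.argmax(counts)] + 0.2 * len(init_means))
    init_means = np.sort(init_means)
    p0 = []
    for m in init_means:
        h0 = max(float(counts[np.argmin(np.abs(centers - m))]), 1.0)
        p0 += [h0, m, 0.05]

    def model(x, *p):
        y = np.zeros_like(x, dtype=float)
        for i in range(n_components):
            h, mu, sd = p[3 * i : 3 * i + 3]
            y = y + h * np.exp(-0.5 * ((x - mu) / sd) ** 2)
        return y

    lower = [0.0, hist_range[0], 1e-3] * n_components
    upper = [np.inf, hist_range[1], 1.0] * n_components
    popt, pcov = optimize.curve_fit(
        model, centers, counts, p0=p0, bounds=(lower, upper), maxfev=20000
    )
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    heights = popt[0::3]
    mus = popt[1::3]
    sds = np.abs(popt[2::3])
    mu_err = perr[1::3]
    areas = heights * sds  # Gaussian area up to the common sqrt(2*pi) factor
    weights = areas / areas.sum()
    order = np.argsort(mus)
    comps = []
    for i in order:
        ci = (mus[i] - 1.96 * mu_err[i], mus[i] + 1.96 * mu_err[i])
        comps.append(
            MixtureComponent(
                weight=float(weights[i]),
                mean=float(mus[i]),
                sd=float(sds[i]),
                mean_ci95=(float(ci[0]), float(ci[1])),
                collapsed=bool(weights[i] < 0.02),
            )
        )
    resid = counts - model(centers, *popt)
    return MixtureFit(comps, chi_square=float(np.sum(resid**2)), n_obs=n_obs)


# --------------------------------------------------------------------------
# steady-state affinity


@dataclass
class BindingSeries:
    """Equilibrium SPR responses over an analyte titration (concentrations in M)."""

    concentration: np.ndarray
    response: np.ndarray
    ligand: str = ""

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be >= 0")
        if len(np.unique(self.concentration[self.concentration > 0])) < 4:
            raise ValueError("need at least 4 distinct non-zero concentrations")


@dataclass
class SsaFit:
    """1:1 steady-state affinity fit; K_D in the same units as the series."""

    kd: float
    rmax: float
    se_kd: float
    se_rmax: float
    rss: float
    non_monotone: bool = False


def fit_ssa(series: BindingSeries) -> SsaFit:
    """Nonlinear least squares for R_eq = R_max [A] / ([A] + K_D).

    Initialized at K_D = concentration nearest half-max response and
    R_max = 1.1 x max response.  A non-monotone response (beyond noise)
    raises no error but sets a flag.
    """
    conc, resp = series.concentration, series.response
    # fit in normalized units so convergence tolerances are scale-invariant
    # across molar / micromolar titrations and arbitrary response units
    c_scale = conc.max()
    r_scale = resp.max() if resp.max() > 0 else 1.0
    cn, rn = conc / c_scale, resp / r_scale
    rmax0 = 1.1 * rn.max()
    kd0 = cn[np.argmin(np.abs(rn - 0.5 * rn.max()))]
    if kd0 <= 0:
        kd0 = np.median(cn[cn > 0])

    def model(a, kd, rmax):
        return rmax * a / (a + kd)

    popt, pcov = optimize.curve_fit(
        model, cn, rn, p0=[kd0, rmax0], bounds=([0, 0], [np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, maxfev=10000,
    )
    resid_n = rn - model(cn, *popt)
    popt = popt * [c_scale, r_scale]
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None)) * [c_scale, r_scale]
    resid = resid_n * r_scale
    order = np.argsort(conc)
    diffs = np.diff(resp[order])
    # robust noise scale so a single genuine dip cannot hide in its own residual
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    tol = 3.0 * sigma + 1e-12
    non_mono = bool(np.any(diffs < -tol))
    if non_mono:
        warnings.warn("binding series is non-monotone beyond the fit noise level")
    return SsaFit(
        kd=float(popt[0]),
        rmax=float(popt[1]),
        se_kd=float(perr[0]),
        se_rmax=float(perr[1]),
        rss=float(np.sum(resid**2)),
        non_monotone=non_mono,
    )


def extract_req(time_s, response, window: tuple[float, float]) -> float:
    """Average the sensorgram response over the steady-state time window."""
    t = np.asarray(time_s, float)
    r = np.asarray(response, float)
    mask = (t >= window[0]) & (t <= window[1])
    if not mask.any():
        raise ValueError("steady-state window contains no samples")
    return float(r[mask].mean())


def overhang_trend(fits: list[tuple[int, SsaFit]]):
    """K_D versus single-stranded overhang length.

    Returns ``(table, fold_change, monotone)`` where fold change is
    K_D(longest) / K_D(shortest length) and ``monotone`` reports a strictly
    increasing trend.
    """
    import pandas as pd

    if len(fits) < 2:
        raise ValueError("need at least two overhang lengths")
    fits = sorted(fits, key=lambda lf: lf[0])
    lengths = [lf[0] for lf in fits]
    kds = [lf[1].kd for lf in fits]
    table = pd.DataFrame({"overhang_nt": lengths, "kd": kds,
                          "se_kd": [lf[1].se_kd for lf in fits]})
    fold = kds[-1] / kds[0]
    monotone = bool(np.all(np.diff(kds) > 0))
    return table, float(fold), monotone


# --------------------------------------------------------------------------
# emission spectra


@dataclass
class Spectrum:
    """Fluorescence emission spectrum (wavelength in nm, intensity a.u.)."""

    wavelength: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelength.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity must align")


def difference_spectrum(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise a - b; grids must match exactly (no interpolation)."""
    if len(a.wavelength) != len(b.wavelength) or np.any(a.wavelength != b.wavelength):
        raise ValueError("wavelength grids differ; refusing to interpolate")
    return Spectrum(a.wavelength.copy(), a.intensity - b.intensity)


def moving_average(s: Spectrum, window: int = 5) -> Spectrum:
    """Centered moving average with shrinking windows at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    n = len(s.intensity)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = s.intensity[lo:hi].mean()
    return Spectrum(s.wavelength.copy(), out)
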