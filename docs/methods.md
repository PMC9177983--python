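# Methods

This note documents the models behind `fretkinetics`, the choices that were
genuinely open, and what the synthetic-data tests do and do not demonstrate
about real microscope data.

## Signal model

A surface-immobilized molecule carries a donor/acceptor dye pair reporting a
conformational coordinate — here, the register of a transcription elongation
complex on its template.  Under donor excitation the two detection channels
are modeled as

    I_A(t) = I_tot · E(t) + bg_A + ε_A(t)
    I_D(t) = I_tot · (1 − E(t)) + bg_D + ε_D(t)

with additive Gaussian channel noise ε and E(t) the instantaneous FRET
efficiency.  The analyzer computes the proximity ratio
E = (I_A − bg_A) / ((I_A − bg_A) + (I_D − bg_D)) with **no** detection-factor
(gamma), donor-leakage or direct-excitation corrections: simulator and
analyzer deliberately share one convention, so every recovery test is
internally consistent.  On real data the proximity ratio differs from the
photophysical efficiency by those instrument factors; absolute state
positions would shift, while state counting, classification and kinetics are
unaffected.

Masked frames: any frame whose corrected total intensity falls below 10% of
the initial 10-frame median yields no meaningful ratio and is set to NaN.

## State kinetics and discretization

True dynamics are a continuous-time Markov chain over discrete FRET levels;
`simulate_state_path` samples it by Gillespie jumps (exponential holding
times at each state's total exit rate) and records the occupying state at
each frame midpoint (frame interval 0.2 s, 600-frame/120 s movies by
default).  Sub-frame dwells can therefore vanish, exactly as in real sampled
acquisitions; the dwell-distribution test uses a frame interval far below
the mean dwell so this bias does not contaminate the goodness-of-fit check.

Photobleaching is an irreversible single exponential-time event per dye
(default acceptor mean survival 11.3 s, matching a typical Cy5 under the
imaging conditions emulated); blinking is not modeled (experimentally
suppressed with Trolox).  Two consequences worth noting:

* **Donor bleach** collapses the total intensity; the detector below finds
  it and truncates the analysis.
* **Acceptor bleach** conserves the total (the donor de-quenches), so a
  total-intensity detector cannot see it; the trajectory continues at E ≈ 0.
  Simulations that exercise the trajectory-analysis layers therefore drive
  the observation horizon with donor bleaching; acceptor bleaching is
  exercised where its ground-truth metadata is the point (survival-curve
  checks).  On real data an acceptor-channel-specific detector or manual
  curation would be used instead.

The photobleach detector takes the median corrected total over the first 10
frames as baseline and reports the first run of ≥ 5 consecutive frames below
50% of baseline (a below-threshold run reaching the trace end also counts).
Both thresholds are exposed as arguments.

## Idealization

Each trajectory is fit by a K-state Gaussian-emission hidden Markov model,
maximized by EM.  Implementation choices:

* Scaled linear-space forward–backward with per-frame emission
  renormalization (shifts accumulate exactly into the log-likelihood);
  log-space forward/backward recursions are kept as an exact cross-check and
  are verified against brute-force path enumeration in the tests.
* Restarts (default 10): restart 0 starts at the (i+½)/K quantiles of the
  usable frames; later restarts perturb those means with Gaussian noise of
  one sample standard deviation, clipped to the data range.  The wide
  perturbation matters: rarely-visited states are otherwise missed.
* Convergence: log-likelihood gain < 1e-6 or 500 iterations.
* Emission sd floor 0.01 FRET.  Shot noise alone exceeds this on real
  traces, so any state fit with a smaller sd is a spurious split of noise;
  the floor removes a family of degenerate high-likelihood optima.
* Masked frames stay in the chain but contribute no emission term.
* Model selection: BIC = −2 logL + p ln T with p = K² + 2K − 1, K = 1..k_max
  (default 6), ties to smaller K.
* Viterbi ties break toward the lower state index.  States whose fitted
  means lie within 0.05 with overlapping ±1 sd intervals are merged to one
  level before segments are built, since classification needs distinct
  levels.

This ML-HMM + BIC stack fills the role that variational-Bayes idealizers
play in many smFRET pipelines; it is fully specified and testable, at the
cost of not marginalizing over parameters.

## Classification, TDPs

Regime bounds default to low [0, 0.4), mid [0.4, 0.7), high [0.7, 1].  The
field's verbal convention ("0.4–0.7", "0.7–1") overlaps at the boundaries;
the half-open choice here assigns 0.7 to high and 0.4 to mid, and is
config-exposed.  A trajectory is static if it holds exactly one state;
otherwise it is labelled by the set of regimes its fitted state means visit,
and any trajectory touching both high and low (with or without mid) counts
as high-low — the only reading under which the seven classes are mutually
exclusive and exhaustive.  Regime membership uses fitted state means, not
per-frame values.

TDPs are product-Gaussian kernel densities of (FRET before, FRET after)
over all adjacent-segment transitions, pooled across molecules per
condition, on a 100×100 grid over [0,1]², normalized to integrate to 1;
"auto" bandwidth is Silverman's d=2 rule per axis (σ·n^(−1/6), floored at
1e-3).  The asymmetry score is (mass with after < before − mass with
after > before) / total off-diagonal mass: +1 for a purely FRET-decreasing
(irreversible) cascade, 0 for mirror-symmetric (reversible) exchange.

## Dwell-time kinetics

Dwells are maximal runs of consecutive in-window segments.  The first
observed dwell of a molecule started before acquisition (left-censored) and
is excluded from fitting by default — the standard unbiased choice, and
switchable; dwells truncated by the horizon are right-censored and enter
the likelihood through survival terms.

* Exponential: closed-form censored MLE, τ̂ = Σ(all durations)/n_events,
  SE = τ̂/√n_events.  Verified against a numerical optimizer to 1e-6.
* Gamma: Nelder–Mead in log-parameters on the censored log-likelihood
  (scipy's regularized upper incomplete gamma supplies survival terms),
  method-of-moments start, SEs from a finite-difference observed-information
  matrix (verified against the analytic information to 8 digits).  The
  "characteristic lifetime" is reported as the scale parameter θ — the
  per-step lifetime of the k sequential sub-steps — with shape and mean also
  reported, since the verbal phrase is ambiguous among θ, kθ and kθ/k.
  The shape is capped at 100 with a warning on degenerate near-constant
  samples.
* Model comparison reports AIC and BIC for both fits; preference is lower
  BIC, with |ΔBIC| < 2 flagged indeterminate.

A note on coverage: at n = 500 the Wald interval θ̂ ± 2·SE(θ̂) for the gamma
scale has true coverage within a few tenths of a percent of its nominal
95.4% (the θ̂ sampling distribution is mildly skewed); the recovery tests
therefore sit close to their thresholds by construction rather than through
any implementation defect.

## Ensemble fits

* **Global decay** (Levenberg–Marquardt, lmfit): all curves share τ; each
  curve contributes A_1,i, and non-constrained curves add (A_2,i, τ_2,i).
  Curves are normalized to their first point before fitting — the
  normalization anchor of published "normalized intensity" plots is
  unstated, and first-frame normalization is the simplest reproducible
  choice (it rescales amplitudes by y(0), a ~1% effect at the noise level
  used).  Convergence tolerance 1e-9 on chi-square.
* **Three-Gaussian histogram fit**: least squares of a sum of three
  Gaussians on counts binned at width 0.02 over [−0.1, 1.1], initialized at
  the three largest modes of a 5-point-smoothed histogram; weights are
  normalized component areas; 95% CIs on means from the parameter
  covariance; components with weight < 0.02 are flagged collapsed.  An EM
  backend (scikit-learn GaussianMixture on the raw sample) is provided and
  agrees with the binned fit on well-separated fixtures.  The default input
  is the set of state occurrences from idealized trajectories; raw frames
  can be supplied instead.
* **Steady-state affinity**: R_eq = R_max[A]/([A]+K_D) by trust-region
  least squares in internally normalized units (scale-invariant down to
  nanomolar K_D), K_D initialized at the concentration nearest half-max
  response.  A response dip exceeding three robust (MAD) noise scales sets
  a non-monotone flag without aborting the fit.  R_eq extraction from a
  full sensorgram is a windowed mean with a config-specified steady-state
  window.
* **Spectra**: pointwise difference on identical wavelength grids (no
  interpolation) and a centered moving average (default 5 points) with
  shrinking windows at the edges.

## Synthetic data: what passing tests show

The generator reproduces the statistical structure the analysis relies on —
Markov switching with exponential dwells, anti-correlated channels,
single-step bleaching, Gaussian noise, multi-exponential ensemble decays,
1:1 isotherms on the eight-point titration [0, 10, 20, 40, 80, 160, 320,
640] nM, Gaussian-mixture FRET populations.  It does not model camera
EM-gain statistics, triplet blinking, spectral crosstalk, baseline drift or
stage drift.  Passing recovery tests therefore demonstrate correctness of
the estimators under the stated noise model, not robustness to every
instrument artifact.

Problem sizes in the test-suite and acceptance runs (molecule counts,
replicate counts of 20–200, trace lengths of 300–600 frames) are chosen to
give stable pass/fail behavior at the stated thresholds while keeping a
full run in the minutes range on one core; estimator properties quoted
above were additionally spot-checked at larger sizes during development.

## Known limitations

* No missed-event (dead-time) correction for sub-frame dwells; minimum
  dwell is one frame.
* No hierarchical/global HMM across molecules; each trajectory is fit
  independently.
* Distance inference from measured FRET is out of scope (only the forward
  Förster prediction E = 1/(1+(r/r₀)⁶) is provided).
* SPR kinetic (association/dissociation-phase) modeling is out of scope;
  only steady-state responses are fit.
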