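# fretkinetics

Kinetic analysis of single-molecule FRET trajectories, built for studies of
transcription-complex dynamics — for example, how the bacterial
transcription-repair coupling factor Mfd remodels a stalled RNA polymerase
elongation complex (EC) through a long-lived, catalytically poised
intermediate before transcript loss.

The package implements the full trajectory workflow used in such studies:

1. **Trajectories** — donor/acceptor intensity traces are background-corrected
   and converted to proximity-ratio FRET, E = I_A / (I_A + I_D), with a
   photobleach detector setting the analysis horizon of each molecule.
2. **Heat maps** — ensemble FRET-vs-time densities.
3. **Idealization** — each trajectory is reduced to a piecewise-constant
   state path with a maximum-likelihood Gaussian-emission hidden Markov
   model (EM with restarts), BIC model selection over the state count, and
   Viterbi decoding.
4. **Classification and TDPs** — idealized trajectories are sorted into
   static/dynamic classes over the low (0–0.4), mid (0.4–0.7) and high
   (0.7–1) FRET regimes, and transition density plots (kernel densities of
   FRET-before vs FRET-after) expose irreversible transitions as
   off-diagonal asymmetry.
5. **Kinetics** — residence times in a FRET window are fit by censored
   maximum likelihood to a single exponential (one rate-limiting step,
   p(t) ∝ e^(−t/τ)) or a gamma distribution (several sequential steps,
   p(t) ∝ t^(k−1) e^(−t/θ)).

Ensemble-level fits accompany the trajectory workflow:

* **Global two-exponential decay** for direct-excitation transcript-lifetime
  experiments, y_i(t) = A_1,i e^(−t/τ) + A_2,i e^(−t/τ_2,i), with the
  photobleaching lifetime τ shared across conditions and single-component
  conditions constrained to A_2 = 0;
* **Three-Gaussian decomposition** of FRET-state histograms;
* **1:1 steady-state affinity** for SPR titrations,
  R_eq = R_max·[A]/([A]+K_D), plus the K_D-vs-overhang-length trend;
* **2-aminopurine spectra**: difference spectra and five-point smoothing.

A synthetic-data module generates every input with known ground truth —
continuous-time Markov state paths sampled at the 200 ms frame interval,
anti-correlated two-channel intensities with single-step photobleaching,
decay curves, dwell samples, binding isotherms and mixture samples — so the
entire pipeline is testable without microscope data.

## Worked example

```python
import numpy as np
import fretkinetics as fk

# a three-state EC scheme: high = pre-translocated (inactive),
# mid = catalytically poised, low = extended/terminated
scheme = fk.KineticScheme(
    states=[fk.StateSpec("low", 0.1, 0.03),
            fk.StateSpec("mid", 0.6, 0.03),
            fk.StateSpec("high", 0.9, 0.03)],
    rates=np.array([[0.0, 0.2, 0.0],
                    [0.1, 0.0, 0.2],
                    [0.0, 0.25, 0.0]]),
)
phot = fk.PhotophysicsModel(total_intensity=1000, donor_bleach_rate=1/11.3,
                            acceptor_bleach_rate=0.0, noise_sd=15)
cfg = fk.SimConfig(frame_interval=0.2, n_frames=600)

rng = np.random.default_rng(5)
trace, true_path = fk.simulate_molecule(scheme, phot, cfg, rng)
traj = fk.compute_fret(trace)                      # FRET + bleach horizon
model, k = fk.select_states(traj, k_max=4, seed=rng)
ideal = fk.viterbi_path(traj, model)               # idealized segments
print(k, np.round(model.means, 3))
print(fk.classify_trajectory(ideal, fk.RegimeBounds()))

dwells = fk.extract_dwells(ideal, window=(0.35, 0.7))
```

Running this prints, for the seed shown:

```
3 [0.108 0.595 0.895]
high-low
```

that is, BIC selects three states whose fitted FRET means recover the
simulated levels (0.1/0.6/0.9) to within ~0.01, and the molecule visited
both the high and low regimes before photobleaching.

A YAML-driven command line wraps the same functions
(`fretkin simulate|analyze|fret|idealize|classify|tdp|dwell|decayfit|mixfit|sprfit|spectra|report`);
`fretkin analyze` writes per-condition segment tables, class percentages,
TDP matrices, dwell tables and fit reports plus a run manifest, all
reproducible from one master seed.

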