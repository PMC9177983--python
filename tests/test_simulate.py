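"""Synthetic-data generator: analytic oracles and determinism."""

import numpy as np
import pytest
from scipy import stats

import fretkinetics as fk


def segment_dwells(path, frame_interval):
    """Interior dwell lengths (s) per run of constant state, ends excluded."""
    change = np.flatnonzero(np.diff(path)) + 1
    if len(change) < 2:
        return np.array([])
    bounds = np.r_[change]
    return np.diff(bounds) * frame_interval


class TestStatePath:
    def test_one_state_scheme_is_constant(self):
        scheme = fk.KineticScheme(states=[fk.StateSpec("s", 0.5)], rates=np.zeros((1, 1)))
        path = fk.simulate_state_path(scheme, fk.SimConfig(n_frames=100), rng=0)
        assert np.all(path == 0)

    def test_absorbing_state_never_left(self):
        scheme = fk.KineticScheme(
            states=[fk.StateSpec("a", 0.2), fk.StateSpec("b", 0.8)],
            rates=np.array([[0.0, 0.5], [0.0, 0.0]]),
        )
        path = fk.simulate_state_path(scheme, fk.SimConfig(n_frames=500), rng=1)
        entered = np.flatnonzero(path == 1)
        assert len(entered) > 0
        assert np.all(path[entered[0] :] == 1)

    def test_mean_dwell_matches_rate(self, two_state_scheme):
        # 10^4 s of simulation; analytic mean dwell is 1/k = 5 s per state
        cfg = fk.SimConfig(frame_interval=0.2, n_frames=50_000)
        path = fk.simulate_state_path(two_state_scheme, cfg, rng=2)
        dwells = segment_dwells(path, cfg.frame_interval)
        assert len(dwells) > 300
        se = dwells.std() / np.sqrt(len(dwells))
        # discretization truncates sub-frame dwells; allow 3 SE + half frame
        assert abs(dwells.mean() - 5.0) < 3 * se + cfg.frame_interval

    def test_occupancy_matches_stationary_distribution(self):
        scheme = fk.KineticScheme(
            states=[fk.StateSpec("a", 0.3), fk.StateSpec("b", 0.8)],
            rates=np.array([[0.0, 0.3], [0.1, 0.0]]),
        )
        cfg = fk.SimConfig(frame_interval=0.2, n_frames=100_000)
        path = fk.simulate_state_path(scheme, cfg, rng=3)
        # stationary P(a) = k21 / (k12 + k21)
        expected = 0.1 / 0.4
        occ = np.mean(path == 0)
        n_dwell = np.sum(np.diff(path) != 0) + 1  # effective independent samples
        se = np.sqrt(expected * (1 - expected) / n_dwell)
        assert abs(occ - expected) < 3 * se

    def test_dwell_distribution_is_exponential(self, two_state_scheme):
        """Chi-square GOF of interior dwells against Exp(total exit rate).

        The frame interval is kept far below the mean dwell so that
        discretization (lost sub-frame dwells) does not distort the test.
        """
        cfg = fk.SimConfig(frame_interval=0.01, n_frames=2_500_000)
        path = fk.simulate_state_path(two_state_scheme, cfg, rng=4)
        dwells = segment_dwells(path, cfg.frame_interval)
        tau = 5.0
        edges = np.r_[np.arange(0, 20, 2.0), np.inf]
        observed, _ = np.histogram(dwells, bins=edges)
        cdf = 1 - np.exp(-edges / tau)
        expected = np.diff(cdf) * len(dwells)
        keep = expected > 5
        chi2 = np.sum((observed[keep] - expected[keep]) ** 2 / expected[keep])
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            fk.KineticScheme(
                states=[fk.StateSpec("a", 0.2), fk.StateSpec("b", 0.8)],
                rates=np.array([[0.0, -0.1], [0.1, 0.0]]),
            )

    def test_fixed_seed_is_bit_identical(self, two_state_scheme):
        cfg = fk.SimConfig(n_frames=1000, seed=9)
        p1 = fk.simulate_state_path(two_state_scheme, cfg)
        p2 = fk.simulate_state_path(two_state_scheme, cfg)
        assert np.array_equal(p1, p2)


class TestIntensityTrace:
    def test_noiseless_ratio_closed_form(self):
        scheme = fk.KineticScheme(states=[fk.StateSpec("s", 0.9)], rates=np.zeros((1, 1)))
        phot = fk.PhotophysicsModel(
            total_intensity=1000, donor_bleach_rate=0, acceptor_bleach_rate=0, noise_sd=0
        )
        cfg = fk.SimConfig(n_frames=50)
        path = np.zeros(50, dtype=int)
        trace = fk.simulate_intensity_trace(path, scheme, phot, cfg, rng=0)
        assert np.allclose(trace.acceptor / trace.donor, 9.0)
        assert np.allclose(trace.donor + trace.acceptor, 1000.0)

    def test_acceptor_bleach_zeroes_fret(self):
        scheme = fk.KineticScheme(states=[fk.StateSpec("s", 0.8)], rates=np.zeros((1, 1)))
        phot = fk.PhotophysicsModel(
            total_intensity=1000, acceptor_bleach_rate=0.5, noise_sd=0
        )
        cfg = fk.SimConfig(n_frames=200)
        trace = fk.simulate_intensity_trace(
            np.zeros(200, dtype=int), scheme, phot, cfg, rng=3
        )
        b = trace.metadata["acceptor_bleach_frame"]
        assert b is not None
        post = trace.acceptor[b:] / (trace.acceptor[b:] + trace.donor[b:])
        assert np.allclose(post, 0.0)
        assert np.allclose(trace.donor[b:], 1000.0)

    def test_donor_bleach_darkens_both_channels(self):
        scheme = fk.KineticScheme(states=[fk.StateSpec("s", 0.8)], rates=np.zeros((1, 1)))
        phot = fk.PhotophysicsModel(
            total_intensity=1000, donor_bleach_rate=0.5, background_donor=30,
            background_acceptor=20, noise_sd=0,
        )
        trace = fk.simulate_intensity_trace(
            np.zeros(200, dtype=int), scheme, phot, fk.SimConfig(n_frames=200), rng=4
        )
        b = trace.metadata["donor_bleach_frame"]
        assert b is not None
        assert np.allclose(trace.donor[b:], 30.0)
        assert np.allclose(trace.acceptor[b:], 20.0)

    def test_acceptor_survival_matches_exponential(self):
        """Ensemble fraction of unbleached acceptors follows exp(-t/tau)."""
        scheme = fk.KineticScheme(states=[fk.StateSpec("s", 0.5)], rates=np.zeros((1, 1)))
        tau = 11.3
        phot = fk.PhotophysicsModel(total_intensity=1000, acceptor_bleach_rate=1 / tau)
        cfg = fk.SimConfig(n_frames=600)
        rng = np.random.default_rng(5)
        n = 400
        frames = []
        for _ in range(n):
            tr = fk.simulate_intensity_trace(np.zeros(600, dtype=int), scheme, phot, cfg, rng)
            frames.append(tr.metadata["acceptor_bleach_frame"])
        for t_check in (5.0, 11.3, 25.0):
            f_check = t_check / cfg.frame_interval
            surviving = sum(1 for b in frames if b is None or b >= f_check)
            p = np.exp(-t_check / tau)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(surviving / n - p) < 3.5 * se


class TestEnsembleDecay:
    def test_single_exponential_closed_form(self):
        t, y = fk.simulate_ensemble_decay([1.0], [10.0], np.array([0.0, 10.0]), 0.0)
        assert y[0] == pytest.approx(1.0)
        assert y[1] == pytest.approx(np.exp(-1.0))

    def test_printed_two_component_initial_value(self):
        # amplitudes from the optimized two-condition decay fit sum to 1.01
        t, y = fk.simulate_ensemble_decay(
            [0.49, 0.52], [11.3, 4.6], np.array([0.0]), 0.0
        )
        assert y[0] == pytest.approx(1.01)

    def test_monotone_nonincreasing_without_noise(self):
        t = np.linspace(0, 60, 301)
        _, y = fk.simulate_ensemble_decay([0.5, 0.5], [11.3, 4.6], t, 0.0)
        assert np.all(np.diff(y) <= 0)

    def test_negative_lifetime_rejected(self):
        with pytest.raises(ValueError):
            fk.simulate_ensemble_decay([1.0], [-5.0], np.array([0.0, 1.0]), 0.0)


class TestDwellSample:
    def test_exponential_sample_mean(self):
        dwells = fk.simulate_dwells(("exponential", 5.0), 100_000, None, rng=6)
        d = np.array([x.duration_s for x in dwells])
        se = 5.0 / np.sqrt(len(d))
        assert abs(d.mean() - 5.0) < 3 * se

    def test_gamma_shape_one_is_exponential(self):
        n = 10_000
        e = [x.duration_s for x in fk.simulate_dwells(("exponential", 2.0), n, None, rng=7)]
        g = [x.duration_s for x in fk.simulate_dwells(("gamma", 1.0, 2.0), n, None, rng=8)]
        _, p = stats.ks_2samp(e, g)
        assert p > 0.01

    def test_forced_censoring(self):
        dwells = fk.simulate_dwells(("exponential", 100.0), 50, censor_at=1.0, rng=9)
        assert all(d.right_censored for d in dwells)
        assert all(d.duration_s == 1.0 for d in dwells)

    def test_zero_n_gives_empty(self):
        assert fk.simulate_dwells(("exponential", 5.0), 0, None, rng=0) == []


class TestBindingSeries:
    def test_half_saturation_and_zero(self):
        s = fk.simulate_binding_series(
            kd=170e-9, rmax=100.0,
            concentrations=[0.0, 42.5e-9, 85e-9, 170e-9, 340e-9, 680e-9],
            noise_frac=0.0,
        )
        assert s.response[0] == pytest.approx(0.0)  # zero analyte, zero response
        assert s.response[3] == pytest.approx(50.0)  # [A] = K_D -> R_max / 2

    def test_default_grid_is_the_eight_point_titration(self):
        s = fk.simulate_binding_series(kd=170e-9, rmax=100.0)
        np.testing.assert_allclose(
            s.concentration * 1e9, [0, 10, 20, 40, 80, 160, 320, 640]
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            fk.simulate_binding_series(170e-9, 100.0, concentrations=[-1e-9, 1e-9])


class TestFretSample:
    def test_single_component_moments(self):
        x = fk.simulate_fret_sample([(1.0, 0.5, 0.01)], 10_000, rng=10)
        se = 0.01 / np.sqrt(len(x))
        assert abs(x.mean() - 0.5) < 3 * se

    def test_mixture_mean(self):
        x = fk.simulate_fret_sample([(0.5, 0.0, 0.01), (0.5, 1.0, 0.01)], 10_000, rng=11)
        se = np.sqrt(0.25 + 0.01**2) / np.sqrt(len(x))
        assert abs(x.mean() - 0.5) < 3 * se

    def test_empty_and_invalid(self):
        assert len(fk.simulate_fret_sample([(1.0, 0.5, 0.1)], 0, rng=0)) == 0
        with pytest.raises(ValueError):
            fk.simulate_fret_sample([(-0.5, 0.5, 0.1), (1.5, 0.5, 0.1)], 10, rng=0)
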