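"""HMM idealization: exhaustive-enumeration oracles, EM recovery, selection."""

import itertools

import numpy as np
import pytest

import fretkinetics as fk
from fretkinetics.idealize import (
    InsufficientDataError,
    backward_loglik,
    forward_loglik,
    posterior_probs,
)


def brute_force_loglik(obs, means, sds, transmat, initial_probs):
    """Sum the joint density over every one of the K^T state paths."""
    k, t_len = len(means), len(obs)
    total = 0.0
    for path in itertools.product(range(k), repeat=t_len):
        p = initial_probs[path[0]]
        for a, b in zip(path, path[1:]):
            p *= transmat[a, b]
        for t, s in enumerate(path):
            p *= np.exp(-0.5 * ((obs[t] - means[s]) / sds[s]) ** 2) / (
                sds[s] * np.sqrt(2 * np.pi)
            )
        total += p
    return np.log(total)


def brute_force_viterbi(obs, means, sds, transmat, initial_probs):
    """Argmax path by exhaustive enumeration; ties -> lexicographically first
    (lowest state indices), matching the dynamic program's convention."""
    k, t_len = len(means), len(obs)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(k), repeat=t_len):
        lp = np.log(initial_probs[path[0]])
        for a, b in zip(path, path[1:]):
            lp += np.log(transmat[a, b])
        for t, s in enumerate(path):
            lp += -0.5 * ((obs[t] - means[s]) / sds[s]) ** 2 - np.log(
                sds[s] * np.sqrt(2 * np.pi)
            )
        if lp > best_lp + 1e-12:
            best, best_lp = path, lp
    return np.array(best)


def random_params(rng, k=2):
    means = np.sort(rng.uniform(0, 1, k))
    sds = rng.uniform(0.05, 0.3, k)
    transmat = rng.dirichlet(np.ones(k), size=k)
    initial = rng.dirichlet(np.ones(k))
    return means, sds, transmat, initial


class TestForwardBackwardOracles:
    def test_forward_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            means, sds, transmat, initial = random_params(rng)
            obs = rng.uniform(0, 1, 6)
            ll, _ = forward_loglik(obs, means, sds, transmat, initial)
            expected = brute_force_loglik(obs, means, sds, transmat, initial)
            assert ll == pytest.approx(expected, rel=1e-8)

    def test_forward_and_backward_agree(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            means, sds, transmat, initial = random_params(rng, k=3)
            obs = rng.uniform(0, 1, 40)
            llf, _ = forward_loglik(obs, means, sds, transmat, initial)
            llb, _ = backward_loglik(obs, means, sds, transmat, initial)
            assert llf == pytest.approx(llb, rel=1e-8)

    def test_posterior_rows_normalize(self):
        rng = np.random.default_rng(9)
        means, sds, transmat, initial = random_params(rng, k=3)
        obs = rng.uniform(0, 1, 80)
        model = fk.HmmModel(means, sds, transmat, initial)
        gamma = posterior_probs(obs, model)
        assert np.abs(gamma.sum(axis=1) - 1.0).max() < 1e-10

    def test_likelihood_agrees_with_hmmlearn(self):
        """Independent cross-check of the forward likelihood at fixed params."""
        hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(10)
        means, sds, transmat, initial = random_params(rng, k=3)
        obs = rng.uniform(0, 1, 200)
        ref = hmm.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        ref.startprob_ = initial
        ref.transmat_ = transmat
        ref.means_ = means.reshape(-1, 1)
        ref.covars_ = (sds**2).reshape(-1, 1)
        expected = ref.score(obs.reshape(-1, 1))
        ll, _ = forward_loglik(obs, means, sds, transmat, initial)
        assert ll == pytest.approx(expected, rel=1e-8)


class TestViterbi:
    def test_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            means, sds, transmat, initial = random_params(rng)
            obs = rng.uniform(0, 1, 6)
            traj = fk.FretTrajectory("m", 0.2, obs, valid_until=6)
            model = fk.HmmModel(means, sds, transmat, initial)
            ideal = fk.viterbi_path(traj, model)
            expected = brute_force_viterbi(obs, means, sds, transmat, initial)
            got = ideal.metadata["state_path"]
            assert np.array_equal(got, expected)

    def test_noiseless_single_level_gives_one_segment(self):
        obs = np.full(50, 0.7)
        traj = fk.FretTrajectory("m", 0.2, obs, valid_until=50)
        model = fk.HmmModel(
            means=np.array([0.2, 0.7]),
            sds=np.array([0.05, 0.05]),
            transition_matrix=np.array([[0.9, 0.1], [0.1, 0.9]]),
            initial_probs=np.array([0.5, 0.5]),
        )
        ideal = fk.viterbi_path(traj, model)
        assert len(ideal.segments) == 1
        assert ideal.segments[0].level == pytest.approx(0.7)

    def test_segments_tile_without_gaps(self, three_state_scheme, rng):
        phot = fk.PhotophysicsModel(total_intensity=1000, acceptor_bleach_rate=0.0, noise_sd=15)
        cfg = fk.SimConfig(n_frames=400)
        trace, _ = fk.simulate_molecule(three_state_scheme, phot, cfg, rng)
        traj = fk.compute_fret(trace)
        model = fk.fit_hmm(traj, 3, seed=rng, n_restarts=4)
        ideal = fk.viterbi_path(traj, model)
        assert ideal.segments[0].start_frame == 0
        assert ideal.n_frames == traj.valid_until
        for a, b in zip(ideal.segments, ideal.segments[1:]):
            assert a.end_frame == b.start_frame
            assert a.level != b.level

    def test_frame_agreement_with_simulated_truth(self, three_state_scheme):
        """Decoded path matches simulator ground truth nearly everywhere."""
        rng = np.random.default_rng(21)
        scheme = three_state_scheme
        # sd 0.02, mean dwell ~25 frames at 0.2 s/frame
        scheme = fk.KineticScheme(
            states=[fk.StateSpec(s.label, s.fret_level, 0.02) for s in scheme.states],
            rates=scheme.rates,
        )
        phot = fk.PhotophysicsModel(total_intensity=1000, acceptor_bleach_rate=0.0, noise_sd=5)
        cfg = fk.SimConfig(n_frames=500)
        agree = []
        for _ in range(5):
            trace, path = fk.simulate_molecule(scheme, phot, cfg, rng)
            traj = fk.compute_fret(trace)
            model = fk.fit_hmm(traj, 3, seed=rng, n_restarts=4)
            ideal = fk.viterbi_path(traj, model)
            decoded = ideal.frame_levels()
            levels = scheme.fret_levels
            nearest = levels[np.argmin(np.abs(decoded[:, None] - levels[None, :]), axis=1)]
            agree.append(np.mean(nearest == levels[path[: traj.valid_until]]))
        assert np.mean(agree) >= 0.98


class TestFitHmm:
    def test_constant_trace_single_state_closed_form(self, rng):
        obs = rng.normal(0.5, 0.05, 200)
        traj = fk.FretTrajectory("m", 0.2, obs, valid_until=200)
        model = fk.fit_hmm(traj, 1, seed=0, n_restarts=2)
        assert model.means[0] == pytest.approx(obs.mean(), abs=1e-8)
        assert model.sds[0] == pytest.approx(obs.std(), abs=1e-6)

    def test_square_wave_two_state_recovery(self):
        # noiseless 25-frame square wave between 0.2 and 0.8
        obs = np.tile(np.r_[np.full(25, 0.2), np.full(25, 0.8)], 4)
        traj = fk.FretTrajectory("m", 0.2, obs, valid_until=len(obs))
        model = fk.fit_hmm(traj, 2, seed=0, n_restarts=4)
        assert model.means == pytest.approx([0.2, 0.8], abs=1e-3)
        # 7 switches in 199 in-state transitions -> off-diagonal ~ 7/2 per state
        ideal = fk.viterbi_path(traj, model)
        assert len(ideal.segments) == 8

    def test_too_short_trajectory_raises(self):
        traj = fk.FretTrajectory("m", 0.2, np.full(8, 0.5), valid_until=8)
        with pytest.raises(InsufficientDataError):
            fk.fit_hmm(traj, 2, seed=0)

    def test_masked_frames_excluded_from_likelihood(self):
        obs = np.full(60, 0.4)
        obs[10:20] = np.nan
        traj = fk.FretTrajectory("m", 0.2, obs, valid_until=60)
        model = fk.fit_hmm(traj, 1, seed=0, n_restarts=1)
        assert model.means[0] == pytest.approx(0.4, abs=1e-9)
        assert model.n_obs == 50

    def test_loglik_nondecreasing_in_k(self, three_state_scheme, rng):
        phot = fk.PhotophysicsModel(total_intensity=1000, acceptor_bleach_rate=0.0, noise_sd=10)
        cfg = fk.SimConfig(n_frames=300)
        trace, _ = fk.simulate_molecule(three_state_scheme, phot, cfg, rng)
        traj = fk.compute_fret(trace)
        lls = [
            fk.fit_hmm(traj, k, seed=1, n_restarts=6).log_likelihood for k in (1, 2, 3, 4)
        ]
        for a, b in zip(lls, lls[1:]):
            assert b >= a - 1e-6


class TestSelectStates:
    def test_kmax_one_is_forced(self, rng):
        obs = rng.normal(0.5, 0.05, 100)
        traj = fk.FretTrajectory("m", 0.2, obs, valid_until=100)
        _, k = fk.select_states(traj, k_max=1, seed=0)
        assert k == 1

    def test_constant_noisy_trace_selects_one_state(self):
        hits = 0
        n_rep = 20
        for i in range(n_rep):
            rng = np.random.default_rng(100 + i)
            obs = rng.normal(0.5, 0.05, 200)
            traj = fk.FretTrajectory("m", 0.2, obs, valid_until=200)
            _, k = fk.select_states(traj, k_max=3, seed=rng, n_restarts=3, max_iter=100)
            hits += k == 1
        assert hits / n_rep >= 0.95

    def test_three_level_simulation_selects_three(self):
        levels = [0.9, 0.6, 0.1]
        hits = 0
        n_rep = 20
        for i in range(n_rep):
            rng = np.random.default_rng(200 + i)
            # deterministic 20-frame dwells cycling through the three levels
            seq = np.concatenate([np.full(20, lv) for lv in levels * 5])
            obs = seq + rng.normal(0, 0.03, len(seq))
            traj = fk.FretTrajectory("m", 0.2, obs, valid_until=len(obs))
            _, k = fk.select_states(traj, k_max=4, seed=rng, n_restarts=4, max_iter=150)
            hits += k == 3
        assert hits / n_rep >= 0.9
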