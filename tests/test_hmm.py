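import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import norm

from actisleep.hmm import (
    FitConfig,
    HMMParams,
    MISSING,
    SLEEP,
    WAKE,
    baum_welch,
    emission_sleep,
    emission_wake,
    fit_individual,
    forward_backward,
    log_transform,
    split_segments,
    viterbi,
)
from actisleep.io import EpochSeries
from actisleep.simulate import GeneratorConfig, generate_cohort, simulate_observations

from conftest import enumerate_paths, random_obs, random_params


class TestLogTransform:
    def test_values_and_missing(self):
        out = log_transform([0, 99, np.nan])
        assert out[0] == 0.0
        assert out[1] == pytest.approx(np.log(100), abs=1e-12)
        assert np.isnan(out[2])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform([-1])


class TestEmissions:
    def test_pure_point_mass(self):
        assert emission_sleep(0.0, 1.0, 0.3, 0.4) == pytest.approx(1.0)

    def test_half_normal_at_zero(self):
        # alpha=0, mu=0, sigma=1: density 2*phi(0)
        assert emission_sleep(0.0, 0.0, 0.0, 1.0) == pytest.approx(0.7978845608, abs=1e-9)

    def test_wake_gaussian(self):
        assert emission_wake(4.5, 4.5, 1.0) == pytest.approx(1 / np.sqrt(2 * np.pi))
        assert emission_wake(5.5, 4.5, 1.0) == pytest.approx(norm.pdf(1.0))
        assert emission_wake(4.5, 4.5, 2.0) == pytest.approx(0.5 / np.sqrt(2 * np.pi))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            emission_sleep(1.0, 0.5, 0.3, 0.0)
        with pytest.raises(ValueError):
            emission_wake(1.0, 2.0, -1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_plus_density_normalizes(self, seed):
        # alpha + integral of the truncated-normal part over [0, inf) = 1
        rng = np.random.default_rng(seed)
        alpha = rng.uniform(0, 1)
        mu, sigma = rng.uniform(-1, 2), rng.uniform(0.1, 2)
        dens, _ = integrate.quad(
            lambda k: emission_sleep(k, alpha, mu, sigma), 1e-12, np.inf
        )
        assert alpha + dens == pytest.approx(1.0, abs=1e-8)


class TestForwardBackward:
    def test_single_step_bayes(self):
        rng = np.random.default_rng(0)
        params = random_params(rng)
        o = np.array([1.3])
        _, gamma, xi = forward_backward(o, params)
        b = [
            (1 - params.alpha_zero)
            * norm.pdf(1.3, params.mu_sleep, params.sigma_sleep)
            / norm.sf(-params.mu_sleep / params.sigma_sleep),
            norm.pdf(1.3, params.mu_wake, params.sigma_wake),
        ]
        expect = np.array([0.5 * b[0], 0.5 * b[1]])
        expect /= expect.sum()
        np.testing.assert_allclose(gamma[0], expect, atol=1e-12)
        assert xi.shape == (0, 2, 2)

    @pytest.mark.parametrize("T", [2, 3, 5, 8, 10])
    def test_matches_path_enumeration(self, T):
        rng = np.random.default_rng(T)
        for _ in range(5):
            params = random_params(rng)
            obs = random_obs(rng, T)
            ll, gamma, _ = forward_backward(obs, params)
            ll_ref, gamma_ref, _, _ = enumerate_paths(obs, params)
            assert ll == pytest.approx(ll_ref, abs=1e-10)
            np.testing.assert_allclose(gamma, gamma_ref, atol=1e-10)

    def test_gamma_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        params = random_params(rng)
        obs = random_obs(rng, 200)
        _, gamma, xi = forward_backward(obs, params)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-12)

    def test_absorbing_chain(self):
        params = HMMParams(
            a=np.eye(2), alpha_zero=0.2, mu_sleep=0.3, sigma_sleep=0.5,
            mu_wake=3.0, sigma_wake=1.0, pi=np.array([1.0, 0.0]),
        )
        obs = np.array([4.0, 4.2, 3.9])  # wake-looking data
        _, gamma, _ = forward_backward(obs, params)
        np.testing.assert_allclose(gamma[:, SLEEP], 1.0, atol=1e-12)

    def test_missing_marginalized(self):
        rng = np.random.default_rng(9)
        params = random_params(rng)
        obs = random_obs(rng, 50)
        obs[10:13] = np.nan
        ll, gamma, _ = forward_backward(obs, params)
        assert np.isfinite(ll)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            forward_backward(np.full(5, np.nan), random_params(np.random.default_rng(0)))


class TestViterbi:
    def test_matches_brute_force_100_instances(self):
        rng = np.random.default_rng(42)
        for i in range(100):
            T = int(rng.integers(2, 13))
            params = random_params(rng)
            obs = random_obs(rng, T)
            got = viterbi(obs, params)
            _, _, best_path, best_lj = enumerate_paths(obs, params)
            assert got.log_joint == pytest.approx(best_lj, abs=1e-9)
            np.testing.assert_array_equal(got.states, best_path)

    def test_all_zero_counts_decode_sleep(self):
        params = HMMParams(
            a=np.array([[0.9, 0.1], [0.1, 0.9]]), alpha_zero=0.5,
            mu_sleep=0.2, sigma_sleep=0.3, mu_wake=4.0, sigma_wake=0.5,
            pi=np.array([0.5, 0.5]),
        )
        obs = np.zeros(20)
        assert np.all(viterbi(obs, params).states == SLEEP)

    def test_absorbing_wake_chain(self):
        params = HMMParams(
            a=np.eye(2), alpha_zero=0.5, mu_sleep=0.2, sigma_sleep=0.3,
            mu_wake=4.0, sigma_wake=0.5, pi=np.array([0.0, 1.0]),
        )
        obs = np.zeros(10)  # sleep-looking data cannot override pi + identity A
        assert np.all(viterbi(obs, params).states == WAKE)

    def test_missing_labeled_missing(self):
        rng = np.random.default_rng(3)
        params = random_params(rng)
        obs = random_obs(rng, 30)
        obs[5] = np.nan
        path = viterbi(obs, params)
        assert path.states[5] == MISSING
        assert np.all(path.states[np.isnan(obs)] == MISSING)


class TestBaumWelch:
    def test_loglik_nondecreasing_and_convergence(self):
        truth = HMMParams(
            a=np.array([[0.95, 0.05], [0.03, 0.97]]), alpha_zero=0.4,
            mu_sleep=0.3, sigma_sleep=0.4, mu_wake=4.5, sigma_wake=1.0,
            pi=np.array([0.5, 0.5]),
        )
        obs, _ = simulate_observations(truth, 1000, seed=7)
        params, diag = baum_welch(obs, init="auto")
        trace = np.array(diag.log_likelihood_trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert diag.converged
        assert params.mu_sleep < params.mu_wake

    def test_init_at_truth_stays_close(self):
        truth = HMMParams(
            a=np.array([[0.95, 0.05], [0.03, 0.97]]), alpha_zero=0.4,
            mu_sleep=0.3, sigma_sleep=0.4, mu_wake=4.5, sigma_wake=1.0,
            pi=np.array([0.5, 0.5]),
        )
        obs, _ = simulate_observations(truth, 2016, seed=11)
        params, diag = baum_welch(obs, init=truth)
        assert diag.converged and diag.n_iterations < 50
        assert params.mu_wake == pytest.approx(truth.mu_wake, abs=0.1)

    def test_no_zeros_gives_zero_alpha(self):
        truth = HMMParams(
            a=np.array([[0.9, 0.1], [0.1, 0.9]]), alpha_zero=0.0,
            mu_sleep=1.0, sigma_sleep=0.3, mu_wake=4.0, sigma_wake=0.8,
            pi=np.array([0.5, 0.5]),
        )
        obs, _ = simulate_observations(truth, 1500, seed=2)
        obs = np.maximum(obs, 1e-6)  # ensure no exact zeros at all
        params, _ = baum_welch(obs, init="auto")
        assert params.alpha_zero == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery(self, recovery_fits):
        truth = recovery_fits[0]["truth"]
        est = {k: np.mean([f["params"].__getattribute__(k) for f in recovery_fits])
               for k in ("mu_sleep", "mu_wake", "alpha_zero")}
        assert est["mu_sleep"] == pytest.approx(truth.mu_sleep, abs=0.1)
        assert est["mu_wake"] == pytest.approx(truth.mu_wake, abs=0.1)
        assert est["alpha_zero"] == pytest.approx(truth.alpha_zero, abs=0.05)
        a11 = np.mean([f["params"].a[0, 0] for f in recovery_fits])
        a22 = np.mean([f["params"].a[1, 1] for f in recovery_fits])
        assert a11 == pytest.approx(truth.a[0, 0], abs=0.02)
        assert a22 == pytest.approx(truth.a[1, 1], abs=0.02)

    def test_every_fit_monotone(self, recovery_fits):
        for f in recovery_fits:
            trace = np.array(f["diag"].log_likelihood_trace)
            assert np.all(np.diff(trace) >= -1e-8)


class TestFitIndividual:
    def test_synthetic_week_accuracy(self, default_cohort):
        series, truth = default_cohort
        s = series[0]
        params, path, diag = fit_individual(s)
        true_states = truth[s.individual_id]["states"]
        seen = path.states != MISSING
        acc = np.mean(path.states[seen] == true_states[seen])
        assert acc >= 0.95
        assert params.mu_sleep < params.mu_wake

    def test_deterministic(self, default_cohort):
        series, _ = default_cohort
        s = series[1]
        p1, path1, _ = fit_individual(s)
        p2, path2, _ = fit_individual(s)
        assert p1.mu_wake == p2.mu_wake and p1.alpha_zero == p2.alpha_zero
        np.testing.assert_array_equal(path1.states, path2.states)

    def test_too_short_rejected(self):
        s = EpochSeries("x", pd.Timestamp("2014-01-06"), 300, np.arange(50, dtype=float))
        with pytest.raises(ValueError, match="fewer than"):
            fit_individual(s)

    def test_long_gap_splits_segments(self):
        obs = np.concatenate([np.ones(100), np.full(30, np.nan), np.ones(100)])
        segs = split_segments(obs, epoch_seconds=300, max_gap_minutes=60)
        assert len(segs) == 2
        assert segs[0][0] == 0 and segs[1][0] == 130
        # short gap stays within one segment
        obs2 = np.concatenate([np.ones(100), np.full(5, np.nan), np.ones(100)])
        assert len(split_segments(obs2, 300, 60)) == 1
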