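"""Likelihood, prior, tempering and sensitivity computations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import odemcmc as om
from odemcmc.models import Dataset
from odemcmc.posterior import log_posterior, sensitivities


class TestLogPrior:
    def test_inside_and_outside_box(self, m3_problem):
        assert om.log_prior(m3_problem, [1.0, 0.2, 0.03]) == 0.0
        assert om.log_prior(m3_problem, [6.0, 0.2, 0.03]) == -np.inf

    def test_boundary_is_closed(self, m3_problem):
        theta = np.array([5.0, 0.2, 0.03])  # b1 exactly at theta_max
        assert om.log_prior(m3_problem, theta) == 0.0


class TestLogLikelihood:
    def _point_problem(self, resid, sigma):
        """Single-observation likelihood via a zero-dynamics M3 variant."""
        p = om.make_benchmark("M3")
        data = Dataset(np.array([1.0]), np.array([[resid]]))
        theta = np.array([0.0, 1.0, sigma])  # b1=0 => y(t)=0, residual=resid
        return om.log_likelihood(p, data, theta)

    def test_zero_residual_unit_sigma(self):
        assert self._point_problem(0.0, 1.0) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_unit_residual_unit_sigma(self):
        assert self._point_problem(1.0, 1.0) == pytest.approx(
            -0.5 * np.log(2 * np.pi) - 0.5, abs=1e-12)

    def test_m1b_symmetry_exact(self, m1b_problem, m1b_data):
        theta = m1b_problem.theta_true
        swapped = theta.copy()
        swapped[[2, 3]] = swapped[[3, 2]]
        a = om.log_likelihood(m1b_problem, m1b_data, theta)
        b = om.log_likelihood(m1b_problem, m1b_data, swapped)
        assert a == b

    def test_missing_values_are_skipped(self, m3_problem):
        data = om.generate_data(m3_problem, seed=2)
        full = om.log_likelihood(m3_problem, data, m3_problem.theta_true)
        ragged_obs = data.observations.copy()
        ragged_obs[10, 0] = np.nan
        ragged = Dataset(data.times, ragged_obs)
        partial = om.log_likelihood(m3_problem, ragged,
                                    m3_problem.theta_true)
        assert partial != full
        assert np.isfinite(partial)

    def test_time_permutation_invariance(self, m3_problem):
        data = om.generate_data(m3_problem, seed=2)
        perm = np.random.default_rng(0).permutation(data.n_t)
        # likelihood is a product over (t_k, y_k) pairs; use sorted re-pairing
        order = np.argsort(data.times[perm])
        permuted = Dataset(data.times[perm][order],
                           data.observations[perm][order])
        a = om.log_likelihood(m3_problem, data, m3_problem.theta_true)
        b = om.log_likelihood(m3_problem, permuted, m3_problem.theta_true)
        assert a == pytest.approx(b, rel=1e-12)


class TestLogPosterior:
    def test_prior_screen_skips_solver(self, m3_problem, m3_data):
        target = om.PosteriorTarget(m3_problem, m3_data)
        before = target.n_evals
        assert target.log_posterior(np.array([6.0, 0.2, 0.03])) == -np.inf
        assert target.n_evals == before  # likelihood never evaluated

    def test_uniform_prior_adds_nothing(self, m3_problem, m3_data):
        theta = m3_problem.theta_true
        ev = log_posterior(m3_problem, m3_data, theta)
        assert ev.log_posterior == ev.log_likelihood
        assert ev.log_prior == 0.0

    def test_m1b_posterior_symmetry(self, m1b_problem, m1b_data):
        theta = m1b_problem.theta_true
        swapped = theta.copy()
        swapped[[2, 3]] = swapped[[3, 2]]
        a = log_posterior(m1b_problem, m1b_data, theta)
        b = log_posterior(m1b_problem, m1b_data, swapped)
        assert a.log_posterior == b.log_posterior


class TestTempering:
    def test_beta_one_is_posterior(self, m3_problem, m3_data):
        theta = m3_problem.theta_true
        assert om.log_tempered_posterior(m3_problem, m3_data, theta, 1.0) == \
            log_posterior(m3_problem, m3_data, theta).log_posterior

    def test_tempering_arithmetic(self, m3_problem, m3_data):
        theta = m3_problem.theta_true
        ll = om.log_likelihood(m3_problem, m3_data, theta)
        assert om.log_tempered_posterior(m3_problem, m3_data, theta, 2.0) == \
            pytest.approx(ll / 2.0, rel=1e-12)

    def test_beta_below_one_rejected(self, m3_problem, m3_data):
        with pytest.raises(ValueError, match=">= 1"):
            om.log_tempered_posterior(m3_problem, m3_data,
                                      m3_problem.theta_true, 0.5)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=1.0, max_value=1e6))
    def test_monotone_in_beta_for_negative_loglik(self, beta):
        # with log L < 0 the tempered value is non-decreasing in beta
        p = om.make_benchmark("M3")
        data = Dataset(np.array([1.0]), np.array([[5.0]]))
        theta = np.array([0.0, 1.0, 0.5])
        base = om.log_tempered_posterior(p, data, theta, 1.0)
        assert base < 0
        assert om.log_tempered_posterior(p, data, theta, beta) >= base


class TestSensitivities:
    @pytest.mark.parametrize("name,seed", [("M3", 1), ("M1b", 3)])
    def test_gradient_matches_finite_differences(self, name, seed):
        p = om.make_benchmark(name)
        data = om.generate_data(p, seed=seed)
        rng = np.random.default_rng(9)
        width = p.theta_max - p.theta_min
        for _ in range(3):
            if p.theta_true is not None:
                theta = np.clip(
                    p.theta_true + 0.01 * width * rng.standard_normal(p.n_theta),
                    p.theta_min + 1e-6 * width, p.theta_max - 1e-6 * width)
            grad = sensitivities(p, data, theta).gradient
            fd = np.zeros_like(theta)
            for j in range(theta.size):
                h = 1e-5 * max(abs(theta[j]), 1e-3)
                tp, tm = theta.copy(), theta.copy()
                tp[j] += h
                tm[j] -= h
                fd[j] = (log_posterior(p, data, tp).log_posterior
                         - log_posterior(p, data, tm).log_posterior) / (2 * h)
            np.testing.assert_allclose(grad, fd, rtol=1e-4,
                                       atol=1e-4 * np.abs(fd).max())

    def test_ode_route_gradient(self):
        # forward sensitivity equations on a model without closed form
        p = om.make_benchmark("M2")
        times = np.linspace(0.0, 20.0, 11)
        sim = om.simulate(p, p.theta_true, times)
        data = Dataset(times, sim.observables + 0.1)
        theta = p.theta_true
        grad = sensitivities(p, data, theta).gradient
        fd = np.zeros_like(theta)
        for j in range(theta.size):
            h = 1e-5 * max(abs(theta[j]), 1e-3)
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd[j] = (log_posterior(p, data, tp).log_posterior
                     - log_posterior(p, data, tm).log_posterior) / (2 * h)
        np.testing.assert_allclose(grad, fd, rtol=1e-3,
                                   atol=1e-4 * np.abs(fd).max())

    def test_fim_symmetric_positive_semidefinite(self, m3_problem, m3_data):
        rng = np.random.default_rng(4)
        for _ in range(5):
            theta = rng.uniform(m3_problem.theta_min + 1e-3,
                                np.minimum(m3_problem.theta_max, 5.0))
            fim = sensitivities(m3_problem, m3_data, theta).fim
            np.testing.assert_allclose(fim, fim.T, atol=1e-12)
            assert np.min(np.linalg.eigvalsh(fim)) > 0  # after regularization

    def test_m1b_gradient_symmetry_pattern(self, m1b_problem, m1b_data):
        theta = m1b_problem.theta_true
        swapped = theta.copy()
        swapped[[2, 3]] = swapped[[3, 2]]
        g = sensitivities(m1b_problem, m1b_data, theta).gradient
        gs = sensitivities(m1b_problem, m1b_data, swapped).gradient
        mirrored = gs.copy()
        mirrored[[2, 3]] = mirrored[[3, 2]]
        np.testing.assert_allclose(g, mirrored, rtol=1e-5, atol=1e-6)

    def test_outside_box_raises(self, m3_problem, m3_data):
        with pytest.raises(ValueError, match="prior box"):
            sensitivities(m3_problem, m3_data, np.array([6.0, 0.2, 0.03]))
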