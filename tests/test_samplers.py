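"""Kernel mechanics of the five samplers against analytic oracles."""

import math

import numpy as np
import pytest

import odemcmc as om
from odemcmc.samplers import (
    ChainState,
    ProposalState,
    SamplerConfig,
    TemperatureLadder,
    am_update,
    dr_log_acceptance,
    dram_step,
    mh_step,
    phs_step,
    pt_swap,
    run_sampler,
)


class TestMhStep:
    def test_uphill_always_accepted(self, gauss2d):
        state = ChainState(np.array([3.0, 3.0]), gauss2d)
        uphill = lambda rng, theta: (theta * 0.5, 0.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert mh_step(state, gauss2d, uphill, rng)

    def test_out_of_box_always_rejected(self, gauss2d):
        state = ChainState(np.zeros(2), gauss2d)
        escape = lambda rng, theta: (theta + 1e3, 0.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert not mh_step(state, gauss2d, escape, rng)
        np.testing.assert_array_equal(state.theta, 0.0)

    def test_two_state_occupation(self, two_state):
        # exact stationary occupation (2/3, 1/3) of the flip-proposal chain
        state = ChainState(np.array([0.0]), two_state)
        rng = np.random.default_rng(42)
        hits = 0
        n = 100_000
        for _ in range(n):
            mh_step(state, two_state, two_state.flip_proposal, rng)
            hits += state.theta[0] < 0.5
        assert abs(hits / n - 2.0 / 3.0) < 0.01


class TestAmUpdate:
    def test_dim_scale_factor(self):
        # s_d = 2.38^2 / d for d = 5
        p = ProposalState(5, scheme="dim", adapt_start=1, chol_interval=1)
        for i in range(20):
            am_update(p, np.arange(5) * 1.0 + i**2)
        emp = p.empirical_covariance() + p.eps * np.eye(5)
        np.testing.assert_allclose(p.covariance, (2.38**2 / 5) * emp,
                                   rtol=1e-10)
        assert 2.38**2 / 5 == pytest.approx(1.1329, abs=1e-4)

    def test_recursive_covariance_matches_batch(self):
        rng = np.random.default_rng(1)
        samples = rng.standard_normal((50, 3))
        p = ProposalState(3, scheme="acc")
        for s in samples:
            am_update(p, s)
        np.testing.assert_allclose(p.empirical_covariance(),
                                   np.cov(samples.T, ddof=1), atol=1e-10)

    def test_constant_history_falls_back_to_regularization(self):
        p = ProposalState(2, scheme="dim", adapt_start=10, chol_interval=1)
        for _ in range(20):
            am_update(p, np.ones(2))
        np.testing.assert_allclose(
            p.base_chol(), math.sqrt(p.eps) * np.eye(2), atol=1e-12)

    def test_acceptance_scale_decays_toward_target(self):
        # with everything accepted the log-scale grows by sum i^-0.51 * 0.766
        p = ProposalState(2, scheme="acc")
        start = p.log_scale
        for _ in range(100):
            am_update(p, np.zeros(2), accepted=True)
        expected = start + (1 - 0.234) * np.sum(
            np.arange(1, 101) ** -0.51)
        assert p.log_scale == pytest.approx(expected, rel=1e-12)


class TestDelayedRejection:
    def test_two_stage_alpha_matches_hand_formula(self):
        # 1-d standard normal target, x=0, rejected y1=3, then y2=0.5,
        # unit-variance symmetric proposals at both stages
        x, y1, y2 = np.zeros(1), np.array([3.0]), np.array([0.5])
        logpi = lambda v: -0.5 * float(v @ v)
        log_q = lambda j, a, b: -0.5 * float((b - a) @ (b - a))
        alpha1 = lambda a, b: min(1.0, math.exp(logpi(b) - logpi(a)))
        num = (math.exp(logpi(y2)) * math.exp(log_q(1, y2, y1))
               * (1 - alpha1(y2, y1)))
        den = (math.exp(logpi(x)) * math.exp(log_q(1, x, y1))
               * (1 - alpha1(x, y1)))
        expected = min(1.0, num / den)
        got = math.exp(dr_log_acceptance(
            [x, y1, y2], [logpi(x), logpi(y1), logpi(y2)], log_q))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_first_stage_acceptance_short_circuits(self, gauss2d):
        state = ChainState(np.array([5.0, 5.0]), gauss2d,
                           ProposalState(2, scheme="dim"))
        rng = np.random.default_rng(3)
        for _ in range(200):
            accepted = dram_step(state, gauss2d, rng)
            if accepted and state.stage_counter == 1:
                break
        else:
            pytest.fail("no first-stage acceptance observed")

    def test_two_state_stationarity(self, two_state):
        state = ChainState(np.array([0.0]), two_state,
                           ProposalState(1, scheme="dim", eps=0.25))
        rng = np.random.default_rng(7)
        hits = 0
        n = 40_000
        for _ in range(n):
            dram_step(state, two_state, rng)
            hits += state.theta[0] < 0.5
        assert abs(hits / n - 2.0 / 3.0) < 0.02


class TestMala:
    def test_proposal_moments_on_standard_normal(self):
        # N(0,1) target at theta=1 with eps=1, G=1: mean 0.5, variance 1
        target = om.GaussianTarget([0.0], [[1.0]])
        grad, fim = target.grad_fim(np.array([1.0]))
        assert grad[0] == pytest.approx(-1.0)
        from odemcmc.samplers import _mala_forward, _mala_log_q

        L = np.linalg.cholesky(fim)
        mean = _mala_forward(np.array([1.0]), grad, L, 1.0)
        assert mean[0] == pytest.approx(0.5, abs=1e-12)
        # hand-checked acceptance ratio for a concrete draw y = -0.3
        y = np.array([-0.3])
        grad_y, fim_y = target.grad_fim(y)
        Ly = np.linalg.cholesky(fim_y)
        mean_rev = _mala_forward(y, grad_y, Ly, 1.0)
        log_ratio = (target.log_likelihood(y)
                     - target.log_likelihood(np.array([1.0]))
                     + _mala_log_q(mean_rev, Ly, 0.0, 1.0, np.array([1.0]))
                     - _mala_log_q(mean, L, 0.0, 1.0, y))
        expected = (-0.5 * 0.3**2 + 0.5 * 1.0
                    - 0.5 * (1.0 - mean_rev[0]) ** 2
                    + 0.5 * (y[0] - mean[0]) ** 2)
        assert log_ratio == pytest.approx(expected, abs=1e-12)

    def test_drift_vanishes_at_mode(self):
        target = om.GaussianTarget(np.zeros(2), np.eye(2))
        grad, fim = target.grad_fim(np.zeros(2))
        from odemcmc.samplers import _mala_forward

        mean = _mala_forward(np.zeros(2), grad, np.linalg.cholesky(fim), 0.7)
        np.testing.assert_allclose(mean, 0.0, atol=1e-14)

    def test_stationary_on_standard_normal(self):
        target = om.GaussianTarget([0.0], [[1.0]])
        cfg = SamplerConfig(algorithm="mala", step_size=1.5)
        run = run_sampler(cfg, target, np.array([[0.0]]), 40_000, seed=5)
        sample = run.trace[5_000:, 0]
        assert abs(sample.mean()) < 0.04
        assert sample.var() == pytest.approx(1.0, rel=0.05)


class TestParallelTempering:
    def test_swap_probability_hand_value(self, gauss2d):
        ladder = TemperatureLadder(np.array([1.0, 2.0]))
        a = ChainState(np.zeros(2), gauss2d, beta=1.0)
        b = ChainState(np.zeros(2), gauss2d, beta=2.0)
        a.log_lik, b.log_lik = -5.0, -10.0
        from odemcmc.samplers import _swap_log_prob

        # (1/1 - 1/2) * (-10 - (-5)) = -2.5
        assert _swap_log_prob(a, b) == pytest.approx(-2.5)
        assert math.exp(-2.5) == pytest.approx(0.0821, abs=1e-4)

    def test_equal_temperatures_always_swap(self, gauss2d):
        a = ChainState(np.zeros(2), gauss2d, beta=3.0)
        b = ChainState(np.ones(2) * 0.1, gauss2d, beta=3.0)
        from odemcmc.samplers import _swap_log_prob

        assert _swap_log_prob(a, b) == 0.0

    def test_ee_proposes_nearest_energies(self, gauss2d):
        ladder = TemperatureLadder(np.array([1.0, 10.0, 100.0]),
                                   swap_strategy="ee")
        states = [ChainState(np.zeros(2), gauss2d, beta=b)
                  for b in ladder.betas]
        for s, e in zip(states, (-3.0, -7.1, -7.3)):
            s.log_lik = e
        rng = np.random.default_rng(0)
        results = pt_swap(states, ladder, rng)
        assert len(results) == 1
        assert results[0][0] == 1  # the (2, 3) adjacent pair

    def test_single_temperature_degenerates_to_am(self, m3_target):
        init = om.init_from_prior(m3_target.problem, 1, seed=2)
        run_pt = run_sampler(SamplerConfig(algorithm="pt", n_temperatures=1),
                             m3_target, init, 500, seed=11)
        run_am = run_sampler(SamplerConfig(algorithm="am", scheme="acc"),
                             m3_target, init, 500, seed=11)
        np.testing.assert_array_equal(run_pt.trace, run_am.trace)

    def test_ladder_stays_sorted_with_unit_base(self, gauss2d):
        ladder = TemperatureLadder.geometric(6, 1e4)
        rng = np.random.default_rng(1)
        for i in range(500):
            pairs = [(j, bool(rng.integers(2)))
                     for j in range(ladder.L - 1)]
            ladder.adapt(pairs)
            assert ladder.betas[0] == 1.0
            assert np.all(np.diff(ladder.betas) > 0)

    def test_adaptive_count_never_below_two(self, gauss2d):
        ladder = TemperatureLadder(np.array([1.0, 1.001, 1.002]),
                                   adaptive_count=True, drop_threshold=0.1)
        assert ladder.should_drop_hottest()
        ladder.drop_hottest()
        assert ladder.L == 2
        assert not ladder.should_drop_hottest()


class TestPhs:
    def test_exchange_every_iteration_with_one_auxiliary(self, gauss2d):
        ss = np.random.SeedSequence(0)
        main = ChainState(np.array([1.0, 1.0]), gauss2d)
        aux = ChainState(np.array([-1.0, -1.0]), gauss2d,
                         ProposalState(2, scheme="acc"))
        rngs = [np.random.default_rng(s) for s in ss.spawn(2)]
        before_main = main.theta.copy()
        before_aux = aux.theta.copy()
        phs_step(main, [aux], gauss2d, rngs[:1], rngs[1])
        # main now holds the (possibly moved) auxiliary position
        assert not np.array_equal(main.theta, before_main)

    def test_zero_auxiliaries_is_an_error(self, gauss2d):
        main = ChainState(np.zeros(2), gauss2d)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="auxiliary"):
            phs_step(main, [], gauss2d, [], rng)

    def test_swap_count_equals_iterations(self, two_state):
        cfg = SamplerConfig(algorithm="phs", n_aux=2)
        run = run_sampler(cfg, two_state, np.array([[0.0]]), 1000, seed=3)
        assert run.extras["swap_count"] == 1000

    def test_two_state_occupation(self, two_state):
        cfg = SamplerConfig(algorithm="phs", n_aux=4, eps=0.25)
        run = run_sampler(cfg, two_state, np.array([[0.0]]), 40_000, seed=9)
        assert abs(two_state.occupation(run.trace) - 2 / 3) < 0.02


class TestRunSampler:
    def test_trace_bookkeeping(self, m3_target):
        init = om.init_from_prior(m3_target.problem, 1, seed=0)
        run = run_sampler(SamplerConfig(algorithm="am"), m3_target, init,
                          10, seed=1)
        assert run.trace.shape == (10, 3)
        assert run.log_posterior_trace.shape == (10,)
        assert run.cpu_seconds > 0

    def test_bit_reproducibility(self, m3_target):
        init = om.init_from_prior(m3_target.problem, 1, seed=0)
        cfg = SamplerConfig(algorithm="am", scheme="acc")
        a = run_sampler(cfg, m3_target, init, 300, seed=4)
        b = run_sampler(cfg, m3_target, init, 300, seed=4)
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_dram_refuses_acceptance_scaling(self):
        with pytest.raises(ValueError, match="dim"):
            SamplerConfig(algorithm="dram", scheme="acc").validate()

    def test_trace_stays_inside_prior_box(self, m3_target):
        init = om.init_from_prior(m3_target.problem, 1, seed=5)
        run = run_sampler(SamplerConfig(algorithm="am"), m3_target, init,
                          2000, seed=6)
        assert np.all(run.trace >= m3_target.lower)
        assert np.all(run.trace <= m3_target.upper)

    def test_am_acc_acceptance_near_target(self, m3_target):
        # the 0.234-target adaptation should land in a sensible band
        ms = om.multistart_optimize(m3_target.problem, m3_target.data,
                                    n_starts=10, seed=8)
        init = om.init_from_multistart(ms, 1)
        cfg = SamplerConfig(algorithm="am", scheme="acc")
        run = run_sampler(cfg, m3_target, init, 50_000, seed=2)
        assert 0.15 < run.acceptance_rate < 0.35
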