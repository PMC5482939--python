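"""Metropolis-Hastings kernel and the five sampler variants.

Single-chain samplers: adaptive Metropolis with dimension-based (``dim``)
or acceptance-rate-based (``acc``) proposal scaling, delayed rejection
adaptive Metropolis (DRAM, ``dim`` scaling only), and the Fisher-
preconditioned Metropolis-adjusted Langevin algorithm (MALA).

Multi-chain samplers: parallel tempering (PT) over an adaptive ladder of
inverse-temperature exponents beta_l >= 1 (tempered target
log p(theta) + log L(theta)/beta_l) with all-adjacent (``aa``) or
equi-energy (``ee``) swap proposals, and parallel hierarchical sampling
(PHS) where auxiliary chains target the posterior and the main chain
exchanges its state with a uniformly chosen auxiliary, unconditionally.

Adaptation follows diminishing Robbins-Monro steps ~ i^(-0.51): the
acceptance-rate proposal scale targets 0.234, the MALA step size targets
0.574, and PT temperature spacings target a 0.23 swap rate.  The empirical
proposal covariance is tracked by a rank-1 (Welford) recursion; its
Cholesky factor is refreshed every few iterations since adaptation is
diminishing anyway.

Reproducibility contract: a master seed spawns one stream per chain plus a
dedicated stream for swap decisions, so within-chain random sequences do
not depend on swap outcomes.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from odemcmc.targets import Target

__all__ = [
    "ProposalState",
    "ChainState",
    "TemperatureLadder",
    "SamplerConfig",
    "SamplerRun",
    "mh_step",
    "am_update",
    "am_chain_step",
    "dram_step",
    "dr_log_acceptance",
    "mala_step",
    "pt_swap",
    "pt_step",
    "phs_step",
    "run_sampler",
]

_log = logging.getLogger(__name__)

TARGET_ACCEPT_RW = 0.234
TARGET_ACCEPT_MALA = 0.574
TARGET_SWAP_RATE = 0.23
ADAPT_DECAY = 0.51  # exponent in (0.5, 1]: diminishing adaptation


# ---------------------------------------------------------------------------
# Proposal adaptation
# ---------------------------------------------------------------------------

class ProposalState:
    """Adaptive Gaussian proposal: empirical covariance plus a scale.

    ``scheme='dim'`` scales the regularized sample covariance by
    2.38^2 / d; ``scheme='acc'`` multiplies it by an adapted scalar
    exp(log_scale) driven toward ``target_accept``.  Before ``adapt_start``
    samples have accrued the proposal is eps * I.
    """

    __slots__ = ("d", "scheme", "eps", "target_accept", "adapt_start",
                 "chol_interval", "mean", "_m2", "n_samples", "iteration",
                 "acceptance_count", "log_scale", "_chol", "_chol_age",
                 "_scale_sqrt")

    def __init__(self, d: int, scheme: str = "acc", eps: float = 1e-8,
                 target_accept: float = TARGET_ACCEPT_RW,
                 adapt_start: int = 100, chol_interval: int = 25):
        if scheme not in ("dim", "acc"):
            raise ValueError(f"unknown adaptation scheme {scheme!r}")
        self.d = d
        self.scheme = scheme
        self.eps = eps
        self.target_accept = target_accept
        self.adapt_start = adapt_start
        self.chol_interval = chol_interval
        self.mean = np.zeros(d)
        self._m2 = np.zeros((d, d))
        self.n_samples = 0
        self.iteration = 0
        self.acceptance_count = 0
        self.log_scale = math.log(2.38**2 / d)
        self._chol = math.sqrt(eps) * np.eye(d)
        self._chol_age = 0
        self._refresh_scale()

    def _refresh_scale(self) -> None:
        if self.scheme == "dim":
            self._scale_sqrt = 2.38 / math.sqrt(self.d)
        else:
            self._scale_sqrt = math.exp(0.5 * self.log_scale)

    @property
    def covariance(self) -> np.ndarray:
        """Current full proposal covariance (scale times regularized cov)."""
        L = self._scale_sqrt * self._chol
        return L @ L.T

    def empirical_covariance(self) -> np.ndarray:
        if self.n_samples < 2:
            return np.zeros((self.d, self.d))
        return self._m2 / (self.n_samples - 1)

    def base_chol(self) -> np.ndarray:
        return self._chol

    def draw(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.d)
        return theta + self._scale_sqrt * (self._chol @ z)

    def _refresh_chol(self) -> None:
        cov = self.empirical_covariance() + self.eps * np.eye(self.d)
        try:
            self._chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:  # degenerate history
            self._chol = math.sqrt(self.eps) * np.eye(self.d)
        self._chol_age = 0


def am_update(proposal: ProposalState, new_sample: np.ndarray,
              accepted: bool = False,
              scheme: Optional[str] = None,
              target_acceptance: Optional[float] = None) -> ProposalState:
    """Advance the adaptive-Metropolis proposal by one chain sample.

    Called once per iteration after the MH step with the (possibly
    repeated) chain sample.  Updates the running mean/covariance recursion,
    the acceptance-rate-driven scalar scale for the ``acc`` scheme, and
    periodically refreshes the proposal Cholesky factor.
    """
    p = proposal
    if scheme is not None and scheme != p.scheme:
        raise ValueError("scheme mismatch with proposal state")
    target = p.target_accept if target_acceptance is None else target_acceptance
    p.iteration += 1
    if accepted:
        p.acceptance_count += 1

    p.n_samples += 1
    delta = new_sample - p.mean
    p.mean = p.mean + delta / p.n_samples
    p._m2 = p._m2 + np.outer(delta, new_sample - p.mean)

    if p.scheme == "acc":
        step = p.iteration ** (-ADAPT_DECAY)
        p.log_scale += step * ((1.0 if accepted else 0.0) - target)
        p._refresh_scale()

    if p.n_samples >= p.adapt_start:
        p._chol_age += 1
        if p._chol_age >= p.chol_interval or p.n_samples == p.adapt_start:
            p._refresh_chol()
    return p


# ---------------------------------------------------------------------------
# Chain state and the generic MH kernel
# ---------------------------------------------------------------------------

class ChainState:
    """Current position of one chain with cached target values.

    ``log_target`` caches log_prior + log_likelihood / beta and is kept
    coherent whenever theta or beta changes.
    """

    __slots__ = ("theta", "log_lik", "log_prior", "beta", "proposal",
                 "log_target", "mala", "stage_counter")

    def __init__(self, theta: np.ndarray, target: Target,
                 proposal: Optional[ProposalState] = None, beta: float = 1.0):
        self.theta = np.asarray(theta, dtype=float)
        self.log_prior = target.log_prior(self.theta)
        self.log_lik = (target.log_likelihood(self.theta)
                        if self.log_prior > -np.inf else -np.inf)
        self.beta = beta
        self.proposal = proposal
        self.mala = None  # cached (grad, metric chol, logdet) at theta
        self.stage_counter = 0
        self._recompute_target()

    def _recompute_target(self) -> None:
        if self.log_prior == -np.inf:
            self.log_target = -np.inf
        else:
            self.log_target = self.log_prior + self.log_lik / self.beta

    def set_beta(self, beta: float) -> None:
        self.beta = beta
        self._recompute_target()

    def set_position(self, theta, log_lik, log_prior) -> None:
        self.theta = theta
        self.log_lik = log_lik
        self.log_prior = log_prior
        self.mala = None
        self._recompute_target()

    def log_posterior(self) -> float:
        return self.log_prior + self.log_lik


def _evaluate(target: Target, theta: np.ndarray) -> tuple[float, float]:
    """(log_prior, log_likelihood); the likelihood is skipped out of box."""
    lp = target.log_prior(theta)
    if lp == -np.inf:
        return lp, -np.inf
    return lp, target.log_likelihood(theta)


def mh_step(state: ChainState, target: Target,
            proposal_sampler: Callable[[np.random.Generator, np.ndarray],
                                       tuple[np.ndarray, float]],
            rng: np.random.Generator) -> bool:
    """One Metropolis-Hastings step with a user-supplied proposal.

    ``proposal_sampler(rng, theta)`` returns a candidate and the log
    proposal-density correction log q(cand -> theta) - log q(theta -> cand)
    (0 for symmetric proposals).  NaN target values are treated as -inf.
    """
    cand, log_q_corr = proposal_sampler(rng, state.theta)
    lp, ll = _evaluate(target, cand)
    if math.isnan(ll):
        _log.warning("target returned NaN at %s; treating as -inf", cand)
        ll = -np.inf
    if lp == -np.inf:
        return False
    log_ratio = (lp + ll / state.beta) - state.log_target + log_q_corr
    if log_ratio >= 0 or rng.random() < math.exp(log_ratio):
        state.set_position(cand, ll, lp)
        return True
    return False


def am_chain_step(state: ChainState, target: Target,
                  rng: np.random.Generator) -> bool:
    """One adaptive-Metropolis step (symmetric Gaussian proposal)."""
    p = state.proposal
    cand = p.draw(state.theta, rng)
    accepted = False
    if target.in_box(cand):
        ll = target.log_likelihood(cand)
        if math.isnan(ll):
            ll = -np.inf
        log_ratio = ll / state.beta - (state.log_target - state.log_prior)
        if log_ratio >= 0 or rng.random() < math.exp(log_ratio):
            state.set_position(cand, ll, 0.0)
            accepted = True
    am_update(p, state.theta, accepted)
    return accepted


# ---------------------------------------------------------------------------
# Delayed rejection
# ---------------------------------------------------------------------------

def _log1mexp(log_a: float) -> float:
    """log(1 - exp(log_a)) for log_a <= 0."""
    if log_a >= 0.0:
        return -np.inf
    if log_a > -1e-12:
        return -np.inf
    return math.log1p(-math.exp(log_a))


def dr_log_acceptance(points: Sequence[np.ndarray],
                      log_pi: Sequence[float],
                      stage_log_q: Callable[[int, np.ndarray, np.ndarray],
                                            float]) -> float:
    """Log delayed-rejection acceptance probability for a proposal path.

    ``points = [x, y1, ..., yk]`` is the current point followed by the
    successively rejected (and final) candidates; ``log_pi`` their target
    log-densities; ``stage_log_q(j, a, b)`` the stage-j proposal log-density
    of b given a (symmetric kernels).  Implements the reversibility-
    preserving recursion with stage-k kernels cancelling between numerator
    and denominator.
    """

    def alpha(idx: tuple[int, ...]) -> float:
        k = len(idx) - 1
        if log_pi[idx[-1]] == -np.inf:
            return -np.inf
        if k == 1:
            return min(0.0, log_pi[idx[1]] - log_pi[idx[0]])
        log_num = log_pi[idx[-1]]
        log_den = log_pi[idx[0]]
        for j in range(1, k):
            log_num += stage_log_q(j, points[idx[-1]], points[idx[-1 - j]])
            log_den += stage_log_q(j, points[idx[0]], points[idx[j]])
            log_num += _log1mexp(alpha(idx[::-1][: j + 1]))
            a_fwd = _log1mexp(alpha(idx[: j + 1]))
            if a_fwd == -np.inf:  # earlier stage accepts surely: unreachable
                return -np.inf
            log_den += a_fwd
        if log_den == -np.inf:
            return 0.0
        return min(0.0, log_num - log_den)

    return alpha(tuple(range(len(points))))


def dram_step(state: ChainState, target: Target, rng: np.random.Generator,
              n_tries: int = 2, stage_scale: float = 0.2) -> bool:
    """One DRAM step: AM('dim') proposal with delayed-rejection stages.

    On rejection of stage j, stage j+1 proposes from the current point with
    the stage covariance scaled by ``stage_scale**(2 j)`` (standard-
    deviation down-scaling by 1/5 per stage by default).
    """
    p = state.proposal
    base_chol = p._scale_sqrt * p.base_chol()
    d = p.d
    prec_chol = None  # lazily built for stage densities

    points = [state.theta]
    log_pi = [state.log_target]
    accepted = False
    stage = 0
    for stage in range(1, n_tries + 1):
        fac = stage_scale ** (stage - 1)
        cand = points[0] + fac * (base_chol @ rng.standard_normal(d))
        lp, ll = _evaluate(target, cand)
        if math.isnan(ll):
            ll = -np.inf
        points.append(cand)
        log_pi.append(lp + ll / state.beta if lp > -np.inf else -np.inf)
        if stage == 1:
            log_alpha = (min(0.0, log_pi[1] - log_pi[0])
                         if log_pi[1] > -np.inf else -np.inf)
        else:
            if prec_chol is None:
                prec_chol = np.linalg.inv(base_chol)

            def stage_log_q(j, a, b, _pc=prec_chol):
                z = _pc @ (b - a)
                facj = stage_scale ** (j - 1)
                return (-0.5 * float(z @ z) / facj**2
                        - d * math.log(facj))

            log_alpha = dr_log_acceptance(points, log_pi, stage_log_q)
        if log_alpha >= 0 or (log_alpha > -np.inf
                              and rng.random() < math.exp(log_alpha)):
            state.set_position(cand, ll, lp)
            accepted = True
            break
    state.stage_counter = stage
    am_update(p, state.theta, accepted)
    return accepted


# ---------------------------------------------------------------------------
# MALA
# ---------------------------------------------------------------------------

class MalaState:
    """Adapted step size for the Langevin proposal."""

    __slots__ = ("log_eps", "iteration", "acceptance_count", "target_accept")

    def __init__(self, step_size: float = 0.1,
                 target_accept: float = TARGET_ACCEPT_MALA):
        self.log_eps = math.log(step_size)
        self.iteration = 0
        self.acceptance_count = 0
        self.target_accept = target_accept

    @property
    def step_size(self) -> float:
        return math.exp(self.log_eps)

    def adapt(self, accepted: bool) -> None:
        self.iteration += 1
        if accepted:
            self.acceptance_count += 1
        step = self.iteration ** (-ADAPT_DECAY)
        self.log_eps += step * ((1.0 if accepted else 0.0) - self.target_accept)


def _mala_cache(state: ChainState, target: Target):
    """(grad, metric Cholesky, log det metric) at the current position."""
    if state.mala is None:
        grad, fim = target.grad_fim(state.theta)
        if state.beta != 1.0:
            grad = grad / state.beta
            fim = fim / state.beta
        L = np.linalg.cholesky(fim)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        state.mala = (grad, L, logdet)
    return state.mala


def _mala_forward(theta, grad, L, eps):
    """Proposal mean theta + (eps^2/2) G^-1 grad using G = L L^T."""
    half = np.linalg.solve(L, grad)
    drift = np.linalg.solve(L.T, half)
    return theta + 0.5 * eps**2 * drift


def _mala_log_q(mean, L, logdet, eps, point):
    """log N(point; mean, eps^2 G^-1) up to the dimension constant."""
    z = L.T @ (point - mean) / eps
    d = point.size
    return 0.5 * logdet - d * math.log(eps) - 0.5 * float(z @ z)


def mala_step(state: ChainState, target: Target, rng: np.random.Generator,
              mala: MalaState) -> bool:
    """One Fisher-preconditioned MALA step with full asymmetric MH ratio."""
    eps = mala.step_size
    try:
        grad, L, logdet = _mala_cache(state, target)
    except (np.linalg.LinAlgError, RuntimeError):
        mala.adapt(False)
        return False
    mean_fwd = _mala_forward(state.theta, grad, L, eps)
    z = rng.standard_normal(state.theta.size)
    cand = mean_fwd + eps * np.linalg.solve(L.T, z)

    accepted = False
    if target.in_box(cand):
        ll = target.log_likelihood(cand)
        if math.isnan(ll):
            ll = -np.inf
        if ll > -np.inf:
            try:
                grad_c, fim_c = target.grad_fim(cand)
                if state.beta != 1.0:
                    grad_c = grad_c / state.beta
                    fim_c = fim_c / state.beta
                L_c = np.linalg.cholesky(fim_c)
                logdet_c = 2.0 * float(np.sum(np.log(np.diag(L_c))))
            except (np.linalg.LinAlgError, RuntimeError):
                L_c = None
            if L_c is not None:
                mean_rev = _mala_forward(cand, grad_c, L_c, eps)
                log_q_fwd = _mala_log_q(mean_fwd, L, logdet, eps, cand)
                log_q_rev = _mala_log_q(mean_rev, L_c, logdet_c, eps,
                                        state.theta)
                log_ratio = (ll / state.beta
                             - (state.log_target - state.log_prior)
                             + log_q_rev - log_q_fwd)
                if log_ratio >= 0 or rng.random() < math.exp(log_ratio):
                    state.set_position(cand, ll, 0.0)
                    state.mala = (grad_c, L_c, logdet_c)
                    accepted = True
    mala.adapt(accepted)
    return accepted


# ---------------------------------------------------------------------------
# Parallel tempering
# ---------------------------------------------------------------------------

@dataclass
class TemperatureLadder:
    """Inverse-temperature exponents beta_1 = 1 < ... < beta_L.

    Spacings adapt in log-difference space toward a target swap rate; with
    ``adaptive_count`` the hottest chain is dropped once the top spacing
    collapses (L decreases, never below 2).
    """

    betas: np.ndarray
    L0: int = 0
    adaptive_count: bool = False
    swap_strategy: str = "aa"
    target_swap_rate: float = TARGET_SWAP_RATE
    drop_threshold: float = 0.01
    beta_cap: float = 1e6  # upper clamp on a single adapted spacing
    iteration: int = 0
    swap_proposed: np.ndarray = field(default=None)  # type: ignore[assignment]
    swap_accepted: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas[0] != 1.0 or np.any(np.diff(self.betas) <= 0):
            raise ValueError("betas must start at 1 and increase strictly")
        if self.swap_strategy not in ("aa", "ee"):
            raise ValueError(f"unknown swap strategy {self.swap_strategy!r}")
        if not self.L0:
            self.L0 = self.betas.size
        if self.swap_proposed is None:
            self.swap_proposed = np.zeros(self.betas.size - 1, dtype=int)
            self.swap_accepted = np.zeros(self.betas.size - 1, dtype=int)

    @classmethod
    def geometric(cls, L0: int = 10, beta_max: float = 1e4,
                  **kwargs) -> "TemperatureLadder":
        if L0 == 1:
            return cls(np.array([1.0]), L0=1, **kwargs)
        return cls(np.geomspace(1.0, beta_max, L0), L0=L0, **kwargs)

    @property
    def L(self) -> int:
        return self.betas.size

    def adapt(self, pair_results: Sequence[tuple[int, bool]]) -> None:
        """Robbins-Monro update of the proposed pairs' log-spacings."""
        if self.L < 2 or not pair_results:
            return
        self.iteration += 1
        step = self.iteration ** (-ADAPT_DECAY)
        log_gaps = np.log(np.diff(self.betas))
        for pair, accepted in pair_results:
            self.swap_proposed[pair] += 1
            if accepted:
                self.swap_accepted[pair] += 1
            log_gaps[pair] += step * ((1.0 if accepted else 0.0)
                                      - self.target_swap_rate)
        # clamp spacings: once a chain is essentially at the prior the swap
        # rate no longer depends on the spacing, which would otherwise drift
        np.clip(log_gaps, np.log(1e-6), np.log(self.beta_cap), out=log_gaps)
        self.betas = np.concatenate([[1.0], 1.0 + np.cumsum(np.exp(log_gaps))])

    def should_drop_hottest(self) -> bool:
        if not self.adaptive_count or self.L <= 2:
            return False
        return (math.log(self.betas[-1]) - math.log(self.betas[-2])
                < self.drop_threshold)

    def drop_hottest(self) -> None:
        self.betas = self.betas[:-1]
        self.swap_proposed = self.swap_proposed[:-1]
        self.swap_accepted = self.swap_accepted[:-1]


def _swap_log_prob(state_l: ChainState, state_m: ChainState) -> float:
    return ((1.0 / state_l.beta - 1.0 / state_m.beta)
            * (state_m.log_lik - state_l.log_lik))


def pt_swap(states: Sequence[ChainState], ladder: TemperatureLadder,
            rng: np.random.Generator) -> list[tuple[int, bool]]:
    """Propose swaps between tempered chains; exchange positions on accept.

    ``aa`` proposes every adjacent pair in sequence; ``ee`` proposes the
    adjacent pair whose current log-likelihoods (energies) are closest.
    The swap of theta between levels l and m is accepted with probability
    min{1, exp[(1/beta_l - 1/beta_m)(log L_m - log L_l)]}.
    """
    if len(states) < 2:
        return []
    if ladder.swap_strategy == "aa":
        pairs = range(len(states) - 1)
    else:
        energies = np.array([s.log_lik for s in states])
        gaps = np.abs(np.diff(energies))
        gaps = np.where(np.isnan(gaps), np.inf, gaps)
        pairs = [int(np.argmin(gaps))]
    results = []
    for l in pairs:
        a, b = states[l], states[l + 1]
        log_p = _swap_log_prob(a, b)
        accepted = log_p >= 0 or rng.random() < math.exp(log_p)
        if accepted:
            theta_a, ll_a, lp_a = a.theta, a.log_lik, a.log_prior
            a.set_position(b.theta, b.log_lik, b.log_prior)
            b.set_position(theta_a, ll_a, lp_a)
        results.append((l, accepted))
    return results


def pt_step(states: list[ChainState], ladder: TemperatureLadder,
            target: Target, chain_rngs: Sequence[np.random.Generator],
            swap_rng: np.random.Generator,
            malas: Optional[Sequence[MalaState]] = None) -> bool:
    """One PT iteration: within-temperature steps, swaps, ladder adaptation.

    Returns the acceptance indicator of the untempered (beta = 1) chain's
    within-temperature step.  With an adaptive chain count the hottest
    chain is removed in place once its spacing collapses.
    """
    cold_accept = False
    for i, state in enumerate(states):
        if malas is not None:
            acc = mala_step(state, target, chain_rngs[i], malas[i])
        else:
            acc = am_chain_step(state, target, chain_rngs[i])
        if i == 0:
            cold_accept = acc
    results = pt_swap(states, ladder, swap_rng)
    ladder.adapt(results)
    for state, beta in zip(states, ladder.betas):
        state.set_beta(beta)
    if ladder.should_drop_hottest():
        ladder.drop_hottest()
        states.pop()
    return cold_accept


# ---------------------------------------------------------------------------
# Parallel hierarchical sampling
# ---------------------------------------------------------------------------

def phs_step(main: ChainState, auxiliaries: Sequence[ChainState],
             target: Target, aux_rngs: Sequence[np.random.Generator],
             swap_rng: np.random.Generator) -> int:
    """One PHS iteration: advance auxiliaries, then exchange with the main.

    Every auxiliary chain performs one AM('acc') step on the (untempered)
    posterior; the main chain then exchanges positions with one uniformly
    chosen auxiliary — the exchange is always accepted because all chains
    share the same stationary distribution.  Returns the chosen index.
    """
    if not auxiliaries:
        raise ValueError("PHS requires at least one auxiliary chain")
    for aux, rng in zip(auxiliaries, aux_rngs):
        am_chain_step(aux, target, rng)
    j = int(swap_rng.integers(len(auxiliaries)))
    aux = auxiliaries[j]
    theta_m, ll_m, lp_m = main.theta, main.log_lik, main.log_prior
    main.set_position(aux.theta, aux.log_lik, aux.log_prior)
    aux.set_position(theta_m, ll_m, lp_m)
    return j


# ---------------------------------------------------------------------------
# Run driver
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """Algorithm selection and tuning for :func:`run_sampler`."""

    algorithm: str = "am"
    scheme: str = "acc"  # 'dim' or 'acc' (AM); DRAM is 'dim' only
    n_tries: int = 2  # DRAM delayed-rejection stages
    step_size: float = 0.1  # MALA initial step size
    n_temperatures: int = 10  # PT initial ladder size L0
    beta_max: float = 1e4
    adaptive_count: bool = False  # PT: adaptive L <= L0 (default fixed L)
    swap_strategy: str = "aa"
    pt_kernel: str = "am"  # within-temperature kernel: 'am' or 'mala'
    n_aux: int = 4  # PHS auxiliary chains
    adapt_start: int = 100
    chol_interval: int = 25
    eps: Optional[float] = None  # proposal regularization; default from box

    def validate(self) -> None:
        if self.algorithm not in ("am", "dram", "mala", "pt", "phs"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "dram" and self.scheme != "dim":
            raise ValueError("DRAM supports only the 'dim' adaptation scheme")
        if self.algorithm == "am" and self.scheme not in ("dim", "acc"):
            raise ValueError(f"unknown adaptation scheme {self.scheme!r}")
        if self.pt_kernel not in ("am", "mala"):
            raise ValueError(f"unknown PT kernel {self.pt_kernel!r}")
        if self.algorithm == "phs" and self.n_aux < 1:
            raise ValueError("PHS requires at least one auxiliary chain")

    def settings_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "scheme": self.scheme,
            "n_tries": self.n_tries,
            "step_size": self.step_size,
            "n_temperatures": self.n_temperatures,
            "beta_max": self.beta_max,
            "adaptive_count": self.adaptive_count,
            "swap_strategy": self.swap_strategy,
            "pt_kernel": self.pt_kernel,
            "n_aux": self.n_aux,
        }


@dataclass
class SamplerRun:
    """One run's trace and bookkeeping (main / untempered chain only)."""

    trace: np.ndarray
    log_posterior_trace: np.ndarray
    cpu_seconds: float
    acceptance_rate: float
    algorithm: str
    settings: dict
    seed: int
    problem: str = ""
    scenario: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def n_iter(self) -> int:
        return self.trace.shape[0]


def default_eps(target: Target) -> float:
    """Proposal regularization 1e-8 * (mean prior range)^2."""
    return 1e-8 * float(np.mean(target.upper - target.lower)) ** 2


def _n_init_points(config: SamplerConfig) -> int:
    if config.algorithm == "pt":
        return config.n_temperatures
    if config.algorithm == "phs":
        return config.n_aux + 1
    return 1


def run_sampler(config: SamplerConfig, target: Target,
                init: np.ndarray, n_iter: int, seed: int,
                problem_name: str = "", scenario: str = "",
                init_cpu_seconds: float = 0.0) -> SamplerRun:
    """Execute one MCMC run and record the main chain.

    ``init`` is a single point for single-chain algorithms, L points for PT
    (cold chain first) or K+1 points for PHS (main chain first); a single
    point is broadcast where several are needed.  The run is fully
    reproducible from (config, seed).
    """
    config.validate()
    d = target.dim
    init = np.atleast_2d(np.asarray(init, dtype=float))
    needed = _n_init_points(config)
    if init.shape[0] == 1 and needed > 1:
        init = np.repeat(init, needed, axis=0)
    if init.shape[0] != needed or init.shape[1] != d:
        raise ValueError(
            f"init must supply {needed} point(s) of dimension {d}"
        )
    eps = config.eps if config.eps is not None else default_eps(target)
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(needed)
    swap_rng = np.random.default_rng(ss.spawn(1)[0])
    rngs = [np.random.default_rng(s) for s in chain_seeds]

    def make_proposal(scheme):
        return ProposalState(d, scheme=scheme, eps=eps,
                             adapt_start=config.adapt_start,
                             chol_interval=config.chol_interval)

    trace = np.empty((n_iter, d))
    logpost = np.empty(n_iter)
    extras: dict = {}
    t_start = time.process_time()

    if config.algorithm in ("am", "dram"):
        scheme = "dim" if config.algorithm == "dram" else config.scheme
        state = ChainState(init[0], target, make_proposal(scheme))
        rng = rngs[0]
        accepted = 0
        if config.algorithm == "am":
            for i in range(n_iter):
                accepted += am_chain_step(state, target, rng)
                trace[i] = state.theta
                logpost[i] = state.log_posterior()
        else:
            for i in range(n_iter):
                accepted += dram_step(state, target, rng,
                                      n_tries=config.n_tries)
                trace[i] = state.theta
                logpost[i] = state.log_posterior()
        acc_rate = accepted / n_iter

    elif config.algorithm == "mala":
        state = ChainState(init[0], target)
        mala = MalaState(config.step_size)
        rng = rngs[0]
        accepted = 0
        for i in range(n_iter):
            accepted += mala_step(state, target, rng, mala)
            trace[i] = state.theta
            logpost[i] = state.log_posterior()
        acc_rate = accepted / n_iter
        extras["final_step_size"] = mala.step_size

    elif config.algorithm == "pt":
        ladder = TemperatureLadder.geometric(
            config.n_temperatures, config.beta_max,
            adaptive_count=config.adaptive_count,
            swap_strategy=config.swap_strategy,
        )
        states = [ChainState(init[l], target, make_proposal("acc"),
                             beta=ladder.betas[l])
                  for l in range(ladder.L)]
        malas = ([MalaState(config.step_size) for _ in range(ladder.L)]
                 if config.pt_kernel == "mala" else None)
        accepted = 0
        for i in range(n_iter):
            accepted += pt_step(states, ladder, target, rngs, swap_rng,
                                malas)
            if malas is not None and len(malas) > len(states):
                del malas[len(states):]
            trace[i] = states[0].theta
            logpost[i] = states[0].log_posterior()
        acc_rate = accepted / n_iter
        extras["ladder"] = ladder.betas.copy()
        extras["swap_proposed"] = ladder.swap_proposed.copy()
        extras["swap_accepted"] = ladder.swap_accepted.copy()

    else:  # phs
        main = ChainState(init[0], target)
        auxiliaries = [ChainState(init[k + 1], target, make_proposal("acc"))
                       for k in range(config.n_aux)]
        aux_rngs = rngs[1:]
        swaps = 0
        for i in range(n_iter):
            phs_step(main, auxiliaries, target, aux_rngs, swap_rng)
            swaps += 1
            trace[i] = main.theta
            logpost[i] = main.log_posterior()
        acc_rate = (sum(a.proposal.acceptance_count for a in auxiliaries)
                    / max(1, sum(a.proposal.iteration for a in auxiliaries)))
        extras["swap_count"] = swaps

    cpu = time.process_time() - t_start + init_cpu_seconds
    return SamplerRun(
        trace=trace,
        log_posterior_trace=logpost,
        cpu_seconds=cpu,
        acceptance_rate=float(acc_rate),
        algorithm=config.algorithm,
        settings=config.settings_dict(),
        seed=seed,
        problem=problem_name,
        scenario=scenario,
        extras=extras,
    )
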