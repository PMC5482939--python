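"""Target distributions for the samplers.

A :class:`Target` bundles a box-constrained unnormalized density into the
minimal interface the samplers need: a cheap in-box test, a log-likelihood,
and (optionally, for Langevin proposals) a gradient and Fisher information.
:class:`PosteriorTarget` adapts a benchmark problem plus dataset;
:class:`GaussianTarget` and :class:`TwoStateTarget` are analytically
tractable references used to validate sampler stationarity.
"""

from __future__ import annotations

import math

import numpy as np

from odemcmc.models import BenchmarkProblem, Dataset, simulate
from odemcmc.posterior import gaussian_loglik, sensitivities

__all__ = ["Target", "PosteriorTarget", "GaussianTarget", "TwoStateTarget"]


class Target:
    """Box-constrained unnormalized target density.

    Subclasses set ``lower``/``upper`` and implement ``log_likelihood``;
    the prior is uniform on the box with its constant dropped.
    """

    lower: np.ndarray
    upper: np.ndarray

    @property
    def dim(self) -> int:
        return self.lower.size

    def in_box(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def log_prior(self, theta: np.ndarray) -> float:
        return 0.0 if self.in_box(theta) else -np.inf

    def log_likelihood(self, theta: np.ndarray) -> float:
        raise NotImplementedError

    def log_posterior(self, theta: np.ndarray) -> float:
        lp = self.log_prior(theta)
        if lp == -np.inf:
            return -np.inf
        return lp + self.log_likelihood(theta)

    def grad_fim(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gradient of the log-posterior and a positive-definite metric."""
        raise NotImplementedError(
            f"{type(self).__name__} does not provide derivatives"
        )


class PosteriorTarget(Target):
    """The posterior of a benchmark problem given a dataset.

    Evaluations are counted in ``n_evals`` (cost accounting hook).  When the
    model carries a closed-form solution it is called directly, bypassing
    the integrator dispatch in the hot loop.
    """

    def __init__(self, problem: BenchmarkProblem, data: Dataset):
        if data.n_y != problem.model.n_y:
            raise ValueError("dataset observable count does not match problem")
        self.problem = problem
        self.data = data
        self.lower = problem.theta_min
        self.upper = problem.theta_max
        self.n_evals = 0
        self._times = data.times
        self._obs = data.observations
        self._n_eta = problem.model.n_eta
        self._log10 = np.asarray(problem.model.log10_scale)
        self._any_log10 = bool(self._log10.any())
        self._solution = problem.model.solution
        self._obs_idx = list(problem.model.obs_indices)
        mask = np.isnan(self._obs)
        self._has_missing = bool(mask.any())
        self._counts = (~mask).sum(axis=0).astype(float)
        self._half_log_2pi = 0.5 * np.log(2.0 * np.pi)
        # single-observable, fully-observed problems get a scalar fast path
        self._scalar = (not self._has_missing and problem.model.n_y == 1
                        and self._solution is not None)
        if self._scalar:
            self._obs1 = np.ascontiguousarray(self._obs[:, 0])
            self._solution_obs = problem.model.solution_obs

    def log_likelihood(self, theta: np.ndarray) -> float:
        self.n_evals += 1
        theta = np.asarray(theta, dtype=float)
        if self._any_log10:
            nat = theta.copy()
            nat[self._log10] = 10.0 ** nat[self._log10]
        else:
            nat = theta
        eta, sigma = nat[: self._n_eta], nat[self._n_eta:]
        if self._scalar:
            s = sigma[0]
            if s <= 0:
                return -np.inf
            if self._solution_obs is not None:
                y = self._solution_obs(self._times, eta)
            else:
                y = self._solution(self._times, eta)[:, self._obs_idx[0]]
            resid = self._obs1 - y
            ss = float(resid @ resid)
            ll = (-self._counts[0] * (math.log(s) + self._half_log_2pi)
                  - 0.5 * ss / (s * s))
            return ll if math.isfinite(ll) else -np.inf
        if np.any(sigma <= 0):
            return -np.inf
        if self._solution is not None:
            states = self._solution(self._times, eta)
            y = states[:, self._obs_idx]
            if not np.all(np.isfinite(y)):
                return -np.inf
        else:
            sim = simulate(self.problem, theta, self._times)
            if not sim.success:
                return -np.inf
            y = sim.observables
        if self._has_missing:
            return gaussian_loglik(self._obs, y, sigma)
        resid = self._obs - y
        ss = np.einsum("ij,ij->j", resid, resid)
        return float(
            -np.sum(self._counts * (np.log(sigma) + self._half_log_2pi))
            - 0.5 * np.sum(ss / (sigma * sigma))
        )

    def grad_fim(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        res = sensitivities(self.problem, self.data, theta)
        return res.gradient, res.fim


class GaussianTarget(Target):
    """A multivariate normal density truncated to a (wide) box."""

    def __init__(self, mean, cov, lower=None, upper=None):
        self.mean = np.atleast_1d(np.asarray(mean, dtype=float))
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        self.cov = cov
        self.prec = np.linalg.inv(cov)
        sd = np.sqrt(np.diag(cov))
        self.lower = (np.asarray(lower, dtype=float) if lower is not None
                      else self.mean - 20.0 * sd)
        self.upper = (np.asarray(upper, dtype=float) if upper is not None
                      else self.mean + 20.0 * sd)

    def log_likelihood(self, theta: np.ndarray) -> float:
        r = np.asarray(theta, dtype=float) - self.mean
        return float(-0.5 * r @ self.prec @ r)

    def grad_fim(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        r = np.asarray(theta, dtype=float) - self.mean
        return -self.prec @ r, self.prec


class TwoStateTarget(Target):
    """A two-point target on {0, 1} with probabilities (p0, 1 - p0).

    Continuous coordinates are rounded to the nearest state, so the target
    composes with the generic Metropolis-Hastings kernel and a flip
    proposal; occupation fractions have an exact stationary reference.
    """

    def __init__(self, p0: float = 2.0 / 3.0):
        if not 0 < p0 < 1:
            raise ValueError("p0 must be in (0, 1)")
        self.p0 = p0
        self.lower = np.array([-0.5])
        self.upper = np.array([1.5])

    def log_likelihood(self, theta: np.ndarray) -> float:
        state = int(round(float(np.atleast_1d(theta)[0])))
        return float(np.log(self.p0 if state == 0 else 1.0 - self.p0))

    def grad_fim(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # piecewise-constant density: zero gradient almost everywhere
        return np.zeros(1), np.eye(1)

    @staticmethod
    def flip_proposal(rng: np.random.Generator, theta: np.ndarray):
        """Deterministic symmetric flip between the two states."""
        state = int(round(float(np.atleast_1d(theta)[0])))
        return np.array([1.0 - state]), 0.0

    @staticmethod
    def occupation(trace: np.ndarray) -> float:
        """Fraction of samples rounding to state 0."""
        return float(np.mean(np.round(np.asarray(trace).ravel()) == 0))
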