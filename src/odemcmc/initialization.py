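"""Chain starting points: prior draws (RND) and multi-start optimization (MS).

Multi-start initialization draws starting points from the prior, maximizes
the log-posterior locally from each with a bounded quasi-Newton method, and
initializes chains from the best optima: a single chain starts at the top
optimum, multi-chain configurations sample their starts uniformly from the
optima whose log-posterior lies within ``delta`` of the best.  The
optimization CPU time should be charged to the run when comparing
efficiency (the run driver accepts it as ``init_cpu_seconds``).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from odemcmc.models import BenchmarkProblem, Dataset
from odemcmc.posterior import log_posterior, sensitivities
from odemcmc.targets import PosteriorTarget

__all__ = [
    "MultistartResult",
    "StartRecord",
    "init_from_prior",
    "multistart_optimize",
    "init_from_multistart",
]


@dataclass
class StartRecord:
    theta0: np.ndarray
    theta_opt: np.ndarray
    log_post: float
    converged: bool
    n_iterations: int


@dataclass
class MultistartResult:
    """Local-optimization results sorted by final log-posterior, best first."""

    starts: list[StartRecord]
    cpu_seconds: float = 0.0

    @property
    def best(self) -> StartRecord:
        return self.starts[0]

    def distinct_optima(self, problem: BenchmarkProblem,
                        tol: float = 1e-4) -> list[StartRecord]:
        """Collapse duplicates at box-scaled theta distance below tol."""
        width = problem.theta_max - problem.theta_min
        kept: list[StartRecord] = []
        for rec in self.starts:
            if not np.isfinite(rec.log_post):
                continue
            if all(np.max(np.abs(rec.theta_opt - k.theta_opt) / width) >= tol
                   for k in kept):
                kept.append(rec)
        return kept

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "theta0": r.theta0.tolist(),
                    "theta_opt": r.theta_opt.tolist(),
                    "log_post": r.log_post,
                    "converged": r.converged,
                    "n_iterations": r.n_iterations,
                }
                for r in self.starts
            ],
            indent=2,
        )


def init_from_prior(problem: BenchmarkProblem, n_points: int,
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Independent uniform draws from the prior box, shape (n_points, n_theta)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.uniform(problem.theta_min, problem.theta_max,
                       size=(n_points, problem.n_theta))


def multistart_optimize(problem: BenchmarkProblem, data: Dataset,
                        n_starts: int = 100,
                        seed: Optional[int] = None,
                        max_iter: int = 1000,
                        gtol: float = 1e-6) -> MultistartResult:
    """Bounded local maximization of the log-posterior from prior draws.

    Each start runs L-BFGS-B with the analytic gradient from the forward
    sensitivities; individual failures are recorded, only all-failed runs
    raise.  Results are returned sorted by final log-posterior.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    t0 = time.process_time()
    rng = np.random.default_rng(seed)
    starts = init_from_prior(problem, n_starts, rng=rng)
    target = PosteriorTarget(problem, data)
    bounds = list(zip(problem.theta_min, problem.theta_max))
    # stay strictly inside the box so the solver and sensitivities are defined
    margin = 1e-10 * (problem.theta_max - problem.theta_min)

    def neg_log_post(theta):
        val = target.log_posterior(theta)
        return -val if np.isfinite(val) else 1e100

    def neg_grad(theta):
        try:
            return -sensitivities(problem, data, theta).gradient
        except (RuntimeError, ValueError):
            return np.zeros(problem.n_theta)

    records = []
    for theta0 in starts:
        x0 = np.clip(theta0, problem.theta_min + margin,
                     problem.theta_max - margin)
        try:
            res = minimize(neg_log_post, x0, jac=neg_grad, method="L-BFGS-B",
                           bounds=bounds,
                           options={"maxiter": max_iter, "gtol": gtol})
            theta_opt = np.clip(res.x, problem.theta_min, problem.theta_max)
            lp = float(log_posterior(problem, data, theta_opt).log_posterior)
            records.append(StartRecord(theta0, theta_opt, lp,
                                       bool(res.success), int(res.nit)))
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            records.append(StartRecord(theta0, theta0, -np.inf, False, 0))
    if all(not np.isfinite(r.log_post) for r in records):
        raise RuntimeError("all multistart optimizations failed")
    records.sort(key=lambda r: -r.log_post)
    return MultistartResult(records, cpu_seconds=time.process_time() - t0)


def init_from_multistart(ms: MultistartResult, n_chains: int,
                         problem: Optional[BenchmarkProblem] = None,
                         delta: float = 10.0,
                         seed: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Starting points from the filtered multistart optima.

    A single chain starts at the best optimum.  For multiple chains, optima
    with log-posterior within ``delta`` of the best are retained (after
    duplicate collapsing when the problem is supplied for scaling) and
    ``n_chains`` starts are drawn uniformly with replacement.
    """
    if not ms.starts:
        raise ValueError("empty multistart result")
    if n_chains == 1:
        return ms.best.theta_opt[None, :].copy()
    optima = (ms.distinct_optima(problem) if problem is not None
              else [r for r in ms.starts if np.isfinite(r.log_post)])
    best_lp = optima[0].log_post
    retained = [r for r in optima if r.log_post >= best_lp - delta]
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(len(retained), size=n_chains)
    return np.array([retained[i].theta_opt for i in idx])
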