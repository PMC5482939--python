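"""Scenario bookkeeping: repeated runs of algorithm/setting combinations.

A *scenario* is one combination of sampling algorithm, tuning settings and
initialization scheme; a study repeats every scenario ``n_runs`` times on
the same dataset.  Run seeds derive deterministically from (master seed,
scenario index, run index), so any single run can be reproduced in
isolation.  Multi-start initialization is performed per run (with its own
derived seed) and its CPU time is charged to the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from odemcmc.initialization import (
    init_from_multistart,
    init_from_prior,
    multistart_optimize,
)
from odemcmc.models import BenchmarkProblem, Dataset
from odemcmc.samplers import SamplerConfig, SamplerRun, run_sampler
from odemcmc.targets import PosteriorTarget

__all__ = ["ScenarioSpec", "run_scenario", "run_study", "derive_seed"]


@dataclass
class ScenarioSpec:
    """One algorithm + settings + initialization combination."""

    name: str
    config: SamplerConfig
    init: str = "rnd"  # 'rnd' (prior draws) or 'ms' (multi-start optima)
    n_runs: int = 100
    n_iter: int = 1_000_000
    ms_n_starts: int = 100
    ms_delta: float = 10.0

    def __post_init__(self):
        if self.init not in ("rnd", "ms"):
            raise ValueError(f"unknown initialization scheme {self.init!r}")
        self.config.validate()


def derive_seed(master_seed: int, scenario_index: int, run_index: int,
                salt: int = 0) -> int:
    """Deterministic sub-seed below 2^31 for one run (or its helper)."""
    ss = np.random.SeedSequence([master_seed, scenario_index, run_index, salt])
    return int(ss.generate_state(1)[0] % (2**31))


def _n_init_points(config: SamplerConfig) -> int:
    if config.algorithm == "pt":
        return config.n_temperatures
    if config.algorithm == "phs":
        return config.n_aux + 1
    return 1


def prepare_init(problem: BenchmarkProblem, data: Dataset,
                 spec: ScenarioSpec, seed: int) -> tuple[np.ndarray, float]:
    """Starting points and the CPU seconds spent producing them."""
    n_points = _n_init_points(spec.config)
    if spec.init == "rnd":
        return init_from_prior(problem, n_points, seed=seed), 0.0
    ms = multistart_optimize(problem, data, n_starts=spec.ms_n_starts,
                             seed=seed)
    pts = init_from_multistart(ms, n_points, problem=problem,
                               delta=spec.ms_delta, seed=seed + 1)
    return pts, ms.cpu_seconds


def run_scenario(problem: BenchmarkProblem, data: Dataset, spec: ScenarioSpec,
                 master_seed: int, scenario_index: int = 0,
                 run_indices: Optional[Sequence[int]] = None
                 ) -> list[SamplerRun]:
    """Execute (a subset of) one scenario's runs."""
    target = PosteriorTarget(problem, data)
    runs = []
    indices = range(spec.n_runs) if run_indices is None else run_indices
    for r in indices:
        seed = derive_seed(master_seed, scenario_index, r)
        init, init_cpu = prepare_init(problem, data, spec,
                                      derive_seed(master_seed, scenario_index,
                                                  r, salt=1))
        runs.append(run_sampler(spec.config, target, init, spec.n_iter, seed,
                                problem_name=problem.name, scenario=spec.name,
                                init_cpu_seconds=init_cpu))
    return runs


def run_study(problem: BenchmarkProblem, data: Dataset,
              scenarios: Sequence[ScenarioSpec],
              master_seed: int) -> list[SamplerRun]:
    """Execute all scenarios sequentially and return all runs."""
    runs: list[SamplerRun] = []
    for idx, spec in enumerate(scenarios):
        runs.extend(run_scenario(problem, data, spec, master_seed, idx))
    return runs


def reference_scenarios(n_runs: int = 20, n_iter: int = 50_000,
                        ms_n_starts: int = 20) -> list[ScenarioSpec]:
    """The package's reference scenario set for uni-modal benchmarks.

    Three scenarios spanning the method families: single-chain adaptive
    Metropolis with acceptance-rate scaling and prior initialization,
    parallel tempering with a fixed ladder of five temperatures, and
    parallel hierarchical sampling with four auxiliary chains initialized
    from multi-start optima.  Run counts and iteration numbers are sized
    for a desk-scale study.
    """
    return [
        ScenarioSpec("AM-acc-rnd",
                     SamplerConfig(algorithm="am", scheme="acc"),
                     init="rnd", n_runs=n_runs, n_iter=n_iter),
        ScenarioSpec("PT-L5-rnd",
                     SamplerConfig(algorithm="pt", n_temperatures=5),
                     init="rnd", n_runs=n_runs, n_iter=n_iter),
        ScenarioSpec("PHS-ms",
                     SamplerConfig(algorithm="phs", n_aux=4),
                     init="ms", n_runs=n_runs, n_iter=n_iter,
                     ms_n_starts=ms_n_starts),
    ]
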