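"""Semi-automatic comparison pipeline for populations of MCMC runs.

Given all runs of one benchmark across scenarios the pipeline (i) removes
each run's burn-in, (ii) groups runs by pairwise similarity — two runs are
similar when both the two-chain Gelman-Rubin-Brooks diagnostic and the
between-run Geweke mean test pass — with groups as connected components of
the similarity graph, (iii) marks groups below a minimum size fraction as
neglected, (iv) scores exploration: a retained group is well-exploring
when it covers every other retained group's high-posterior region (best
log-posterior within ``delta_mode``) and tails (its pooled [1%, 99%]
sample interval contains the other group's pooled [5%, 95%] interval, per
parameter).  A scenario's exploration quality EQ is the fraction of its
runs that belong to well-exploring groups.  Effective sample sizes are
only credited to converged runs in well-exploring retained groups — all
other runs count zero, so that fast-but-wrong runs cannot dominate the
ESS-per-CPU-second efficiency, which is additionally multiplied by EQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from odemcmc.diagnostics import (
    effective_sample_size,
    estimate_burnin,
    geweke_between,
    grb_diagnostic,
    spectral_variance,
)
from odemcmc.samplers import SamplerRun
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupingResult",
    "ExplorationResult",
    "RunAnalysis",
    "StudySummary",
    "pairwise_similarity",
    "group_runs",
    "assess_exploration",
    "conditioned_efficiency",
    "summarize_study",
]

MPSRF_THRESHOLD = 1.1
SIMILARITY_ALPHA = 0.05
MIN_GROUP_FRACTION = 0.05
DELTA_MODE = 5.0
TAIL_OUTER = (0.01, 0.99)
TAIL_INNER = (0.05, 0.95)


@dataclass
class GroupingResult:
    """Partition of runs into similarity groups (connected components)."""

    labels: np.ndarray  # group label per run
    pass_matrix: np.ndarray  # symmetric pairwise pass/fail
    min_count: int  # groups below this size are neglected
    neglected: set = field(default_factory=set)

    @property
    def group_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def retained_groups(self) -> list[int]:
        return [g for g, size in self.group_sizes.items()
                if g not in self.neglected]

    def members(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.labels == group)


@dataclass
class ExplorationResult:
    well_exploring: dict[int, bool]  # per retained group
    eq: dict[str, float]  # per scenario
    coverage: dict[tuple[int, int], bool]
    no_retained_groups: bool = False


@dataclass
class RunAnalysis:
    run: SamplerRun
    n_burn_in: int
    converged: bool
    ess: float = 0.0
    tau: float = np.inf
    ess_per_second: float = 0.0
    conditioned_ess_per_second: float = 0.0
    group: int = -1

    @property
    def scenario(self) -> str:
        return self.run.scenario


@dataclass
class StudySummary:
    table: pd.DataFrame
    grouping: GroupingResult
    exploration: ExplorationResult
    runs: list[RunAnalysis]


# ---------------------------------------------------------------------------
# Pairwise similarity and grouping
# ---------------------------------------------------------------------------

class _RunSummary:
    """Cached per-run statistics for O(pairs) similarity testing."""

    __slots__ = ("mean", "sv", "cov", "n")

    def __init__(self, trace: np.ndarray):
        trace = np.atleast_2d(np.asarray(trace, dtype=float).T).T
        self.n = trace.shape[0]
        self.mean = trace.mean(axis=0)
        self.sv = np.array([spectral_variance(trace[:, j])
                            for j in range(trace.shape[1])])
        self.cov = np.atleast_2d(np.cov(trace.T, ddof=1))


def _similar(a: _RunSummary, b: _RunSummary,
             mpsrf_threshold: float, alpha: float) -> bool:
    # two-chain Gelman-Rubin-Brooks on cached moments
    W = 0.5 * (a.cov + b.cov)
    diff = a.mean - b.mean
    B_over_n = 0.5 * np.outer(diff, diff)
    n, m = a.n, 2
    try:
        lam = np.max(np.real(np.linalg.eigvals(np.linalg.solve(W, B_over_n))))
    except np.linalg.LinAlgError:
        return False
    mpsrf = np.sqrt((n - 1) / n + (m + 1) / m * max(lam, 0.0))
    if not mpsrf < mpsrf_threshold:
        return False
    # between-run Geweke mean test, Holm-corrected across parameters
    denom = np.sqrt(a.sv + b.sv)
    if np.any(denom == 0):
        return False
    from scipy import stats

    p = 2.0 * stats.norm.sf(np.abs(diff) / denom)
    return not multipletests(p, alpha=alpha, method="holm")[0].any()


def pairwise_similarity(run_a: np.ndarray, run_b: np.ndarray,
                        mpsrf_threshold: float = MPSRF_THRESHOLD,
                        alpha: float = SIMILARITY_ALPHA) -> bool:
    """Are two post-burn-in traces statistically similar?

    Both runs are truncated to their common (shorter) length; the pair
    passes when the two-chain mpsrf stays below ``mpsrf_threshold`` AND the
    between-run Geweke comparison raises no Holm-corrected rejection.
    """
    a = np.atleast_2d(np.asarray(run_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(run_b, dtype=float).T).T
    n = min(a.shape[0], b.shape[0])
    a, b = a[-n:], b[-n:]
    try:
        grb = grb_diagnostic([a, b])
    except ValueError:
        return False
    if not grb.mpsrf < mpsrf_threshold:
        return False
    try:
        gw = geweke_between(a, b)
    except ValueError:
        return False
    return not multipletests(gw.p, alpha=alpha, method="holm")[0].any()


def group_runs(traces: Sequence[np.ndarray],
               min_fraction: float = MIN_GROUP_FRACTION,
               mpsrf_threshold: float = MPSRF_THRESHOLD,
               alpha: float = SIMILARITY_ALPHA) -> GroupingResult:
    """Partition runs into similarity groups by transitive closure.

    All traces are truncated to the common shortest length; per-run moments
    are cached so the all-pairs similarity tests cost O(n_runs^2) cheap
    comparisons.  Groups smaller than ``min_fraction`` of all runs are
    marked neglected.
    """
    n_runs = len(traces)
    if n_runs < 2:
        raise ValueError("grouping requires at least two runs")
    n_common = min(np.atleast_2d(np.asarray(t, dtype=float).T).T.shape[0]
                   for t in traces)
    summaries = [_RunSummary(np.atleast_2d(np.asarray(t, dtype=float).T)
                             .T[-n_common:]) for t in traces]

    pass_matrix = np.eye(n_runs, dtype=bool)
    parent = np.arange(n_runs)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_runs):
        for j in range(i + 1, n_runs):
            if _similar(summaries[i], summaries[j], mpsrf_threshold, alpha):
                pass_matrix[i, j] = pass_matrix[j, i] = True
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    labels = np.array([find(i) for i in range(n_runs)])
    # relabel compactly in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)

    min_count = int(np.ceil(min_fraction * n_runs))
    sizes = np.bincount(labels)
    neglected = {g for g in range(sizes.size) if sizes[g] < min_count}
    return GroupingResult(labels=labels, pass_matrix=pass_matrix,
                          min_count=min_count, neglected=neglected)


# ---------------------------------------------------------------------------
# Exploration quality
# ---------------------------------------------------------------------------

def assess_exploration(grouping: GroupingResult,
                       post_traces: Sequence[np.ndarray],
                       post_logposts: Sequence[np.ndarray],
                       scenarios: Sequence[str],
                       delta_mode: float = DELTA_MODE,
                       tail_outer: tuple = TAIL_OUTER,
                       tail_inner: tuple = TAIL_INNER) -> ExplorationResult:
    """Flag well-exploring groups and compute per-scenario EQ.

    Group G covers group H when G's best post-burn-in log-posterior is
    within ``delta_mode`` of H's best AND, per parameter, G's pooled
    [1%, 99%] interval contains H's pooled [5%, 95%] interval.  G is
    well-exploring when it covers every other retained group.  EQ of a
    scenario is the fraction of its runs lying in well-exploring groups.
    """
    scenarios = list(scenarios)
    retained = grouping.retained_groups()
    if not retained:
        return ExplorationResult(
            well_exploring={}, coverage={},
            eq={s: 0.0 for s in dict.fromkeys(scenarios)},
            no_retained_groups=True,
        )

    best_lp: dict[int, float] = {}
    outer_q: dict[int, np.ndarray] = {}
    inner_q: dict[int, np.ndarray] = {}
    for g in retained:
        members = grouping.members(g)
        pooled = np.vstack([np.atleast_2d(np.asarray(post_traces[i]).T).T
                            for i in members])
        best_lp[g] = max(float(np.max(post_logposts[i])) for i in members)
        outer_q[g] = np.quantile(pooled, tail_outer, axis=0)
        inner_q[g] = np.quantile(pooled, tail_inner, axis=0)

    coverage: dict[tuple[int, int], bool] = {}
    for g in retained:
        for h in retained:
            if g == h:
                coverage[(g, h)] = True
                continue
            mode_ok = best_lp[g] >= best_lp[h] - delta_mode
            tails_ok = bool(
                np.all(outer_q[g][0] <= inner_q[h][0])
                and np.all(outer_q[g][1] >= inner_q[h][1])
            )
            coverage[(g, h)] = mode_ok and tails_ok
    well = {g: all(coverage[(g, h)] for h in retained) for g in retained}

    eq: dict[str, float] = {}
    scen_arr = np.asarray(scenarios)
    good_runs = np.zeros(len(scenarios), dtype=bool)
    for g, ok in well.items():
        if ok:
            good_runs[grouping.members(g)] = True
    for s in dict.fromkeys(scenarios):
        mask = scen_arr == s
        eq[s] = float(good_runs[mask].mean()) if mask.any() else 0.0
    return ExplorationResult(well_exploring=well, eq=eq, coverage=coverage)


def conditioned_efficiency(ess: float, cpu_seconds: float, eq: float) -> float:
    """EQ-weighted effective samples per CPU second: (ess/s) * EQ."""
    if cpu_seconds <= 0:
        raise ValueError("cpu_seconds must be positive")
    return ess / cpu_seconds * eq


# ---------------------------------------------------------------------------
# End-to-end study summary
# ---------------------------------------------------------------------------

def summarize_study(runs: Sequence[SamplerRun],
                    burnin_alpha: float = 0.05,
                    min_fraction: float = MIN_GROUP_FRACTION,
                    mpsrf_threshold: float = MPSRF_THRESHOLD,
                    alpha: float = SIMILARITY_ALPHA,
                    delta_mode: float = DELTA_MODE) -> StudySummary:
    """Run the full pipeline over all runs of one benchmark.

    Burn-in is removed per run; non-converged runs still take part in the
    grouping (contributing their second half, so they can form their own —
    typically neglected — groups) but are credited an ESS of zero, as are
    runs outside well-exploring retained groups.
    """
    analyses: list[RunAnalysis] = []
    post_traces, post_logposts = [], []
    for run in runs:
        bi = estimate_burnin(run.trace, alpha=burnin_alpha)
        start = bi.n_burn_in if bi.converged else run.n_iter // 2
        analyses.append(RunAnalysis(run=run, n_burn_in=bi.n_burn_in,
                                    converged=bi.converged))
        post_traces.append(run.trace[start:])
        post_logposts.append(run.log_posterior_trace[start:])

    grouping = group_runs(post_traces, min_fraction=min_fraction,
                          mpsrf_threshold=mpsrf_threshold, alpha=alpha)
    scenarios = [a.scenario for a in analyses]
    exploration = assess_exploration(grouping, post_traces, post_logposts,
                                     scenarios, delta_mode=delta_mode)

    retained_well = {g for g, ok in exploration.well_exploring.items() if ok}
    for i, a in enumerate(analyses):
        a.group = int(grouping.labels[i])
        eq = exploration.eq[a.scenario]
        if a.converged and a.group in retained_well:
            ess, tau, _ = effective_sample_size(post_traces[i])
            a.ess, a.tau = float(ess), float(tau)
        else:
            a.ess, a.tau = 0.0, np.inf
        if a.run.cpu_seconds > 0:
            a.ess_per_second = a.ess / a.run.cpu_seconds
            a.conditioned_ess_per_second = conditioned_efficiency(
                a.ess, a.run.cpu_seconds, eq)

    rows = []
    for s in dict.fromkeys(scenarios):
        sub = [a for a in analyses if a.scenario == s]
        rows.append({
            "scenario": s,
            "n_runs": len(sub),
            "eq": exploration.eq[s],
            "median_ess": float(np.median([a.ess for a in sub])),
            "median_ess_per_s": float(np.median([a.ess_per_second
                                                 for a in sub])),
            "median_conditioned_ess_per_s": float(
                np.median([a.conditioned_ess_per_second for a in sub])),
            "n_converged": sum(a.converged for a in sub),
        })
    table = pd.DataFrame(rows)
    return StudySummary(table=table, grouping=grouping,
                        exploration=exploration, runs=analyses)
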