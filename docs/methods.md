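# Methods

## Problem setting

`odemcmc` targets Bayesian parameter estimation for ODE models of
biological processes.  A model

    x' = f(x, t, eta),   x(t0) = x0(eta),   y = h(x, t, eta)

is observed at n_t time points through independent additive Gaussian noise
with per-observable standard deviations sigma_i, which are estimated
jointly with the dynamic parameters: theta = (eta, sigma).  The prior is
uniform on a box [theta_min, theta_max]; its normalization constant is
dropped, so reported log-posterior values are comparable within a problem
but not across problems.  The marginal likelihood is never computed — all
samplers work with the unnormalized posterior.

## Benchmark problems

Seven built-in problems (M1a, M1b, M2–M6) cover uni-modal, bimodal and
strongly multi-modal posteriors:

| name | system | n_theta | scale | notes |
|------|--------|---------|-------|-------|
| M1a/M1b | mRNA transfection (2 states, protein observed) | 5 | log10 | beta/delta exchange symmetry makes the posterior bimodal; M1a is the experimental-data design (no generating truth stored) |
| M2 | bistable mass-action switch (2 states) | 8 | linear | bistability creates a steep posterior rim |
| M3 | saturated growth x' = b1 − b2 x | 3 | linear | banana-shaped correlated posterior |
| M4 | 3-species mass-action chain | 11 | linear | oscillatory/Hopf-capable regime |
| M5 | driven Van der Pol oscillator | 9 | linear | chaotic; drive embedded as phase state x3 with x3' = omega |
| M6 | Lorenz system | 9 | linear | chaotic |

Prior boxes, generating parameters, n_t and measurement windows are part
of each problem definition and are frozen in `models.py`.  For M1 only the product
kTL·m0 is identifiable and is stored as a single parameter; states are zero
before the transfection time t0, which is itself estimated.

The M2 and M4–M5 right-hand sides are package defaults written from
verbal descriptions of the underlying systems: M2 uses the
smallest-bistable-network reaction scheme, M4 a logistic-prey mass-action
trophic chain (the sketchier unlimited-growth variant diverges at the
generating parameters), M5 a cosine drive with x0_3 read as the initial
drive phase.  Every RHS is pluggable (`BenchmarkProblem.with_rhs`), so an
alternative published form can be substituted without touching anything
else.

M1 and M3 are linear and carry closed-form solutions which `simulate` uses
by default; the test suite pins them against the numerical integrator
(LSODA, rtol 1e-8 / atol 1e-10) to 1e-6 relative error.  This matters
because a likelihood evaluation through the closed form costs microseconds,
which is what makes desk-scale sampling studies (millions of posterior
evaluations) practical.  Integration failures are flagged and consumed
downstream as log-posterior = −inf, never as partial trajectories.

## Likelihood, gradient, Fisher information

The Gaussian likelihood skips missing observations (NaN) element-wise.
Gradients and the Fisher information come from observable sensitivities
s_ik = dy_i(t_k)/deta: central differences on the closed-form trajectory
where one exists (relative step 1e-6), otherwise the augmented forward
sensitivity system S' = f_x S + f_eta integrated jointly with the states,
with the Jacobians of f formed by central differences.  The FIM is the
Gram matrix sum s s^T/sigma_i² for the dynamic block plus diag(2 n_i /
sigma_i²) for the noise block (cross terms vanish for Gaussian noise),
chain-ruled through the log10 reparameterization where applicable,
symmetrized, and ridge-regularized with 1e-8·max(diag); a condition number
above 1e12 before regularization raises a flag.  The expected (Fisher)
information including the noise block is used as the MALA metric.

## Samplers

All samplers share the Metropolis-Hastings kernel; proposals falling
outside the prior box are rejected without evaluating the likelihood but
still count as proposals for acceptance-rate purposes (such runs are cheap,
which is exactly what the exploration-conditioned efficiency measure is
designed to penalize).

* **AM** — adaptive Metropolis.  The empirical covariance is tracked by a
  Welford recursion (exactly the batch covariance at every step) and
  regularized with eps·I, eps = 1e-8·(mean prior range)²; before 100
  samples have accrued the proposal is eps·I.  Scaling is either
  `dim` (2.38²/d) or `acc` (a scalar exp(log-scale) adapted toward 23.4%
  acceptance with Robbins-Monro steps i^(−0.51)).  The proposal Cholesky
  factor is refreshed every 25 iterations — adaptation is diminishing, so
  the staleness is bounded and shrinking; the scalar scale is applied
  per step.
* **DRAM** — AM with `dim` scaling plus delayed rejection: stage j+1
  proposes from the current point with the stage covariance scaled by
  1/25 per stage (standard deviation /5), up to 2 tries by default.  The
  acceptance probability uses the full reversibility-preserving recursion
  (`dr_log_acceptance`), verified against the hand-evaluated two-stage
  formula.
* **MALA** — Langevin proposal with mean theta + (eps²/2) G⁻¹ grad and
  covariance eps² G⁻¹, full asymmetric MH correction with the metric
  re-evaluated at the proposal; step size adapted toward 57.4% acceptance.
* **PT** — parallel tempering of p(theta)·L(theta)^(1/beta_l) on a ladder
  beta_1 = 1 < … < beta_L, initialized geometrically up to beta = 1e4
  (L0 = 10 by default; fixed L is the default, adaptive L ≤ L0 optional).
  Within-temperature kernels are AM(acc) (or MALA).  Swap strategies: `aa`
  proposes every adjacent pair each iteration, `ee` the adjacent pair with
  the closest log-likelihoods.  Ladder spacings adapt in log-difference
  space toward a 23% swap rate with i^(−0.51) steps, clamped to
  [log 1e-6, log 1e6]: hot chains sampling essentially from the prior
  accept swaps regardless of spacing, so an unclamped Robbins-Monro drift
  would diverge.  With adaptive L the hottest chain is dropped when the top
  log-spacing falls below 0.01 (never below L = 2).
* **PHS** — parallel hierarchical sampling: K auxiliary chains (default 4)
  each take one AM(acc) step on the untempered posterior, then the main
  chain exchanges states with one uniformly chosen auxiliary,
  unconditionally (all chains share the same stationary distribution, so
  the exchange is always valid).

Randomness: a master seed spawns one stream per chain plus a dedicated
swap stream, so within-chain sequences are invariant to swap outcomes and
every run is bit-reproducible from (config, seed).

Stationarity of every variant is validated against two references: a
two-point target embedded by rounding (unit-width support per state, so
the discrete occupation is an exact marginal; MALA runs with the
a.e.-zero gradient) and a correlated 2-d Gaussian (rho = 0.9).

## Initialization

`rnd` draws starting points uniformly from the prior box.  `ms` runs
multi-start local optimization (L-BFGS-B on the negative log-posterior
with analytic sensitivities; default 100 starts, 1000 iterations, gradient
tolerance 1e-6), collapses duplicate optima at box-scaled distance 1e-4,
keeps optima within delta = 10 log-units of the best, and samples chain
starts uniformly with replacement (a single chain starts at the best
optimum).  Optimization CPU time is charged to the run so that
ESS-per-second comparisons include the initialization overhead.

## Analysis pipeline

* **Burn-in** — a sequence of Geweke tests on 20 equispaced truncation
  candidates (0%, 5%, …, 95%); segment fractions 10%/50% (the classical
  choice).  Per-parameter p-values are Holm-corrected
  at alpha = 0.05; the first candidate with no rejection ends burn-in, and
  a chain that never passes is flagged non-converged (burn-in = whole
  chain).  Segment-mean variances use the zero-frequency spectral density
  estimated through the adaptively truncated autocorrelation sum.
* **Similarity grouping** — all post-burn-in traces (non-converged runs
  contribute their second half) truncated to the common shortest length;
  a pair of runs is similar when the two-chain multivariate
  Gelman-Rubin-Brooks factor is below 1.1 AND the between-run Geweke mean
  comparison raises no Holm-corrected rejection at 0.05.  Groups are the
  connected components of the similarity graph; groups below 5% of all
  runs are neglected.
* **Exploration quality** — a retained group covers another when its best
  log-posterior is within 5 log-units of the other's AND, per parameter,
  its pooled [1%, 99%] interval contains the other's pooled [5%, 95%]
  interval (marginal tail check; a joint variant would be stricter but the
  marginal one matches the per-parameter reporting).  A group exploring
  well covers all other retained groups; a scenario's EQ is the fraction
  of its runs in well-exploring groups.
* **ESS** — Sokal's adaptively truncated autocorrelation-time estimator
  (window constant c = 6, FFT autocorrelation, tau floored at 1); the ESS
  of a trace is N / max_i tau_i.  Only converged runs inside
  well-exploring retained groups are credited; all others count ESS = 0,
  and efficiency is reported as (ESS/s)·EQ so that fast-but-wrong runs
  cannot dominate.

All thresholds (mpsrf 1.1, alpha 0.05, delta_mode 5, quantile pairs, 5%
group filter) are exposed as keyword arguments and surfaced in reports.

## Scaled study sizes

A full-scale comparison of this kind (tens of scenarios × 100 runs ×
1e6 iterations per benchmark) costs hundreds of thousands of CPU hours;
the study machinery supports those sizes, but the package's reference
study (`reference_scenarios`) is sized for a desk-scale uni-modal
headline experiment:
3 scenarios {AM(acc)+RND, PT(fixed L = 5)+RND, PHS(4 aux)+MS}, 20 runs
each, 5e4 iterations, on M3 data generated at the true parameters.  At
this scale the pipeline reproduces the qualitative pattern — multi-chain
methods reach EQ = 1, single-chain AM runs partially fail to converge or
land in banana-tail groups — and an average EQ well above one half.
Multi-start initialization inside the study uses 20 starts per run (the
module default of 100 is unnecessary for a 3-parameter posterior).

## What the synthetic data does and does not emulate

`generate_data` reproduces the published simulated-data design exactly:
equidistant sampling, additive homoscedastic Gaussian noise at the true
sigma, all observables fully observed.  Real datasets (e.g. the
experimental M1a data, importable as CSV) additionally feature
heteroscedastic noise, missing values and model misfit; the likelihood and
pipeline handle missing values, but passing tests on synthetic data says
nothing about model misspecification, and EQ statements transfer only
qualitatively.

## Numerical choices and degenerate inputs

Solver tolerances default to rtol 1e-8 / atol 1e-10 (LSODA); determinism
holds at fixed tolerances, which for the chaotic problems (M5, M6) is the
only meaningful reproducibility contract.  Degenerate cases are defined
explicitly: a constant series has zero spectral variance and no
autocorrelation time; identical chains give B = 0 and psrf =
sqrt((n−1)/n); empty prior boxes are rejected at construction; NaN target
values are treated as −inf and rejected; the prior box is closed (boundary
values have prior density).

## Known limitations

* Pipeline conventions without a single canonical value in the
  literature (Geweke segment fractions, burn-in candidate grid,
  similarity thresholds, the MS filter width) use classical defaults and
  are exposed as configuration knobs.
* M2/M4/M5 right-hand sides are labeled package defaults, pluggable.
* No HMC/NUTS/SMC samplers, no marginal-likelihood estimation, no
  structural-identifiability analysis, no SDE/PDE models.
* Chains run serially; CPU seconds are summed across chains of a
  multi-chain run.
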