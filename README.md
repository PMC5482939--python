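# odemcmc

MCMC samplers, benchmark ODE inference problems and chain-quality
analysis for Bayesian parameter estimation in dynamical systems.

## The problem

Parameters of ODE models in systems biology — reaction rates, initial
concentrations, noise levels — are estimated from sparse, noisy
time-series data.  Bayesian inference targets the posterior

    p(theta | D)  ∝  p(D | theta) p(theta),
    p(D | theta)  =  prod_{i,k} N(y~_ik ; y_i(t_k; eta), sigma_i^2),

with theta = (eta, sigma), a uniform box prior, and y(t) the solution of
x' = f(x, t, eta) observed through an output map.  Such posteriors are
routinely multi-modal (non-identifiabilities, bistability, chaos) with
heavy, curved tails, and the practical question for the modeler is which
MCMC sampler, initialization and tuning will actually explore them in a
finite number of iterations.  `odemcmc` provides the ingredients for
answering that question quantitatively:

* **Benchmark problems** M1a/M1b (mRNA transfection, bimodal by a
  degradation-rate exchange symmetry), M2 (bistable switch), M3
  (saturated growth, banana-shaped), M4 (Hopf-capable reaction network),
  M5 (driven Van der Pol, chaotic), M6 (Lorenz, chaotic) — with prior
  boxes, generating parameters, measurement designs and simulated-data
  generation built in.
* **Samplers**: adaptive Metropolis (dimension- or acceptance-rate-based
  proposal scaling), delayed rejection adaptive Metropolis, Fisher-
  preconditioned MALA, parallel tempering (adaptive temperature ladder,
  all-adjacent or equi-energy swaps, fixed or adaptive chain count) and
  parallel hierarchical sampling; prior-draw (RND) or multi-start
  optimization (MS) initialization.
* **Analysis pipeline**: automatic burn-in (sequential Geweke tests with
  Bonferroni–Holm correction), similarity grouping of runs
  (Gelman-Rubin-Brooks + Geweke), exploration quality (EQ = fraction of a
  scenario's runs in groups that cover all modes and tails found by any
  group), Sokal effective sample size with the max-autocorrelation rule,
  and EQ-conditioned ESS per CPU second — so that a fast chain stuck in
  one mode scores zero, not high.

See `docs/methods.md` for the full model and algorithm documentation.

## Worked example

Sample the saturated-growth posterior (M3: x' = b1 − b2 x, truth
b1 = 1, b2 = 0.2, sigma = 0.03) with parallel hierarchical sampling from
multi-start optima:

```python
import numpy as np
import odemcmc as om
from odemcmc.samplers import SamplerConfig, run_sampler

problem = om.make_benchmark("M3")
data = om.generate_data(problem, seed=1)          # synthetic data at truth
target = om.PosteriorTarget(problem, data)

ms = om.multistart_optimize(problem, data, n_starts=20, seed=0)
run = run_sampler(SamplerConfig(algorithm="phs", n_aux=4), target,
                  om.init_from_multistart(ms, 5, problem=problem, seed=0),
                  50_000, seed=0, init_cpu_seconds=ms.cpu_seconds)

bi = om.estimate_burnin(run.trace)
post = run.trace[bi.n_burn_in:]
ess, tau, stride = om.effective_sample_size(post)
```

Output of the accompanying prints:

```
best optimum: [0.9967 0.199  0.0254] log-posterior: 227.6
burn-in: 0 iterations (converged=True)
posterior means: [0.9968 0.1992 0.026 ]
95% credible intervals:
  b1      [0.9801, 1.0135]
  b2      [0.1803, 0.2178]
  sigma1  [0.0226, 0.0300]
ESS: 6740 (max tau 7.4), ESS/s: 1114
```

The optimizer lands on the generating parameters, the chain needs no
burn-in (it starts at an optimum), all three credible intervals cover the
truth, and the integrated autocorrelation time of ~7 means the 50,000
iterations are worth ~6,700 independent draws.

For full studies there is a CLI: `odemcmc generate M1b --seed 1` writes a
dataset CSV, `odemcmc sample study.yaml` executes a (resumable) scenario
grid, `odemcmc diagnose <run.csv>` prints burn-in/ESS for one run, and
`odemcmc report <rundir>` emits the per-scenario EQ/ESS table and the
grouping dump.

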