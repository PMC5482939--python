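"""Convergence diagnostics: Geweke, Gelman-Rubin-Brooks, burn-in, ESS.

The Geweke z-score compares the means of two chain segments, with the
variance of each segment mean estimated from the zero-frequency spectral
density so that autocorrelation is accounted for.  Burn-in is found
automatically by running the Geweke test on a grid of candidate truncation
points with Bonferroni-Holm correction across parameters; the first
truncation at which no test rejects is the end of burn-in.

The (multivariate) Gelman-Rubin-Brooks diagnostic compares within-chain
and between-chain variance of several aligned chains; the multivariate
potential scale reduction factor (mpsrf) uses the largest eigenvalue of
W^-1 B/n.

The integrated autocorrelation time tau = 1 + 2 sum_k rho(k) is estimated
with an adaptively truncated autocorrelation sum (window W chosen as the
smallest W >= c tau(W), c = 6) computed via FFT; the effective sample size
of a multi-parameter trace is N divided by the maximum tau across
parameters, a conservative univariate rule that also fixes a thinning
stride.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GewekeResult",
    "GrbResult",
    "BurnInResult",
    "spectral_variance",
    "geweke_test",
    "geweke_between",
    "grb_diagnostic",
    "estimate_burnin",
    "autocorr_time_sokal",
    "effective_sample_size",
]

SOKAL_WINDOW_C = 6.0


@dataclass
class GewekeResult:
    z: np.ndarray
    p: np.ndarray
    segments: tuple


@dataclass
class GrbResult:
    psrf: np.ndarray
    mpsrf: float
    n_chains: int
    n_iter: int


@dataclass
class BurnInResult:
    n_burn_in: int
    candidates: np.ndarray
    passed: np.ndarray
    converged: bool


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation of a 1-d series via zero-padded FFT."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    if acov[0] <= 0:
        raise ValueError("constant series has no autocorrelation structure")
    return acov / acov[0]


def autocorr_time_sokal(series: np.ndarray, c: float = SOKAL_WINDOW_C) -> float:
    """Integrated autocorrelation time with adaptive window truncation.

    tau(W) = 1 + 2 sum_{k<=W} rho(k); the window is the smallest W with
    W >= c * tau(W).  The estimate is floored at 1 (an i.i.d. series).
    """
    series = np.asarray(series, dtype=float)
    if series.size < 100:
        raise ValueError("series too short for autocorrelation-time estimation")
    rho = _autocorrelation(series)
    taus = 1.0 + 2.0 * np.cumsum(rho[1:])
    windows = np.arange(1, taus.size + 1)
    ok = windows >= c * taus
    W = int(np.argmax(ok)) if ok.any() else taus.size - 1
    return float(max(taus[W], 1.0))


def spectral_variance(series: np.ndarray) -> float:
    """Estimate Var(sample mean) of a correlated series.

    Uses the zero-frequency spectral density S(0) = gamma_0 * tau through
    the adaptively truncated autocorrelation sum: Var(mean) ~ S(0)/n.
    A constant series is flagged by a zero return value.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 10:
        raise ValueError("series too short for spectral variance estimation")
    var = series.var(ddof=1)
    if var == 0:
        return 0.0
    if n < 100:  # too short for windowed truncation; fall back to iid
        return float(var / n)
    tau = autocorr_time_sokal(series)
    return float(var * tau / n)


def _segment_stats(segment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seg = np.atleast_2d(segment.T).T
    means = seg.mean(axis=0)
    svs = np.array([spectral_variance(seg[:, j]) for j in range(seg.shape[1])])
    return means, svs


def _z_to_result(mean_a, sv_a, mean_b, sv_b, segments) -> GewekeResult:
    denom = np.sqrt(sv_a + sv_b)
    if np.any(denom == 0):
        raise ValueError("degenerate (constant) segments in Geweke test")
    z = (mean_a - mean_b) / denom
    p = 2.0 * stats.norm.sf(np.abs(z))
    return GewekeResult(z=z, p=p, segments=segments)


def geweke_test(chain: np.ndarray, frac_a: float = 0.1,
                frac_b: float = 0.5) -> GewekeResult:
    """Geweke stationarity test comparing early and late chain segments.

    Compares the mean of the first ``frac_a`` of the chain against the last
    ``frac_b``, per parameter, with spectral variance estimates; z-scores
    are referred to the standard normal (two-sided).
    """
    chain = np.atleast_2d(np.asarray(chain, dtype=float).T).T
    n = chain.shape[0]
    n_a = int(round(frac_a * n))
    n_b = int(round(frac_b * n))
    if n_a < 10 or n_b < 10 or n_a + n_b > n:
        raise ValueError("chain too short for the requested segment fractions")
    mean_a, sv_a = _segment_stats(chain[:n_a])
    mean_b, sv_b = _segment_stats(chain[n - n_b:])
    return _z_to_result(mean_a, sv_a, mean_b, sv_b,
                        (("first", frac_a), ("last", frac_b)))


def geweke_between(run_a: np.ndarray, run_b: np.ndarray) -> GewekeResult:
    """Between-run Geweke comparison: the two 'signals' are two runs."""
    a = np.atleast_2d(np.asarray(run_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(run_b, dtype=float).T).T
    mean_a, sv_a = _segment_stats(a)
    mean_b, sv_b = _segment_stats(b)
    return _z_to_result(mean_a, sv_a, mean_b, sv_b,
                        (("run_a", 1.0), ("run_b", 1.0)))


def grb_diagnostic(chains: Sequence[np.ndarray]) -> GrbResult:
    """(Multivariate) Gelman-Rubin-Brooks potential scale reduction.

    All chains must be aligned to equal length.  Per-parameter PSRF is
    sqrt(((n-1)/n W + (1 + 1/m) B/n) / W); the multivariate PSRF replaces
    the variance ratio by the largest eigenvalue of W^-1 B/n.
    """
    if len(chains) < 2:
        raise ValueError("at least two chains are required")
    mats = [np.atleast_2d(np.asarray(c, dtype=float).T).T for c in chains]
    n = mats[0].shape[0]
    d = mats[0].shape[1]
    if any(m.shape != (n, d) for m in mats):
        raise ValueError("chains must have equal length and dimensionality")
    m = len(mats)
    means = np.array([c.mean(axis=0) for c in mats])
    W_diag = np.mean([c.var(axis=0, ddof=1) for c in mats], axis=0)
    if np.any(W_diag == 0):
        raise ValueError("zero within-chain variance")
    B_over_n = np.atleast_2d(np.cov(means.T, ddof=1))
    var_hat = (n - 1) / n * W_diag + (1.0 + 1.0 / m) * np.diag(B_over_n)
    psrf = np.sqrt(var_hat / W_diag)

    W_full = np.zeros((d, d))
    for c in mats:
        W_full += np.atleast_2d(np.cov(c.T, ddof=1))
    W_full /= m
    try:
        lam = np.max(np.real(np.linalg.eigvals(np.linalg.solve(W_full,
                                                               B_over_n))))
    except np.linalg.LinAlgError:
        lam = np.inf
    mpsrf = float(np.sqrt((n - 1) / n + (m + 1) / m * max(lam, 0.0)))
    return GrbResult(psrf=psrf, mpsrf=mpsrf, n_chains=m, n_iter=n)


def estimate_burnin(chain: np.ndarray, alpha: float = 0.05,
                    n_candidates: int = 20,
                    frac_a: float = 0.1, frac_b: float = 0.5) -> BurnInResult:
    """Automatic burn-in from a sequence of Geweke tests.

    Truncation candidates are equispaced at 0%, 5%, ..., 95% of the chain;
    for each, the Geweke test runs on the remaining chain with its
    per-parameter p-values corrected by Bonferroni-Holm at level ``alpha``.
    The first candidate at which no corrected test rejects ends the
    burn-in; if none passes the run is flagged non-converged and the whole
    chain is burn-in.
    """
    chain = np.atleast_2d(np.asarray(chain, dtype=float).T).T
    n = chain.shape[0]
    if n < 10 * n_candidates:
        raise ValueError("chain too short for the burn-in candidate grid")
    candidates = np.rint(np.linspace(0.0, 0.95, n_candidates) * n).astype(int)
    passed = np.zeros(n_candidates, dtype=bool)
    for i, start in enumerate(candidates):
        try:
            res = geweke_test(chain[start:], frac_a, frac_b)
        except ValueError:
            continue
        reject = multipletests(res.p, alpha=alpha, method="holm")[0]
        passed[i] = not reject.any()
        if passed[i]:
            return BurnInResult(int(start), candidates, passed, True)
    return BurnInResult(n, candidates, passed, False)


def effective_sample_size(trace: np.ndarray,
                          c: float = SOKAL_WINDOW_C) -> tuple[float, float, int]:
    """(ESS, max tau, thinning stride) of a post-burn-in trace.

    ESS = N / max_i tau_i with the per-parameter integrated autocorrelation
    time maximum; the stride ceil(max tau) thins the chain to approximately
    independent draws.
    """
    trace = np.atleast_2d(np.asarray(trace, dtype=float).T).T
    taus = [autocorr_time_sokal(trace[:, j], c=c)
            for j in range(trace.shape[1])]
    tau_max = float(np.max(taus))
    n = trace.shape[0]
    return n / tau_max, tau_max, int(np.ceil(tau_max))
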