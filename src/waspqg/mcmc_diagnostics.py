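"""Posterior summaries and convergence diagnostics for MCMC output.

Point estimates are posterior modes from a Gaussian kernel density estimate
(Silverman bandwidth); interval estimates are empirical highest-posterior-
density (shortest) intervals.  Convergence checks follow common practice
for animal-model fits: lag-1 autocorrelation of the thinned chain below
0.1, effective sample size above 1000 (Geyer initial-monotone-sequence
estimator), and the Heidelberger–Welch stationarity test (Cramer-von Mises
statistic of a Brownian bridge formed from the cumulative sums, discarding
initial segments of 10% up to 50% until the test passes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def posterior_mode(samples: np.ndarray) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) over the draws."""
    x = np.asarray(samples, dtype=float)
    if x.size < 100:
        raise ValueError("posterior mode needs at least 100 draws")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 1024)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest empirical interval containing the requested posterior mass."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws for an HPD interval")
    k = max(int(np.ceil(mass * n)), 2)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    lo = int(np.argmin(widths))
    return float(x[lo]), float(x[lo + k - 1])


def autocorrelation(samples: np.ndarray, lag: int = 1) -> float:
    """Lag-k autocorrelation of a chain (0 for constant chains)."""
    x = np.asarray(samples, dtype=float)
    if lag >= x.size:
        raise ValueError("lag must be smaller than the chain length")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0
    return float(np.dot(x[:-lag], x[lag:]) / denom)


def _autocovariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = x.size
    xc = x - x.mean()
    # FFT-based autocovariance, biased (divides by n), as Geyer's estimator uses
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[: max_lag + 1].real / n
    return acov


def initial_monotone_variance(samples: np.ndarray) -> float:
    """Geyer's initial-monotone-sequence estimate of the long-run variance.

    Sums adjacent-pair autocovariances while the pair sums stay positive and
    non-increasing; consistent for reversible chains.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    acov = _autocovariances(x, max_lag=n - 1)
    npair = acov.size // 2
    pair = acov[0 : 2 * npair : 2] + acov[1 : 2 * npair : 2]
    sigma2 = -acov[0]
    prev = np.inf
    for p in pair:
        if p <= 0:
            break
        p = min(p, prev)
        prev = p
        sigma2 += 2.0 * p
    return float(max(sigma2, 0.0))


def effective_sample_size(samples: np.ndarray) -> float:
    """ESS = n * var / long-run variance (initial monotone sequence)."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("chain too short for an ESS estimate")
    var = float(x.var())
    if var == 0:
        return float(n)
    sigma2 = initial_monotone_variance(x)
    if sigma2 <= 0:
        return float(n)
    return float(min(n * var / sigma2, n))


# 5% critical value of the limiting Cramer-von Mises (omega^2) distribution
_CVM_CRIT_05 = 0.4614


def _cvm_statistic(x: np.ndarray, sigma2: float) -> float:
    n = x.size
    csum = np.cumsum(x) - np.arange(1, n + 1) * x.mean()
    bridge = csum / np.sqrt(n * sigma2)
    return float(np.mean(bridge**2))


@dataclass(frozen=True)
class HeidelbergerResult:
    passed: bool
    start_iteration: int  # first retained draw (0-based) after discarding
    statistic: float
    n_used: int


def heidelberger_welch(
    samples: np.ndarray, alpha: float = 0.05
) -> HeidelbergerResult:
    """Heidelberger–Welch stationarity test.

    Tests the Brownian-bridge Cramer-von Mises statistic of the chain's
    cumulative sums against the omega-squared null; on failure drops the
    initial 10% repeatedly, up to half the chain.  The long-run variance is
    estimated once from the second half of the full chain.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("chain too short for the stationarity test")
    if alpha != 0.05:
        raise NotImplementedError("only the 5% level is tabulated")
    # long-run variance from the second half, detrended so that a drifting
    # chain cannot inflate the estimate and mask its own nonstationarity
    half = x[n // 2 :]
    t = np.arange(half.size, dtype=float)
    slope, icept = np.polyfit(t, half, 1)
    sigma2 = initial_monotone_variance(half - (slope * t + icept))
    if sigma2 <= 0:
        return HeidelbergerResult(True, 0, 0.0, n)
    step = n // 10
    for start in range(0, n // 2 + 1, max(step, 1)):
        stat = _cvm_statistic(x[start:], sigma2)
        if stat < _CVM_CRIT_05:
            return HeidelbergerResult(True, start, stat, n - start)
        if start + step > n // 2:
            break
    return HeidelbergerResult(False, n // 2, stat, n - n // 2)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Per-parameter convergence summary with pass/fail flags."""

    lag1_autocorr: dict[str, float]
    ess: dict[str, float]
    stationarity: dict[str, HeidelbergerResult]
    autocorr_ok: bool  # all |lag-1| < 0.1
    ess_ok: bool  # all ESS > 1000
    stationary_ok: bool


def diagnostics(
    chains: dict[str, np.ndarray],
    autocorr_threshold: float = 0.1,
    ess_threshold: float = 1000.0,
) -> DiagnosticsReport:
    """Convergence report over named parameter chains (post thinning)."""
    ac = {k: autocorrelation(v, 1) for k, v in chains.items()}
    ess = {k: effective_sample_size(v) for k, v in chains.items()}
    hw = {k: heidelberger_welch(v) for k, v in chains.items()}
    return DiagnosticsReport(
        lag1_autocorr=ac,
        ess=ess,
        stationarity=hw,
        autocorr_ok=all(abs(v) < autocorr_threshold for v in ac.values()),
        ess_ok=all(v > ess_threshold for v in ess.values()),
        stationary_ok=all(v.passed for v in hw.values()),
    )
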