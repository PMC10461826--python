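"""Generalised extreme value (GEV) null distribution.

The null distribution of the GPS statistic is modelled as GEV(a, b, c)
with location a, scale b > 0 and shape c, under the CDF convention

    G(x) = exp(-[1 + c (x - a) / b]^(-1/c))   for 1 + c (x - a) / b > 0,

with the c -> 0 Gumbel limit exp(-exp(-(x - a) / b)). Note scipy's
``genextreme`` uses the opposite shape sign (c_here = -c_scipy); all
public values in this module follow the convention above and any
conversion happens at the call boundary.

Fitting is by maximum likelihood: Nelder-Mead on the negative
log-likelihood over (a, log b, c), started from probability-weighted
moments and a Gumbel method-of-moments point, with up to five seeded
random restarts. Standard errors come from the numerically inverted
observed information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_hess

from .errors import GEVFitError, InputValidationError

_EULER = 0.57721566490153286
_C_GUMBEL = 1e-9  # |c| below this: use the Gumbel limit
_MIN_FIT = 100


@dataclass
class GEVParams:
    """Fitted GEV parameters with uncertainty and fit diagnostics."""

    location: float
    scale: float
    shape: float
    standard_errors: tuple[float, float, float]
    loglik: float
    n_fit: int
    converged: bool

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise InputValidationError(f"scale must be positive, got {self.scale}")


def gev_nll(params: np.ndarray, x: np.ndarray) -> float:
    """Negative GEV log-likelihood at (a, b, c); +inf outside the support."""
    a, b, c = params
    if b <= 0:
        return np.inf
    s = (x - a) / b
    n = x.size
    if abs(c) < _C_GUMBEL:
        return n * math.log(b) + float(np.sum(s + np.exp(-s)))
    t = 1.0 + c * s
    if np.min(t) <= 0.0:
        return np.inf
    logt = np.log(t)
    return n * math.log(b) + float(np.sum((1.0 + 1.0 / c) * logt
                                          + np.exp(-logt / c)))


def _pwm_start(x: np.ndarray) -> tuple[float, float, float]:
    """Hosking's probability-weighted-moments estimator.

    Hosking parameterises the GEV with shape k = -c; the return value is
    converted to the convention of this module.
    """
    xs = np.sort(x)
    n = xs.size
    j = np.arange(1, n + 1)
    b0 = xs.mean()
    b1 = np.sum((j - 1) / (n - 1) * xs) / n
    b2 = np.sum((j - 1) * (j - 2) / ((n - 1) * (n - 2)) * xs) / n
    z = (2 * b1 - b0) / (3 * b2 - b0) - math.log(2) / math.log(3)
    k = 7.8590 * z + 2.9554 * z * z
    if abs(k) < 1e-6:
        b = (2 * b1 - b0) / math.log(2)
        a = b0 - _EULER * b
        return a, b, 0.0
    g = special.gamma(1.0 + k)
    b = (2 * b1 - b0) * k / (g * (1.0 - 2.0 ** (-k)))
    if b <= 0:
        b = x.std(ddof=1) * math.sqrt(6) / math.pi
    a = b0 + b * (g - 1.0) / k
    return a, b, -k


def _gumbel_start(x: np.ndarray) -> tuple[float, float, float]:
    b = x.std(ddof=1) * math.sqrt(6) / math.pi
    return x.mean() - _EULER * b, b, 0.0


def fit_gev(sample, n_restarts: int = 5) -> GEVParams:
    """Maximum-likelihood GEV fit to a null sample of GPS statistics.

    Parameters
    ----------
    sample
        A :class:`~gpstest.permutation.NullSample` or a plain 1-d array of
        null statistic values (at least 100, not all equal).
    n_restarts
        Random restarts attempted (after the deterministic starts) before
        declaring non-convergence.
    """
    x = np.asarray(getattr(sample, "d_values", sample), dtype=np.float64)
    if x.ndim != 1 or x.size < _MIN_FIT:
        raise InputValidationError(
            f"need at least {_MIN_FIT} null values to fit, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        raise InputValidationError("null values are all equal; cannot fit a GEV")

    def nll_logb(theta):
        return gev_nll((theta[0], math.exp(theta[1]), theta[2]), x)

    starts = []
    for a0, b0, c0 in (_pwm_start(x), _gumbel_start(x)):
        if np.isfinite(a0) and b0 > 0 and np.isfinite(c0):
            starts.append((a0, math.log(b0), c0))
    if not starts:  # pragma: no cover - PWM and MoM both need pathological data
        starts = [(x.mean(), math.log(max(x.std(ddof=1), 1e-12)), 0.0)]
    rng = np.random.default_rng(12345)
    base = starts[0]
    for _ in range(n_restarts):
        starts.append((base[0] + rng.normal(0, 0.1 * math.exp(base[1])),
                       base[1] + rng.normal(0, 0.2),
                       base[2] + rng.normal(0, 0.1)))

    n_deterministic = min(2, len(starts))
    best = None
    converged = False
    for k, theta0 in enumerate(starts):
        res = optimize.minimize(
            nll_logb, np.asarray(theta0), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
        )
        ok = res.success and np.isfinite(res.fun)
        if ok and (best is None or res.fun < best.fun):
            best = res
        elif best is None and np.isfinite(res.fun):
            best = res
        converged = converged or ok
        # random restarts are a rescue path: stop once the deterministic
        # starts are done and something has converged
        if converged and k >= n_deterministic - 1:
            break
    if best is None:
        raise GEVFitError("GEV likelihood evaluation failed at every start")

    a = float(best.x[0])
    b = float(math.exp(best.x[1]))
    c = float(best.x[2])
    se = _observed_info_se(np.array([a, b, c]), x)
    params = GEVParams(
        location=a, scale=b, shape=c, standard_errors=se,
        loglik=-float(best.fun), n_fit=int(x.size), converged=converged,
    )
    if not converged:
        raise GEVFitError("GEV fit did not converge after restarts", params=params)
    return params


def _observed_info_se(theta: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Standard errors from the numerically inverted observed information."""
    try:
        hess = approx_hess(theta, gev_nll, args=(x,))
        cov = np.linalg.inv(hess)
        var = np.diag(cov)
        if np.any(var <= 0) or not np.all(np.isfinite(var)):
            raise np.linalg.LinAlgError
        se = np.sqrt(var)
        return (float(se[0]), float(se[1]), float(se[2]))
    except (np.linalg.LinAlgError, ValueError):
        return (math.nan, math.nan, math.nan)


def gev_cdf(x, params: GEVParams):
    """GEV CDF G(x; a, b, c); 0 below / 1 above a finite support endpoint."""
    a, b, c = params.location, params.scale, params.shape
    xv = np.asarray(x, dtype=np.float64)
    s = (xv - a) / b
    if abs(c) < _C_GUMBEL:
        out = np.exp(-np.exp(-s))
    else:
        t = 1.0 + c * s
        with np.errstate(over="ignore"):
            out = np.where(
                t > 0.0,
                np.exp(-np.power(np.maximum(t, 1e-300), -1.0 / c)),
                0.0 if c > 0 else 1.0,
            )
    return float(out) if np.isscalar(x) else out


def gev_quantile(q: float, params: GEVParams) -> float:
    """Inverse of :func:`gev_cdf` for a scalar probability ``q`` in (0, 1)."""
    if not 0.0 < q < 1.0:
        raise InputValidationError(f"quantile level must be in (0, 1), got {q}")
    a, b, c = params.location, params.scale, params.shape
    y = -math.log(q)
    if abs(c) < _C_GUMBEL:
        return a - b * math.log(y)
    return a + b * (y ** (-c) - 1.0) / c
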