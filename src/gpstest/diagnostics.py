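"""Goodness-of-fit diagnostics for the permutation-fitted null.

Uniformity of p-values is checked with the one-sample Kolmogorov-Smirnov
test; adequacy of a fitted GEV is checked with an Anderson-Darling test
on the probability-integral transform of the null sample, whose p-value
is obtained by Monte Carlo from uniform samples of the same size (the A^2
null law depends on n only). Reusing the sample that the parameters were
fitted on makes the AD check conservative in the passing direction,
which suffices for a pass/fail adequacy screen.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest

from .errors import InputValidationError


def ad_statistic_uniform(z: np.ndarray) -> float:
    """Anderson-Darling A^2 for a sample against Uniform(0, 1)."""
    z = np.sort(np.asarray(z, dtype=np.float64))
    n = z.size
    if n < 2:
        raise InputValidationError("need at least 2 values for A^2")
    eps = np.finfo(np.float64).tiny
    z = np.clip(z, eps, 1.0 - 1e-16)
    i = np.arange(1, n + 1)
    s = np.sum((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1])))
    return float(-n - s / n)


def ad_uniform_pvalue(
    z: np.ndarray, n_mc: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo AD test of Uniform(0, 1); returns (A^2, p-value)."""
    z = np.asarray(z, dtype=np.float64)
    a2 = ad_statistic_uniform(z)
    rng = np.random.default_rng(seed)
    n = z.size
    i = np.arange(1, n + 1)
    sims = np.sort(rng.random((n_mc, n)), axis=1)
    eps = np.finfo(np.float64).tiny
    sims = np.clip(sims, eps, 1.0 - 1e-16)
    s = np.sum((2 * i - 1) * (np.log(sims) + np.log1p(-sims[:, ::-1])), axis=1)
    null = -n - s / n
    p = (1.0 + np.sum(null >= a2)) / (n_mc + 1.0)
    return a2, float(p)


def ks_uniform_pvalue(p_values: np.ndarray) -> float:
    """One-sample KS test of p-values against Uniform(0, 1)."""
    return float(kstest(np.asarray(p_values, float), "uniform").pvalue)
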