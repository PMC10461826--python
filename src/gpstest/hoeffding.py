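"""Hoeffding's nonparametric test of bivariate independence.

The canonical comparator for the GPS tests: a rank-based quadratic
functional of the discrepancy between the joint ecdf and the product of
marginals. With midranks R_i, S_i and half-count concordance counts

    c_i = #{j != i : u_j < u_i and v_j < v_i}
          (a tie in a coordinate contributes 1/2, in both 1/4),

the classical x30-scaled statistic is

    D = 30 [ (n-2)(n-3) D1 + D2 - 2 (n-2) D3 ]
            / [ n (n-1)(n-2)(n-3)(n-4) ],
    D1 = sum c_i (c_i - 1),
    D2 = sum (R_i - 1)(R_i - 2)(S_i - 1)(S_i - 2),
    D3 = sum (R_i - 2)(S_i - 2) c_i.

Significance is assessed by the same permutation scheme used for the GPS
statistic rather than asymptotic tables, which keeps the two tests
directly comparable on the same inputs.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from . import _kernels
from .ecdf import _check_lengths, _sweep_inputs
from .errors import InputValidationError
from .inference import TestReport
from .pair import HarmonizedPair

_MIN_N = 5  # the denominator n(n-1)...(n-4) vanishes below this


def _c_counts(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    order, group_starts, vr, m = _sweep_inputs(u, v)
    return _kernels.hoeffding_c(order, group_starts, vr, m)


def _statistic_from_parts(R, S, c, n) -> float:
    d1 = float(np.sum(c * (c - 1.0)))
    d2 = float(np.sum((R - 1.0) * (R - 2.0) * (S - 1.0) * (S - 2.0)))
    d3 = float(np.sum((R - 2.0) * (S - 2.0) * c))
    num = 30.0 * ((n - 2.0) * (n - 3.0) * d1 + d2 - 2.0 * (n - 2.0) * d3)
    den = n * (n - 1.0) * (n - 2.0) * (n - 3.0) * (n - 4.0)
    return num / den


def hoeffding_statistic(u, v) -> float:
    """Classical tie-corrected Hoeffding D (x30 scaling)."""
    u, v = _check_lengths(np.asarray(u, float), np.asarray(v, float))
    n = u.size
    if n < _MIN_N:
        raise InputValidationError(
            f"Hoeffding's statistic needs at least {_MIN_N} observations, got {n}"
        )
    R = rankdata(u)  # midranks
    S = rankdata(v)
    c = _c_counts(u, v)
    return _statistic_from_parts(R, S, c, n)


def hoeffding_test(
    pair: HarmonizedPair,
    n_perm: int = 1000,
    seed: int = 0,
) -> TestReport:
    """Permutation test: p = (1 + #{null >= observed}) / (n_perm + 1).

    ``v`` is permuted exactly as in the GPS permutation null, with one
    substream per replicate spawned from the master seed.
    """
    u, v = pair.u, pair.v
    n = pair.n
    if n < _MIN_N:
        raise InputValidationError(
            f"Hoeffding's test needs at least {_MIN_N} observations, got {n}"
        )
    R = rankdata(u)
    S = rankdata(v)
    order, group_starts, vr, m = _sweep_inputs(u, v)
    c = _kernels.hoeffding_c(order, group_starts, vr, m)
    observed = _statistic_from_parts(R, S, c, n)

    children = np.random.SeedSequence(seed).spawn(n_perm)
    n_ge = 0
    for r in range(n_perm):
        rng = np.random.default_rng(children[r])
        perm = rng.permutation(n)
        c_p = _kernels.hoeffding_c(order, group_starts, vr[perm], m)
        if _statistic_from_parts(R, S[perm], c_p, n) >= observed:
            n_ge += 1
    p = (1.0 + n_ge) / (n_perm + 1.0)
    return TestReport(
        method="hoeffding-perm",
        statistic=observed,
        p_value=p,
        n_variants=n,
        n_perm=n_perm,
        metadata=dict(pair.metadata, seed=seed),
    )
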