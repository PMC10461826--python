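"""Permutation null for the GPS statistic.

Null realisations of D are generated by randomly permuting the order of
one p-value vector and recomputing the statistic, which preserves both
marginals exactly while destroying any dependence between them. The
marginal ecdf ranks are computed once and reused: a permutation only
changes the joint counts.

Reproducibility: one master seed spawns an independent substream per
replicate (``numpy.random.SeedSequence``), so a parallel evaluation order
would give bit-identical results to the sequential one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .ecdf import _sweep_inputs, bivariate_counts, marginal_counts
from .errors import DegenerateInputError, InputValidationError
from .pair import HarmonizedPair
from .statistic import gps_from_counts

_MIN_PERM = 100
DEFAULT_N_PERM = 3000  # accuracy / running-time compromise for single pairs


@dataclass
class NullSample:
    """Null GPS statistics generated by permutation."""

    d_values: np.ndarray
    n_perm: int
    seed: int
    n_variants: int


def permutation_null(
    pair: HarmonizedPair,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    backend: str = "tree",
) -> NullSample:
    """Generate ``n_perm`` null realisations of D for ``pair``.

    The ``tree`` backend uses a fused sweep that accumulates the running
    maximum inside the kernel; ``naive`` and ``dac`` recompute the joint
    counts per permutation and agree exactly with it.
    """
    if n_perm < _MIN_PERM:
        raise InputValidationError(
            f"n_perm must be at least {_MIN_PERM}, got {n_perm}"
        )
    if n_perm < 1000:
        warnings.warn(
            f"n_perm={n_perm} below 1,000; GEV parameter estimates may be "
            "imprecise", stacklevel=2,
        )
    u, v = pair.u, pair.v
    if np.ptp(u) == 0.0 and np.ptp(v) == 0.0:
        raise DegenerateInputError(
            "all evaluation points degenerate (both vectors constant)"
        )
    n = pair.n
    cu = marginal_counts(u)
    vr_counts = marginal_counts(v)  # marginal ranks of v; permutes with v
    order, group_starts, _, _ = _sweep_inputs(u, v)
    m = int(vr_counts.max())
    scale = np.sqrt(n / np.log(n))

    children = np.random.SeedSequence(seed).spawn(n_perm)
    d_values = np.empty(n_perm)
    for r in range(n_perm):
        rng = np.random.default_rng(children[r])
        perm = rng.permutation(n)
        vr_p = vr_counts[perm]
        if backend == "tree":
            d_values[r] = _kernels.sweep_gps_max(
                order, group_starts, vr_p, m, cu, scale
            )
        else:
            cuv = bivariate_counts(u, v[perm], backend=backend)
            d_values[r] = gps_from_counts(cu, vr_p, cuv, backend).D
    return NullSample(
        d_values=d_values, n_perm=n_perm, seed=seed, n_variants=n
    )
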