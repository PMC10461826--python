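"""The GPS statistic.

The genome-wide pairwise-association signal sharing (GPS) statistic is a
weighted supremum-norm distance between the joint ecdf of two traits'
p-values and the product of the marginals:

    D = sup_i sqrt(n / ln n) * |F_uv(i) - F_u(i) F_v(i)|
                              / sqrt(F_u(i) F_v(i) - F_u(i)^2 F_v(i)^2)

evaluated at the n observed pairs (the objective is piecewise constant
between them). The denominator upweights discrepancies at small p-values,
where shared association signal concentrates. Points with
F_u * F_v == 1 make the weight 0/0 and are excluded from the maximum; the
exclusion is reported rather than silently mapped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecdf import bivariate_counts, marginal_counts
from .errors import DegenerateInputError
from .pair import HarmonizedPair


@dataclass
class GPSResult:
    """The GPS statistic and the point attaining the supremum."""

    D: float
    argmax_index: int
    argmax_values: tuple[float, float, float]  #: (F_u, F_v, F_uv) at the argmax
    n_used: int
    n_excluded: int
    backend_name: str = "tree"


def gps_from_counts(cu: np.ndarray, cv: np.ndarray, cuv: np.ndarray,
                    backend_name: str = "tree") -> GPSResult:
    """Assemble the statistic from integer marginal and joint counts."""
    n = cu.size
    fu = cu / n
    fv = cv / n
    fuv = cuv / n
    prod = fu * fv
    radicand = prod - prod * prod  # == fu fv (1 - fu fv)
    ok = radicand > 0.0  # excluded exactly where fu * fv == 1
    n_excluded = int(n - ok.sum())
    if n_excluded == n:
        raise DegenerateInputError(
            "all evaluation points degenerate (both vectors constant)"
        )
    scale = np.sqrt(n / np.log(n))
    t = np.zeros(n)
    t[ok] = scale * np.abs(fuv[ok] - prod[ok]) / np.sqrt(radicand[ok])
    t[~ok] = -np.inf
    i_star = int(np.argmax(t))  # smallest index on ties
    return GPSResult(
        D=float(t[i_star]),
        argmax_index=i_star,
        argmax_values=(float(fu[i_star]), float(fv[i_star]), float(fuv[i_star])),
        n_used=n - n_excluded,
        n_excluded=n_excluded,
        backend_name=backend_name,
    )


def gps_statistic(pair: HarmonizedPair, backend: str = "tree") -> GPSResult:
    """Compute the GPS statistic D for a harmonised pair of p-value vectors."""
    cu = marginal_counts(pair.u)
    cv = marginal_counts(pair.v)
    cuv = bivariate_counts(pair.u, pair.v, backend=backend)
    return gps_from_counts(cu, cv, cuv, backend_name=backend)
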