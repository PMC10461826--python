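"""Aligned per-variant p-value vectors for a pair of traits.

A :class:`HarmonizedPair` is the sample space of the GPS statistic: two
vectors ``u`` and ``v`` of GWAS p-values for the *same* variants, one per
trait, pre-pruned for linkage disequilibrium upstream. All tests in this
package consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InputValidationError

#: Smallest pair size for which any implemented test is meaningful.
MIN_VARIANTS = 5


@dataclass
class HarmonizedPair:
    """P-values for two traits measured at the same variants.

    Parameters
    ----------
    variant_ids
        Identifiers, one per variant.
    u, v
        P-values in ``(0, 1]`` for trait 1 and trait 2. ``p == 1`` is a
        legal value; non-positive or non-finite p-values must be removed
        upstream (see :mod:`gpstest.io`).
    metadata
        Free-form provenance: source files, the r² pruning threshold used
        upstream, whether the MHC was excluded, generator parameters, ...
    """

    variant_ids: list[str]
    u: np.ndarray
    v: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        self.variant_ids = list(self.variant_ids)
        n = len(self.variant_ids)
        if self.u.shape != (n,) or self.v.shape != (n,):
            raise InputValidationError(
                f"length mismatch: {n} ids, {self.u.shape[0]} u values, "
                f"{self.v.shape[0]} v values"
            )
        if n < MIN_VARIANTS:
            raise InputValidationError(
                f"need at least {MIN_VARIANTS} variants, got {n}"
            )
        for name, vec in (("u", self.u), ("v", self.v)):
            bad = ~np.isfinite(vec)
            if bad.any():
                raise InputValidationError(
                    f"non-finite p-value in {name} at index {int(np.flatnonzero(bad)[0])}"
                )
            out = (vec <= 0.0) | (vec > 1.0)
            if out.any():
                raise InputValidationError(
                    f"p-value outside (0, 1] in {name} at index "
                    f"{int(np.flatnonzero(out)[0])}"
                )

    @property
    def n(self) -> int:
        """Number of variants."""
        return len(self.variant_ids)


def validate_pvalues(values: np.ndarray, name: str = "values") -> np.ndarray:
    """Coerce to float64 and reject non-finite entries, naming the index."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 1:
        raise InputValidationError(f"{name} must be a non-empty 1-d vector")
    bad = ~np.isfinite(arr)
    if bad.any():
        raise InputValidationError(
            f"non-finite value in {name} at index {int(np.flatnonzero(bad)[0])}"
        )
    return arr
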