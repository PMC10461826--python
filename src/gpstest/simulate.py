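"""Synthetic paired-GWAS p-value generators.

These generators emulate the statistical structure the GPS and Hoeffding
tests are sensitive to, without whole-genome simulation: per-trait Z
scores are drawn standard normal (optionally correlated ``rho`` across
traits at every SNP, emulating sample overlap, and equicorrelated within
LD-like blocks), a fraction ``pi1`` of SNPs per trait receives a non-null
addend drawn Normal(zmean, zsd), shared associated SNPs receive the same
addend in both traits, and two-sided p-values are taken as
p = 2 Phi(-|z|). Effect signs are not tracked: the GPS tests are
sign-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.stats import norm

from .errors import InputValidationError
from .pair import HarmonizedPair

GWS_THRESHOLD = 5e-8  #: conventional genome-wide significance level


@dataclass
class SimSpec:
    """Parameters of one synthetic paired-GWAS scenario.

    ``pi1_a`` / ``pi1_b`` are the fractions of truly associated SNPs per
    trait; ``n_shared`` of them are associated in both traits with a
    common Z addend. ``rho`` is the between-study correlation of base Z
    scores at every SNP (sample overlap); ``block_size`` / ``block_r``
    optionally make base Z scores equicorrelated within consecutive
    blocks (residual LD after pruning).
    """

    n_snps: int
    pi1_a: float = 0.0
    pi1_b: float = 0.0
    n_shared: int = 0
    zmean: float = 0.0
    zsd: float = 0.0
    rho: float = 0.0
    block_size: Optional[int] = None
    block_r: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 5:
            raise InputValidationError(f"n_snps must be >= 5, got {self.n_snps}")
        for name in ("pi1_a", "pi1_b"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise InputValidationError(f"{name} must be in [0, 1], got {x}")
        if not 0.0 <= self.rho < 1.0:
            raise InputValidationError(f"rho must be in [0, 1), got {self.rho}")
        if not 0.0 <= self.block_r < 1.0:
            raise InputValidationError(
                f"block_r must be in [0, 1), got {self.block_r}"
            )
        if self.zsd < 0:
            raise InputValidationError(f"zsd must be >= 0, got {self.zsd}")
        if self.block_size is not None and self.block_size < 2:
            raise InputValidationError(
                f"block_size must be >= 2, got {self.block_size}"
            )
        if self.n_shared > min(self.n_assoc_a, self.n_assoc_b):
            raise InputValidationError(
                f"n_shared={self.n_shared} exceeds the smaller associated "
                f"set ({min(self.n_assoc_a, self.n_assoc_b)})"
            )
        if self.n_assoc_a + self.n_assoc_b - self.n_shared > self.n_snps:
            raise InputValidationError(
                "associated sets (with required disjointness of private "
                "SNPs) do not fit in n_snps"
            )

    @property
    def n_assoc_a(self) -> int:
        return round(self.pi1_a * self.n_snps)

    @property
    def n_assoc_b(self) -> int:
        return round(self.pi1_b * self.n_snps)


def _variant_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"snp_{i:0{width}d}" for i in range(1, n + 1)]


def _pvalues_from_z(z: np.ndarray) -> tuple[np.ndarray, int]:
    """Two-sided p = 2 Phi(-|z|), clamped away from exact zero."""
    p = 2.0 * norm.sf(np.abs(z))
    tiny = np.finfo(np.float64).tiny
    n_clamped = int(np.sum(p < tiny))
    return np.maximum(p, tiny), n_clamped


def _base_z(spec: SimSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Base Z pairs: cross-trait correlation rho, optional block structure."""
    n = spec.n_snps
    rho = spec.rho

    def correlated_pair(size):
        x = rng.standard_normal(size)
        y = rho * x + np.sqrt(1.0 - rho * rho) * rng.standard_normal(size)
        return x, y

    if spec.block_size is None or spec.block_r == 0.0:
        return correlated_pair(n)
    r = spec.block_r
    n_blocks = -(-n // spec.block_size)
    g_a, g_b = correlated_pair(n_blocks)  # shared block factor per trait
    e_a, e_b = correlated_pair(n)
    block_of = np.minimum(
        np.arange(n) // spec.block_size, n_blocks - 1
    )
    z_a = np.sqrt(r) * g_a[block_of] + np.sqrt(1.0 - r) * e_a
    z_b = np.sqrt(r) * g_b[block_of] + np.sqrt(1.0 - r) * e_b
    return z_a, z_b


def _simulate(spec: SimSpec) -> HarmonizedPair:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_snps
    z_a, z_b = _base_z(spec, rng)

    n_a, n_b, n_s = spec.n_assoc_a, spec.n_assoc_b, spec.n_shared
    n_pa, n_pb = n_a - n_s, n_b - n_s  # trait-private associated counts
    chosen = rng.choice(n, size=n_s + n_pa + n_pb, replace=False)
    shared = chosen[:n_s]
    priv_a = chosen[n_s:n_s + n_pa]
    priv_b = chosen[n_s + n_pa:]

    if n_s:
        w = rng.normal(spec.zmean, spec.zsd, n_s)  # same addend, sign-aligned
        z_a[shared] += w
        z_b[shared] += w
    if n_pa:
        z_a[priv_a] += rng.normal(spec.zmean, spec.zsd, n_pa)
    if n_pb:
        z_b[priv_b] += rng.normal(spec.zmean, spec.zsd, n_pb)

    u, clamp_a = _pvalues_from_z(z_a)
    v, clamp_b = _pvalues_from_z(z_b)
    meta = {
        "generator": "z-mixture",
        "n_snps": n, "pi1_a": spec.pi1_a, "pi1_b": spec.pi1_b,
        "n_shared": n_s, "zmean": spec.zmean, "zsd": spec.zsd,
        "rho": spec.rho, "block_size": spec.block_size,
        "block_r": spec.block_r, "seed": spec.seed,
        "n_clamped": clamp_a + clamp_b,
    }
    return HarmonizedPair(_variant_ids(n), u, v, metadata=meta)


def simulate_independent_null(n_snps: int, seed: int = 0) -> HarmonizedPair:
    """Fully independent pair: u, v i.i.d. Uniform(0, 1]."""
    if n_snps < 5:
        raise InputValidationError(f"n_snps must be >= 5, got {n_snps}")
    rng = np.random.default_rng(seed)
    u = 1.0 - rng.random(n_snps)  # (0, 1]
    v = 1.0 - rng.random(n_snps)
    meta = {"generator": "independent-null", "n_snps": n_snps, "seed": seed}
    return HarmonizedPair(_variant_ids(n_snps), u, v, metadata=meta)


def simulate_overlap_mixture(spec: SimSpec) -> HarmonizedPair:
    """Null/non-null Z mixture with overlap correlation, no shared SNPs.

    The associated SNP sets of the two traits are disjoint, so the only
    cross-trait dependence is the base correlation ``rho`` — the GPS null
    of no shared signal holds while sample overlap does not.
    """
    if spec.n_shared != 0:
        raise InputValidationError(
            "simulate_overlap_mixture requires n_shared == 0; "
            "use simulate_shared_effects"
        )
    return _simulate(spec)


def simulate_shared_effects(spec: SimSpec) -> HarmonizedPair:
    """Mixture with ``n_shared`` SNPs associated in both traits.

    Shared SNPs receive the same Normal(zmean, zsd) addend in both traits
    (maximal per-SNP sharing); remaining associated SNPs are trait-private
    and disjoint.
    """
    return _simulate(spec)


def simulate_ld_blocks(spec: SimSpec) -> HarmonizedPair:
    """Mixture with equicorrelated base Z blocks within each trait.

    Emulates the residual dependence left by LD pruning at a high r²
    threshold; the last block is truncated if n_snps is not divisible by
    block_size.
    """
    if spec.block_size is None:
        raise InputValidationError("simulate_ld_blocks requires block_size")
    return _simulate(spec)


def simulate_pair(spec: SimSpec) -> HarmonizedPair:
    """Dispatch on the scenario: blocked, shared, mixture or independent."""
    if spec.block_size is not None:
        return simulate_ld_blocks(spec)
    if spec.n_shared > 0:
        return simulate_shared_effects(spec)
    if spec.pi1_a > 0 or spec.pi1_b > 0 or spec.rho > 0:
        return simulate_overlap_mixture(spec)
    return simulate_independent_null(spec.n_snps, spec.seed)


def with_seed(spec: SimSpec, seed: int) -> SimSpec:
    """A copy of ``spec`` with a replaced seed."""
    return replace(spec, seed=seed)


def expected_gws_fraction(
    pi1: float, zmean: float, zsd: float, threshold: float = GWS_THRESHOLD
) -> float:
    """Expected fraction of SNPs exceeding genome-wide significance.

    Closed form under the mixture: an associated SNP has
    Z ~ Normal(zmean, sqrt(1 + zsd^2)) and is significant when
    |Z| > Phi^-1(1 - threshold/2); null SNPs contribute the threshold
    itself.
    """
    if not 0.0 <= pi1 <= 1.0:
        raise InputValidationError(f"pi1 must be in [0, 1], got {pi1}")
    if not 0.0 < threshold < 1.0:
        raise InputValidationError(f"threshold must be in (0, 1), got {threshold}")
    zc = norm.isf(threshold / 2.0)
    sd = np.sqrt(1.0 + zsd * zsd)
    p_sig = norm.sf((zc - zmean) / sd) + norm.cdf((-zc - zmean) / sd)
    return pi1 * float(p_sig) + (1.0 - pi1) * threshold
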