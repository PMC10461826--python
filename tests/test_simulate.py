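"""Synthetic paired-GWAS generators."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from gpstest import (
    InputValidationError,
    SimSpec,
    expected_gws_fraction,
    simulate_independent_null,
    simulate_ld_blocks,
    simulate_overlap_mixture,
    simulate_pair,
    simulate_shared_effects,
)


class TestIndependentNull:
    def test_deterministic_given_seed(self):
        a = simulate_independent_null(500, seed=4)
        b = simulate_independent_null(500, seed=4)
        np.testing.assert_array_equal(a.u, b.u)
        np.testing.assert_array_equal(a.v, b.v)
        assert a.variant_ids == b.variant_ids

    def test_marginals_uniform_and_independent(self):
        ks_fail = 0
        for i in range(100):
            pair = simulate_independent_null(1000, seed=i)
            if kstest(pair.u, "uniform").pvalue < 0.01:
                ks_fail += 1
        assert ks_fail <= 5  # ≥95/100 seeds pass at the 1% level
        pair = simulate_independent_null(10000, seed=123)
        r = np.corrcoef(pair.u, pair.v)[0, 1]
        assert abs(r) < 3 / np.sqrt(pair.n)

    def test_pvalues_in_half_open_unit_interval(self):
        pair = simulate_independent_null(2000, seed=9)
        for vec in (pair.u, pair.v):
            assert np.all(vec > 0) and np.all(vec <= 1)


class TestOverlapMixture:
    def test_reduces_to_independent_null_in_distribution(self):
        mix = simulate_overlap_mixture(SimSpec(n_snps=5000, seed=1))
        ind = simulate_independent_null(5000, seed=2)
        assert kstest(mix.u, "uniform").pvalue > 0.01
        from scipy.stats import ks_2samp

        assert ks_2samp(mix.u, ind.u).pvalue > 0.01

    def test_null_snp_correlation_matches_rho(self):
        spec = SimSpec(n_snps=20000, pi1_a=0.01, pi1_b=0.01,
                       zmean=3, zsd=1, rho=0.3, seed=5)
        pair = simulate_overlap_mixture(spec)
        # recover z magnitudes; correlation of |z| is attenuated, so check
        # on the z scale via the signed reconstruction of null SNPs only:
        z_a = norm.isf(pair.u / 2)
        z_b = norm.isf(pair.v / 2)
        null_mask = (z_a < 2) & (z_b < 2)  # associated SNPs are mostly large
        r = np.corrcoef(z_a[null_mask], z_b[null_mask])[0, 1]
        # folding destroys sign, corr(|z_a|,|z_b|) ≈ attenuated rho^2 > 0
        assert r > 0

    def test_signed_base_correlation_construction(self):
        """Direct construction check on the base Z draws."""
        rng = np.random.default_rng(0)
        rho = 0.25
        x = rng.standard_normal(50000)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(50000)
        assert abs(np.corrcoef(x, y)[0, 1] - rho) < 3 / np.sqrt(50000)

    def test_associated_fraction_reaches_significance_at_expected_rate(self):
        spec = SimSpec(n_snps=100000, pi1_a=0.05, pi1_b=0.0,
                       zmean=6, zsd=1, seed=8)
        pair = simulate_overlap_mixture(spec)
        frac = np.mean(pair.u < 5e-8)
        expected = expected_gws_fraction(0.05, 6, 1)
        se = np.sqrt(expected * (1 - expected) / pair.n)
        assert abs(frac - expected) < 3 * se

    def test_shared_requested_through_wrong_entry_point(self):
        with pytest.raises(InputValidationError, match="n_shared"):
            simulate_overlap_mixture(
                SimSpec(n_snps=1000, pi1_a=0.1, pi1_b=0.1, n_shared=5)
            )

    def test_disjointness_constraint_enforced(self):
        with pytest.raises(InputValidationError):
            SimSpec(n_snps=100, pi1_a=0.7, pi1_b=0.7)


class TestSharedEffects:
    def test_no_sharing_reduces_to_mixture(self):
        spec = SimSpec(n_snps=3000, pi1_a=0.02, pi1_b=0.02,
                       zmean=4, zsd=1, n_shared=0, seed=3)
        a = simulate_shared_effects(spec)
        b = simulate_overlap_mixture(spec)
        np.testing.assert_array_equal(a.u, b.u)

    def test_shared_snps_share_signal(self):
        spec = SimSpec(n_snps=5000, pi1_a=0.02, pi1_b=0.02, n_shared=100,
                       zmean=6, zsd=0.5, seed=6)
        pair = simulate_shared_effects(spec)
        both_sig = np.sum((pair.u < 5e-8) & (pair.v < 5e-8))
        # ~100 shared SNPs with mean |Z| ≈ 6 should mostly hit in both
        assert both_sig > 30

    def test_n_shared_bounded_by_associated_sets(self):
        with pytest.raises(InputValidationError):
            SimSpec(n_snps=1000, pi1_a=0.01, pi1_b=0.05, n_shared=20)


class TestLdBlocks:
    def test_within_block_correlation_matches_block_r(self):
        spec = SimSpec(n_snps=20000, block_size=10, block_r=0.6, seed=2)
        pair = simulate_ld_blocks(spec)
        z = norm.isf(pair.u / 2)  # |z| magnitudes
        blocks = z[: 20000 // 10 * 10].reshape(-1, 10)
        # adjacent within-block |z| values correlate; across blocks they don't
        within = np.corrcoef(blocks[:, 0], blocks[:, 1])[0, 1]
        across = np.corrcoef(blocks[:-1, 0], blocks[1:, 0])[0, 1]
        assert within > 0.15
        assert abs(across) < 0.1

    def test_block_r_zero_is_unblocked(self):
        spec = SimSpec(n_snps=1000, block_size=10, block_r=0.0, seed=11)
        blocked = simulate_ld_blocks(spec)
        assert kstest(blocked.u, "uniform").pvalue > 0.01

    def test_requires_block_size(self):
        with pytest.raises(InputValidationError):
            simulate_ld_blocks(SimSpec(n_snps=1000))


class TestExpectedGwsFraction:
    def test_null_only_gives_threshold(self):
        assert expected_gws_fraction(0.0, 5, 1) == pytest.approx(5e-8)

    def test_strong_effect_limit(self):
        assert expected_gws_fraction(0.3, 50, 1) == pytest.approx(
            0.3 + 0.7 * 5e-8, rel=1e-6
        )

    def test_monte_carlo_agreement(self):
        pi1, zmean, zsd = 0.02, 5.0, 1.0
        rng = np.random.default_rng(99)
        n = 100000
        n_assoc = int(pi1 * n)
        z = rng.standard_normal(n)
        z[:n_assoc] += rng.normal(zmean, zsd, n_assoc)
        frac = np.mean(2 * norm.sf(np.abs(z)) < 5e-8)
        expected = expected_gws_fraction(pi1, zmean, zsd)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se


class TestDispatch:
    def test_simulate_pair_routes_by_scenario(self):
        assert simulate_pair(SimSpec(n_snps=100, seed=1)).metadata[
            "generator"] == "independent-null"
        assert simulate_pair(SimSpec(n_snps=100, rho=0.2, seed=1)).metadata[
            "generator"] == "z-mixture"
        blocked = simulate_pair(
            SimSpec(n_snps=100, block_size=10, block_r=0.5, seed=1)
        )
        assert blocked.metadata["block_size"] == 10
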