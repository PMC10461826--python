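"""GEV null: CDF conventions, maximum-likelihood fit, p-values."""

import math

import numpy as np
import pytest
from scipy.stats import genextreme

from gpstest import (
    GEVParams,
    InputValidationError,
    fit_gev,
    gev_cdf,
    gev_quantile,
    gps_exp_pvalue,
    gps_gev_pvalue,
)
from gpstest.gev import gev_nll


def _params(a, b, c):
    return GEVParams(location=a, scale=b, shape=c,
                     standard_errors=(0, 0, 0), loglik=0.0, n_fit=0,
                     converged=True)


def _gev_draws(a, b, c, n, seed):
    # scipy's genextreme uses the opposite shape sign
    return genextreme.rvs(-c, loc=a, scale=b, size=n,
                          random_state=np.random.default_rng(seed))


class TestGevCdf:
    @pytest.mark.parametrize("a,b,c", [(0, 1, 0), (2, 0.5, 0.1), (1, 2, -0.2)])
    def test_cdf_at_location_is_exp_minus_one(self, a, b, c):
        assert gev_cdf(a, _params(a, b, c)) == pytest.approx(math.exp(-1))

    def test_gumbel_median(self):
        p = _params(1.0, 0.5, 0.0)
        x = 1.0 - 0.5 * math.log(math.log(2))
        assert gev_cdf(x, p) == pytest.approx(0.5)

    def test_monotone_nondecreasing_on_grid(self):
        for c in (-0.3, 0.0, 0.3):
            p = _params(0.5, 1.2, c)
            vals = gev_cdf(np.linspace(-10, 10, 500), p)
            assert np.all(np.diff(vals) >= 0)
            assert np.all((vals >= 0) & (vals <= 1))

    def test_support_endpoints(self):
        heavy = _params(0.0, 1.0, 0.5)  # lower endpoint a - b/c = -2
        assert gev_cdf(-2.5, heavy) == 0.0
        bounded = _params(0.0, 1.0, -0.5)  # upper endpoint 2
        assert gev_cdf(2.5, bounded) == 1.0

    def test_matches_scipy_convention_bridge(self):
        p = _params(1.3, 0.7, 0.15)
        x = np.linspace(-2, 30, 200)
        ours = gev_cdf(x, p)
        theirs = genextreme.cdf(x, -0.15, loc=1.3, scale=0.7)
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_quantile_inverts_cdf(self):
        p = _params(2.0, 0.5, 0.1)
        for q in (0.01, 0.5, 0.999):
            assert gev_cdf(gev_quantile(q, p), p) == pytest.approx(q)


class TestFitGev:
    def test_parameter_recovery_within_three_se(self):
        x = _gev_draws(2.0, 0.5, 0.1, 3000, seed=42)
        fit = fit_gev(x)
        for est, se, truth in zip(
            (fit.location, fit.scale, fit.shape), fit.standard_errors,
            (2.0, 0.5, 0.1),
        ):
            assert abs(est - truth) < 3 * se
        assert fit.converged
        assert fit.n_fit == 3000

    def test_gumbel_shape_recovered_near_zero(self):
        x = np.random.default_rng(7).gumbel(2.0, 0.5, 3000)
        fit = fit_gev(x)
        assert abs(fit.shape) < 0.1

    def test_loglik_not_worse_than_scipy_mle(self):
        """Independent cross-check: our MLE attains at least scipy's
        genextreme likelihood on the same data."""
        x = _gev_draws(1.0, 0.3, -0.1, 2000, seed=3)
        fit = fit_gev(x)
        c_s, loc_s, scale_s = genextreme.fit(x)
        ll_scipy = np.sum(genextreme.logpdf(x, c_s, loc_s, scale_s))
        assert fit.loglik >= ll_scipy - 1e-3
        # and the fitted CDF at the location parameter is exp(-1)
        assert gev_cdf(fit.location, fit) == pytest.approx(math.exp(-1))

    def test_support_constraint_holds_at_optimum(self):
        x = _gev_draws(2.0, 0.5, -0.2, 1500, seed=9)
        fit = fit_gev(x)
        t = 1.0 + fit.shape * (x - fit.location) / fit.scale
        assert np.all(t > 0)
        assert np.isfinite(gev_nll((fit.location, fit.scale, fit.shape), x))

    def test_rejects_tiny_or_constant_samples(self):
        with pytest.raises(InputValidationError):
            fit_gev(np.ones(3000))
        with pytest.raises(InputValidationError):
            fit_gev(np.random.default_rng(0).gumbel(size=50))


class TestPvalues:
    def test_gev_pvalue_at_location(self):
        p, flags = gps_gev_pvalue(2.0, _params(2.0, 0.5, 0.1))
        assert p == pytest.approx(1 - math.exp(-1))
        assert not flags

    def test_gev_pvalue_beyond_bounded_support_is_flagged_zero(self):
        p, flags = gps_gev_pvalue(10.0, _params(0.0, 1.0, -0.5))
        assert p == 0.0
        assert "p beyond fitted support" in flags

    def test_gev_pvalue_monotone_in_statistic(self):
        params = _params(1.0, 0.4, 0.05)
        ps = [gps_gev_pvalue(d, params)[0] for d in np.linspace(0, 10, 50)]
        assert np.all(np.diff(ps) <= 1e-15)
        assert all(0.0 <= p <= 1.0 for p in ps)

    def test_exp_pvalue_closed_form(self):
        p, _ = gps_exp_pvalue(1.0 / math.sqrt(math.log(2)))
        assert p == pytest.approx(0.5)

    def test_exp_pvalue_limits_and_monotonicity(self):
        assert gps_exp_pvalue(1e6)[0] == pytest.approx(0.0, abs=1e-10)
        p0, flags = gps_exp_pvalue(0.0)
        assert p0 == 1.0 and flags
        ds = np.linspace(0.05, 8, 100)
        ps = [gps_exp_pvalue(d)[0] for d in ds]
        assert np.all(np.diff(ps) <= 0)  # saturates at p = 1 for tiny D
        mid = [gps_exp_pvalue(d)[0] for d in np.linspace(0.5, 8, 50)]
        assert np.all(np.diff(mid) < 0)
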