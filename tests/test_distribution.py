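import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

import tlbhe.distribution as dist
from tlbhe.distribution import Params


class TestParams:
    @pytest.mark.parametrize("pi,alpha", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0), (np.nan, 1.0)])
    def test_invalid_construction(self, pi, alpha):
        with pytest.raises(ValueError):
            Params(pi, alpha)


class TestPdfCdf:
    def test_pdf_point_value(self):
        # high-precision substitution: 2*1*1*e^{-2}*3/8 * [1 - (e^{-1}/2)^2]^0
        assert dist.pdf(1.0, Params(1.0, 1.0)) == pytest.approx(0.75 * math.exp(-2.0), rel=1e-12)

    def test_pdf_at_zero(self):
        assert dist.pdf(0.0, Params(2.5, 1.0)) == pytest.approx(4 * 2.5)
        assert dist.pdf(0.0, Params(2.5, 2.0)) == 0.0

    def test_pdf_negative_x_raises(self):
        with pytest.raises(ValueError):
            dist.pdf(-0.1, Params(1, 1))

    def test_cdf_values(self):
        p = Params(1.0, 1.0)
        assert dist.cdf(0.0, p) == 0.0
        assert dist.cdf(1.0, p) == pytest.approx(1 - (math.exp(-1) / 2) ** 2, abs=1e-9)
        assert dist.cdf(-3.0, p) == 0.0

    def test_pdf_integrates_to_one(self, param_grid):
        for p in param_grid:
            val, _ = integrate.quad(lambda x: dist.pdf(x, p), 0, np.inf, limit=300)
            assert val == pytest.approx(1.0, abs=1e-8), p

    def test_cdf_monotone_and_bounded(self, param_grid):
        x = np.linspace(0, 50, 600)
        for p in param_grid:
            F = dist.cdf(x, p)
            assert np.all(np.diff(F) >= -1e-14)
            assert F.min() >= 0 and F.max() <= 1

    def test_alpha_one_is_min_of_two_bhe(self, rng):
        # cdf identity 1-(1-G)^2 against simulation of the min of two
        # independent BHE draws (BHE inverted with the same Lambert-W trick)
        from scipy.special import lambertw

        pi = 0.8
        p = Params(pi, 1.0)
        n = 10_000
        u = rng.uniform(size=(2, n))
        xb = (lambertw(math.e / (1.0 - u)).real - 1.0) / pi
        mins = xb.min(axis=0)
        d = stats.kstest(mins, lambda v: dist.cdf(v, p))
        assert d.pvalue > 0.01


class TestSfHazard:
    def test_complementarity(self, param_grid):
        x = np.linspace(0, 20, 101)
        for p in param_grid:
            np.testing.assert_allclose(dist.sf(x, p) + dist.cdf(x, p), 1.0, atol=1e-12)

    def test_sf_relative_accuracy_in_tail(self):
        # for alpha=1, sf = r^2 exactly with r = e^{-x}/(1+x); a naive
        # 1 - cdf would lose all precision here, the expm1 path keeps it
        p = Params(1.0, 1.0)
        x = 40.0
        r = math.exp(-x) / (1 + x)
        assert dist.sf(x, p) == pytest.approx(r * r, rel=1e-10)

    def test_hazard_at_zero(self):
        assert dist.hazard(0.0, Params(3.0, 1.0)) == pytest.approx(12.0)

    def test_hazard_decreasing_for_unit_params(self):
        x = np.linspace(1e-3, 3, 200)
        h = dist.hazard(x, Params(1.0, 1.0))
        assert np.all(np.diff(h) < 0)

    def test_hazard_inf_when_sf_underflows(self):
        # sf underflows to exactly 0 far in the tail; hazard flags +inf
        assert dist.hazard(800.0, Params(1.0, 1.0)) == np.inf


class TestQuantile:
    def test_zero(self):
        assert dist.quantile(0.0, Params(2.0, 3.0)) == 0.0

    def test_median_against_bisection_oracle(self):
        p = Params(1.0, 1.0)
        oracle = optimize.brentq(lambda t: dist.cdf(t, p) - 0.5, 1e-12, 100)
        assert oracle == pytest.approx(0.18057, abs=5e-6)
        assert dist.quantile(0.5, p) == pytest.approx(oracle, abs=1e-10)

    def test_roundtrip(self, param_grid):
        for p in param_grid:
            for u in (0.01, 0.25, 0.5, 0.75, 0.99):
                assert dist.cdf(dist.quantile(u, p), p) == pytest.approx(u, abs=1e-10)

    def test_quantile_cdf_identity(self, param_grid):
        for p in param_grid:
            x = np.array([0.05, 0.3, 1.0, 4.0]) / p.pi
            np.testing.assert_allclose(dist.quantile(dist.cdf(x, p), p), x, rtol=1e-8)

    @pytest.mark.parametrize("u", [-0.01, 1.0, 1.5])
    def test_domain_errors(self, u):
        with pytest.raises(ValueError):
            dist.quantile(u, Params(1, 1))

    @given(
        u=st.floats(1e-6, 1 - 1e-9),
        pi=st.floats(0.05, 20.0),
        alpha=st.floats(0.05, 50.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_property(self, u, pi, alpha):
        p = Params(pi, alpha)
        assert dist.cdf(dist.quantile(u, p), p) == pytest.approx(u, abs=1e-8)


class TestRvs:
    def test_deterministic(self):
        p = Params(0.5, 2.0)
        a = dist.rvs(100, p, seed=7)
        b = dist.rvs(100, p, seed=7)
        np.testing.assert_array_equal(a, b)
        assert np.all(a > 0)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            dist.rvs(0, Params(1, 1))

    def test_one_sample_ks(self):
        p = Params(1.0, 1.0)
        x = dist.rvs(10_000, p, seed=11)
        assert stats.kstest(x, lambda v: dist.cdf(v, p)).pvalue > 0.01


class TestRvsAr:
    def test_matches_inverse_transform(self):
        p = Params(1.0, 1.0)
        # moment-matched Weibull envelope
        x_ref = dist.rvs(5000, p, seed=3)
        x_ar = dist.rvs_ar(5000, p, envelope_shape=1.0, envelope_rate=1.2, seed=4)
        assert stats.ks_2samp(x_ar, x_ref).pvalue > 0.01

    def test_acceptance_rate_is_inverse_bound(self):
        p = Params(1.0, 1.0)
        x, info = dist.rvs_ar(20_000, p, 1.0, 1.2, seed=5, return_info=True)
        assert info["acceptance_rate"] == pytest.approx(1.0 / info["rejection_constant"], rel=0.05)

    def test_deterministic(self):
        p = Params(0.7, 1.5)
        a = dist.rvs_ar(500, p, 0.9, 1.0, seed=9)
        b = dist.rvs_ar(500, p, 0.9, 1.0, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_bad_envelope_rejected(self):
        # steep Weibull tail (shape 3) decays faster than the target density
        with pytest.raises(ValueError):
            dist.rvs_ar(10, Params(0.2, 1.0), envelope_shape=3.0, envelope_rate=1.0, seed=0)


class TestMoments:
    def test_zeroth_moment(self):
        assert dist.raw_moment(0, Params(0.3, 4.0)) == pytest.approx(1.0, abs=1e-9)

    def test_mean_against_monte_carlo(self):
        p = Params(1.0, 1.0)
        x = dist.rvs(1_000_000, p, seed=21)
        se = x.std(ddof=1) / math.sqrt(x.size)
        assert abs(dist.raw_moment(1, p) - x.mean()) < 3 * se

    def test_variance_nonnegative(self, param_grid):
        for p in param_grid:
            m1 = dist.raw_moment(1, p)
            m2 = dist.raw_moment(2, p)
            assert m2 - m1**2 >= 0

    def test_series_honest_about_convergence(self, param_grid):
        # whenever the truncated series claims convergence it must agree
        # with quadrature; divergence must be flagged, never silent
        for p in param_grid:
            value, tail, converged = dist.raw_moment_series(1, p)
            if converged:
                quad = dist.raw_moment(1, p)
                assert value == pytest.approx(quad, rel=1e-3, abs=1e-5)

    def test_series_method_raises_on_divergence(self):
        p = Params(0.1, 10.0)
        value, tail, converged = dist.raw_moment_series(1, p)
        if not converged:
            with pytest.raises(ArithmeticError):
                dist.raw_moment(1, p, method="series")


class TestMgfCharfunc:
    def test_mgf_at_zero(self):
        assert dist.mgf(0.0, Params(2.0, 0.5)) == 1.0

    def test_mgf_derivative_is_mean(self):
        p = Params(1.0, 2.0)
        h = 1e-5
        num = (dist.mgf(h, p) - dist.mgf(-h, p)) / (2 * h)
        assert num == pytest.approx(dist.raw_moment(1, p), rel=1e-6)

    def test_mgf_divergence_error(self):
        with pytest.raises(ValueError):
            dist.mgf(2.0, Params(1.0, 1.0))

    def test_charfunc_modulus_bounded(self):
        p = Params(0.5, 1.5)
        for t in (-3.0, -0.5, 0.0, 0.5, 3.0, 10.0):
            assert abs(dist.charfunc(t, p)) <= 1.0 + 1e-8


class TestEntropy:
    def test_shannon_limit(self):
        p = Params(1.0, 1.0)
        assert dist.renyi_entropy(1 + 1e-4, p) == pytest.approx(dist.shannon_entropy(p), abs=1e-3)

    def test_order_two_definition(self):
        p = Params(0.5, 2.0)
        val, _ = integrate.quad(lambda x: dist.pdf(x, p) ** 2, 0, np.inf, limit=300)
        assert dist.renyi_entropy(2.0, p) == pytest.approx(-math.log(val), abs=1e-8)

    def test_monotone_in_order(self):
        p = Params(1.0, 2.0)
        vals = [dist.renyi_entropy(nu, p) for nu in (0.5, 2.0, 5.0)]
        assert vals[0] >= vals[1] >= vals[2]

    def test_nu_one_raises(self):
        with pytest.raises(ValueError):
            dist.renyi_entropy(1.0, Params(1, 1))


class TestOrderStatistics:
    def test_s1_n1_is_pdf(self):
        p = Params(0.7, 1.5)
        x = np.linspace(0.01, 5, 50)
        np.testing.assert_allclose(dist.order_stat_pdf(1, 1, x, p), dist.pdf(x, p), rtol=1e-12)

    @pytest.mark.parametrize("s,n", [(1, 5), (3, 5), (5, 5)])
    def test_normalization(self, s, n):
        p = Params(1.0, 1.0)
        val, _ = integrate.quad(lambda x: dist.order_stat_pdf(s, n, x, p), 0, np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=1e-7)

    def test_maximum_cdf_identity(self):
        p = Params(1.0, 2.0)
        n = 5
        for x in (0.3, 0.8, 2.0):
            num, _ = integrate.quad(lambda t: dist.order_stat_pdf(n, n, t, p), 0, x)
            assert num == pytest.approx(dist.cdf(x, p) ** n, abs=1e-8)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            dist.order_stat_pdf(0, 5, 1.0, Params(1, 1))
        with pytest.raises(ValueError):
            dist.order_stat_pdf(6, 5, 1.0, Params(1, 1))
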