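"""Closed-form correctness of the DUS-TLE distribution functions.

Frozen expected values were computed independently with 40-digit
arithmetic from the defining closed forms (DUS transform of the
Topp-Leone-exponential CDF), not from the code under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from dustl import DUSTLE, dus_tl_cdf, dus_tl_pdf, exponential_baseline

# 40-digit-arithmetic oracles at (nu, rho) = (1, 0.5), x = 1 / u = 0.5
CDF_ORACLE = 0.5130685624035615
PDF_ORACLE = 0.4028446417175416
Q_ORACLE = 0.9678854057726787
HAZ_ORACLE = 0.8273128629895802


class TestClosedFormOracles:
    def test_cdf_value(self):
        assert DUSTLE(1.0, 0.5).cdf(1.0) == pytest.approx(CDF_ORACLE, abs=1e-12)

    def test_pdf_value(self):
        assert DUSTLE(1.0, 0.5).pdf(1.0) == pytest.approx(PDF_ORACLE, abs=1e-12)

    def test_quantile_value(self):
        assert DUSTLE(1.0, 0.5).ppf(0.5) == pytest.approx(Q_ORACLE, abs=1e-12)

    def test_hazard_value(self):
        assert DUSTLE(1.0, 0.5).hazard(1.0) == pytest.approx(HAZ_ORACLE, abs=1e-10)


class TestCDF:
    def test_boundary_values(self):
        d = DUSTLE(1.75, 2.75)
        assert d.cdf(0.0) == 0.0
        assert d.cdf(-1.0) == 0.0
        assert d.cdf(1e6) == pytest.approx(1.0, abs=1e-15)

    def test_monotone_and_bounded(self, param_grid):
        x = np.geomspace(1e-6, 50, 400)
        for nu, rho in param_grid:
            F = DUSTLE(nu, rho).cdf(x)
            assert np.all(np.diff(F) >= 0)
            assert F.min() >= 0 and F.max() <= 1

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            DUSTLE(-1.0, 0.5)
        with pytest.raises(ValueError):
            DUSTLE(1.0, 0.0)
        with pytest.raises(ValueError):
            DUSTLE(1.0, 1.0).cdf(np.nan)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        nu=st.floats(0.1, 8.0),
        rho=st.floats(0.05, 10.0),
        x=st.floats(1e-8, 100.0),
        dx=st.floats(1e-8, 10.0),
    )
    def test_monotonicity_property(self, nu, rho, x, dx):
        d = DUSTLE(nu, rho)
        a, b = d.cdf([x, x + dx])
        assert 0.0 <= a <= b <= 1.0


class TestGenericGenerator:
    def test_exponential_baseline_reproduces_dustle(self, param_grid):
        """The generic generator with an exponential baseline must agree
        with the specialised DUS-TLE code to near machine precision."""
        x = np.geomspace(0.01, 20, 200)
        for nu, rho in param_grid:
            base = exponential_baseline(rho)
            d = DUSTLE(nu, rho)
            np.testing.assert_allclose(dus_tl_cdf(x, nu, base), d.cdf(x), atol=1e-12)
            # densities agree to machine precision away from the saturated
            # tail, where the generic path's 1-(1-G)^2 cancels
            m = d.cdf(x) < 1 - 1e-9
            np.testing.assert_allclose(
                dus_tl_pdf(x[m], nu, base), d.pdf(x[m]), rtol=1e-11
            )

    def test_generic_oracle_value(self):
        # nu=1, Exp(1) baseline at x=0.5: H = 1 - e^{-1}, frozen 40-digit value
        got = dus_tl_cdf(0.5, 1.0, exponential_baseline(1.0))
        assert got == pytest.approx(0.5130685624035615, abs=1e-12)

    def test_nu_one_reduces_to_dus_of_exp2rho(self):
        """At nu=1 the TL layer is the CDF of Exp(2 rho), so F is its plain
        DUS transform (e^G - 1)/(e - 1)."""
        rho = 0.7
        x = np.linspace(0.01, 8, 100)
        G = -np.expm1(-2 * rho * x)
        expected = np.expm1(G) / (math.e - 1)
        np.testing.assert_allclose(DUSTLE(1.0, rho).cdf(x), expected, atol=1e-14)

    def test_weibull_baseline_contract(self):
        """A non-exponential baseline exercises the generic contract."""
        from dustl import Baseline

        k = 1.5
        base = Baseline(
            cdf=lambda x: -np.expm1(-np.asarray(x) ** k),
            pdf=lambda x: k * np.asarray(x) ** (k - 1) * np.exp(-np.asarray(x) ** k),
        )
        val, _ = integrate.quad(lambda x: dus_tl_pdf(x, 2.0, base), 0, 50, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)
        F = dus_tl_cdf(np.linspace(0.01, 5, 50), 2.0, base)
        assert np.all(np.diff(F) >= 0)


class TestPDF:
    def test_normalization(self, param_grid):
        for nu, rho in param_grid:
            d = DUSTLE(nu, rho)
            val, _ = integrate.quad(d.pdf, 0, float(d.ppf(1 - 1e-13)), limit=200)
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_matches_cdf_derivative(self):
        d = DUSTLE(1.75, 2.75)
        x = np.linspace(0.05, 2.0, 50)
        h = 1e-6
        num = (d.cdf(x + h) - d.cdf(x - h)) / (2 * h)
        np.testing.assert_allclose(d.pdf(x), num, rtol=1e-6)

    def test_vanishing_tails_for_nu_gt_1(self):
        for nu, rho in [(1.2, 1.0), (2.75, 1.5), (5.0, 0.5)]:
            d = DUSTLE(nu, rho)
            # origin: density decreases monotonically to 0 as x -> 0+
            assert d.pdf(1e-250) < 1e-30
            assert d.pdf(1e-60) < d.pdf(1e-30) < d.pdf(1e-10)
            # far tail: exponential decay wins
            assert d.pdf(1e4 / rho) == 0.0 or d.pdf(1e4 / rho) < 1e-300

    def test_single_interior_mode_for_nu_gt_1(self):
        x = np.geomspace(1e-4, 30, 3000)
        for nu, rho in [(1.2, 0.8), (1.75, 2.75), (2.75, 1.5), (4.0, 1.0)]:
            f = DUSTLE(nu, rho).pdf(x)
            signs = np.sign(np.diff(f))
            changes = np.flatnonzero(np.diff(signs[signs != 0]) != 0)
            assert len(changes) == 1  # rises once, falls once

    def test_zero_for_nonpositive_x(self):
        d = DUSTLE(0.5, 1.0)  # nu < 1: density diverges at 0+, still 0 at x <= 0
        assert d.pdf(0.0) == 0.0
        assert d.pdf(-3.0) == 0.0


class TestLogPDF:
    def test_exp_logpdf_is_pdf_on_grid(self, param_grid):
        x = np.geomspace(0.01, 20, 100)
        for nu, rho in param_grid:
            d = DUSTLE(nu, rho)
            pdf = d.pdf(x)
            mask = pdf > 1e-300
            np.testing.assert_allclose(np.exp(d.logpdf(x[mask])), pdf[mask], rtol=1e-12)

    def test_no_overflow_deep_in_tail(self):
        d = DUSTLE(1.75, 0.5)
        v = d.logpdf(700.0)  # 2 rho x = 700
        assert np.isfinite(v) and v < -600

    def test_loglik_of_tfp_at_published_mle(self, tfp):
        """The summed log density over the productivity data at the
        published estimates reproduces the published -53.58."""
        d = DUSTLE(1.5482, 0.4679)
        assert float(np.sum(d.logpdf(tfp.values))) == pytest.approx(-53.58, abs=0.01)


class TestHazard:
    def test_equals_pdf_over_sf(self, param_grid):
        x = np.geomspace(0.05, 10, 60)
        for nu, rho in param_grid:
            d = DUSTLE(nu, rho)
            F = d.cdf(x)
            mask = F < 1 - 1e-5  # where the naive 1-F keeps ~1e-11 accuracy
            expected = d.pdf(x[mask]) / (1.0 - F[mask])
            np.testing.assert_allclose(d.hazard(x[mask]), expected, rtol=1e-10)

    def test_stable_where_cdf_saturates(self):
        d = DUSTLE(1.0, 0.5)
        x = 60.0  # cdf rounds to 1 in double precision
        assert d.cdf(x) == 1.0
        h = float(d.hazard(x))
        assert np.isfinite(h) and h > 0
        # for nu=1 the hazard tends to the exponential-tail constant 2 rho
        assert h == pytest.approx(2 * 0.5, rel=1e-3)

    def test_nonnegative(self):
        x = np.geomspace(1e-4, 30, 200)
        assert np.all(DUSTLE(2.5, 1.25).hazard(x) >= 0)


class TestQuantile:
    def test_zero_maps_to_zero(self):
        assert DUSTLE(1.75, 2.75).ppf(0.0) == 0.0

    def test_round_trip_deciles(self, param_grid):
        u = np.arange(0.1, 1.0, 0.1)
        for nu, rho in param_grid:
            d = DUSTLE(nu, rho)
            np.testing.assert_allclose(d.cdf(d.ppf(u)), u, atol=1e-10)

    def test_domain_errors(self):
        d = DUSTLE(1.0, 1.0)
        for bad in (-0.1, 1.0, 1.5, np.nan):
            with pytest.raises(ValueError):
                d.ppf(bad)

    def test_scale_equivariance_in_rho(self):
        """rho enters only through rho*x: q(u; nu, c rho) = q(u; nu, rho)/c."""
        u = np.linspace(0.05, 0.95, 19)
        c = 3.7
        q1 = DUSTLE(1.75, 2.75).ppf(u)
        q2 = DUSTLE(1.75, 2.75 * c).ppf(u)
        np.testing.assert_allclose(q2, q1 / c, rtol=1e-12)


class TestSampling:
    def test_seed_determinism(self):
        d = DUSTLE(1.75, 2.75)
        np.testing.assert_array_equal(d.rvs(1000, seed=42), d.rvs(1000, seed=42))
        assert not np.array_equal(d.rvs(1000, seed=42), d.rvs(1000, seed=43))

    def test_all_draws_positive(self):
        assert np.all(DUSTLE(0.5, 2.0).rvs(10_000, seed=7) > 0)

    def test_ks_against_cdf(self):
        n = 100_000
        d = DUSTLE(1.75, 2.75)
        x = d.rvs(n, seed=11)
        D = stats.kstest(x, d.cdf).statistic
        assert D < 1.63 / math.sqrt(n)  # alpha = 0.01 asymptotic band

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            DUSTLE(1.0, 1.0).rvs(0)
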