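"""Ex-Gaussian density, likelihood and ML fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from rtnoise import (
    ExGauss,
    ExGaussParams,
    exgauss_fit,
    exgauss_loglik,
    exgauss_logpdf,
    exgauss_pdf,
    exgauss_rvs,
)


def convolution_pdf(x, mu, sigma, tau):
    """Brute-force numerical convolution of normal(mu, sigma) with exponential(tau)."""
    val, _ = quad(
        lambda y: stats.norm.pdf(y, mu, sigma) * stats.expon.pdf(x - y, scale=tau),
        mu - 12 * sigma,
        x,
        limit=300,
    )
    return val


class TestDensity:
    def test_matches_quadrature_convolution(self, fig1_params):
        p = fig1_params
        expected = convolution_pdf(520.0, p.mu, p.sigma, p.tau)
        got = exgauss_pdf(520.0, p)[()]
        assert got == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("mu", [450.0, 550.0])
    @pytest.mark.parametrize("sigma", [25.0, 75.0])
    @pytest.mark.parametrize("tau", [50.0, 150.0])
    def test_normalization_on_prior_grid(self, mu, sigma, tau):
        p = ExGaussParams(mu, sigma, tau)
        total, _ = quad(lambda x: exgauss_pdf(x, p)[()], mu - 12 * sigma, mu + 40 * tau, limit=400)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_mean_by_integration(self, fig1_params):
        p = fig1_params
        mean, _ = quad(lambda x: x * exgauss_pdf(x, p)[()], p.mu - 12 * p.sigma, p.mu + 40 * p.tau, limit=400)
        assert mean == pytest.approx(600.0, rel=1e-7)

    def test_normal_limit_as_tau_vanishes(self):
        # the leading small-tau correction is a mean shift of exactly tau, so
        # the tau-shifted normal agrees to O((tau/sigma)^2) while the unshifted
        # normal is approached linearly in tau
        mu, sigma = 500.0, 50.0
        tau = 1e-3 * sigma
        p = ExGaussParams(mu, sigma, tau)
        x = np.linspace(mu - 3 * sigma, mu + 3 * sigma, 61)
        np.testing.assert_allclose(exgauss_pdf(x, p), stats.norm.pdf(x, mu + tau, sigma), rtol=1e-4)
        np.testing.assert_allclose(exgauss_pdf(x, p), stats.norm.pdf(x, mu, sigma), rtol=5e-3)

    def test_cross_check_against_exponnorm(self, fig1_params):
        # scipy's exponentially-modified normal: K = tau / sigma
        p = fig1_params
        x = np.linspace(200.0, 1800.0, 200)
        ref = stats.exponnorm.logpdf(x, p.tau / p.sigma, loc=p.mu, scale=p.sigma)
        np.testing.assert_allclose(exgauss_logpdf(x, p), ref, rtol=1e-9)

    def test_stable_far_into_both_tails(self):
        # 10 SD each way, plus a small-tau regime where the naive formula overflows
        for p in (ExGaussParams(500.0, 50.0, 100.0), ExGaussParams(500.0, 75.0, 1.0)):
            sd = math.sqrt(p.var)
            x = np.array([p.mean - 10 * sd, p.mean + 10 * sd, p.mean + 40 * sd])
            lp = exgauss_logpdf(x, p)
            assert np.all(np.isfinite(lp))

    def test_invalid_inputs_rejected(self, fig1_params):
        with pytest.raises(ValueError):
            exgauss_pdf(np.array([np.nan]), fig1_params)
        with pytest.raises(ValueError):
            ExGaussParams(500.0, -1.0, 100.0)
        with pytest.raises(ValueError):
            ExGaussParams(500.0, 50.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        x=st.floats(0.0, 3000.0),
        mu=st.floats(300.0, 700.0),
        sigma=st.floats(5.0, 200.0),
        tau=st.floats(5.0, 400.0),
    )
    def test_logpdf_always_finite_in_sane_region(self, x, mu, sigma, tau):
        lp = exgauss_logpdf(np.array([x]), ExGaussParams(mu, sigma, tau))
        assert np.isfinite(lp).all()


class TestLoglik:
    def test_single_point_equals_log_pdf(self, fig1_params):
        x = fig1_params.mean
        assert exgauss_loglik([x], fig1_params) == pytest.approx(
            math.log(convolution_pdf(x, *fig1_params.as_array())), rel=1e-6
        )

    def test_duplicating_data_doubles_loglik(self, fig1_params, rt_sample):
        ll = exgauss_loglik(rt_sample, fig1_params)
        assert exgauss_loglik(np.concatenate([rt_sample, rt_sample]), fig1_params) == pytest.approx(2 * ll)

    def test_maximized_near_generating_mu_on_grid(self, fig1_params, rt_sample):
        grid = np.arange(400.0, 620.0, 20.0)
        lls = [exgauss_loglik(rt_sample, ExGaussParams(m, 50.0, 100.0)) for m in grid]
        assert abs(grid[int(np.argmax(lls))] - fig1_params.mu) <= 20.0

    def test_empty_data_rejected(self, fig1_params):
        with pytest.raises(ValueError):
            exgauss_loglik([], fig1_params)


class TestFit:
    def test_large_sample_recovery(self, fig1_params):
        rng = np.random.default_rng(4242)
        data = exgauss_rvs(fig1_params, 100_000, rng)
        res = exgauss_fit(data)
        assert res.converged
        np.testing.assert_allclose(res.params.as_array(), fig1_params.as_array(), rtol=0.02)

    def test_deterministic_for_identical_input(self, rt_sample):
        r1 = exgauss_fit(rt_sample)
        r2 = exgauss_fit(rt_sample.copy())
        assert r1.params == r2.params and r1.loglik == r2.loglik

    def test_refit_from_optimum_is_idempotent(self, rt_sample):
        r1 = exgauss_fit(rt_sample)
        r2 = ExGauss(rt_sample).fit(start=r1.params)
        assert r2.loglik >= r1.loglik - 1e-6

    def test_moment_identities_of_params(self, rt_sample):
        p = exgauss_fit(rt_sample).params
        assert p.mean == p.mu + p.tau
        assert p.var == p.sigma**2 + p.tau**2

    def test_degenerate_and_short_data_rejected(self):
        with pytest.raises(ValueError):
            ExGauss(np.full(100, 500.0))
        with pytest.raises(ValueError):
            ExGauss(np.arange(5, dtype=float) + 500.0)
        with pytest.raises(ValueError):
            ExGauss(np.array([500.0, np.inf] + [510.0] * 10))

    def test_summary_table_shape(self, rt_sample):
        tab = exgauss_fit(rt_sample).summary()
        assert list(tab.index) == ["mu", "sigma", "tau"]
        assert "loglik" in tab.columns
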