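"""Ex-Gaussian density, moments, likelihood machinery, and the MLE."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import exgauss_rt as xg
from exgauss_rt.exgauss import InsufficientDataError, ParameterError
from exgauss_rt.preprocess import compute_sample_stats

PARAM_GRID = [
    xg.ExGaussParams(0.0, 1.0, 1.0),
    xg.ExGaussParams(417.56, 18.72, 227.72),
    xg.ExGaussParams(502.44, 87.16, 292.10),
    xg.ExGaussParams(-50.0, 200.0, 30.0),
]


class TestDensity:
    def test_rejects_invalid_parameters(self):
        for mu, sigma, tau in [(0, -1, 1), (0, 1, 0), (math.nan, 1, 1)]:
            with pytest.raises(ParameterError):
                xg.ExGaussParams(mu, sigma, tau)

    def test_standard_value(self):
        # closed form e^0.5 * Phi(-1), frozen from the normal-CDF oracle
        assert xg.exgauss_pdf(0.0, xg.ExGaussParams(0, 1, 1)) == pytest.approx(
            0.26157829186512344, rel=1e-12
        )

    def test_vanishing_sigma_is_shifted_exponential(self):
        p = xg.ExGaussParams(0.0, 1e-6, 100.0)
        assert xg.exgauss_pdf(100.0, p) == pytest.approx(math.exp(-1) / 100.0, rel=1e-6)

    @pytest.mark.parametrize("p", PARAM_GRID)
    def test_matches_exponnorm_oracle(self, p):
        x = np.linspace(p.mu - 4 * p.sigma, p.mu + 4 * p.sigma + 8 * p.tau, 200)
        ours = xg.exgauss_pdf(x, p)
        ref = stats.exponnorm.pdf(x, K=p.tau / p.sigma, loc=p.mu, scale=p.sigma)
        np.testing.assert_allclose(ours, ref, rtol=1e-9, atol=1e-300)

    @pytest.mark.parametrize(
        "p",
        PARAM_GRID + [xg.ExGaussParams(500.0, 100.0, 0.1)],  # sigma/tau = 1e3
    )
    def test_integrates_to_one(self, p):
        lo = p.mu - 12 * p.sigma
        hi = p.mu + 12 * p.sigma + 40 * p.tau
        total, err = integrate.quad(lambda v: xg.exgauss_pdf(v, p), lo, hi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestCDF:
    @pytest.mark.parametrize("p", PARAM_GRID)
    def test_limits_and_monotonicity(self, p):
        x = np.linspace(p.mu - 10 * p.sigma, p.mu + 10 * p.sigma + 30 * p.tau, 400)
        F = xg.exgauss_cdf(x, p)
        assert F[0] < 1e-9
        assert F[-1] > 1 - 1e-9
        assert np.all(np.diff(F) >= 0)

    @pytest.mark.parametrize("p", PARAM_GRID)
    def test_derivative_matches_pdf(self, p):
        x = np.linspace(p.mu - 2 * p.sigma, p.mu + 2 * p.sigma + 5 * p.tau, 50)
        h = 1e-5 * (p.sigma + p.tau)
        fd = (xg.exgauss_cdf(x + h, p) - xg.exgauss_cdf(x - h, p)) / (2 * h)
        np.testing.assert_allclose(fd, xg.exgauss_pdf(x, p), rtol=1e-6, atol=1e-12)

    def test_empirical_cdf_of_large_sample(self):
        p = xg.ExGaussParams(450.0, 60.0, 230.0)
        x = np.sort(xg.sample_exgauss(p, 1_000_000, seed=8))
        F = xg.exgauss_cdf(x, p)
        ecdf_hi = np.arange(1, x.size + 1) / x.size
        gap = max(np.abs(ecdf_hi - F).max(), np.abs(F - (ecdf_hi - 1 / x.size)).max())
        assert gap < 0.002


class TestMoments:
    def test_three_four_five(self):
        mean, sd, _ = xg.exgauss_moments(xg.ExGaussParams(0.0, 3.0, 4.0))
        assert (mean, sd) == (4.0, 5.0)

    def test_gaussian_limit_has_no_skew(self):
        *_, skew = xg.exgauss_moments(xg.ExGaussParams(0.0, 1.0, 1e-4))
        assert skew == pytest.approx(0.0, abs=1e-10)

    def test_skewness_of_reference_row_prints_as_sample_t(self, condition_table):
        key = xg.ConditionKey("face", "spain", "test", "identity")
        *_, skew = xg.exgauss_moments(condition_table[key].params)
        assert round(skew, 2) == 1.98


class TestMomentStart:
    def test_plug_in_arithmetic(self):
        start = xg.moment_start(xg.SampleStats(n=100, M=645.57, S=228.38, t=1.98))
        assert start.mu == pytest.approx(417.9538184144313)
        assert start.sigma == pytest.approx(18.662751147818017)
        assert start.tau == pytest.approx(227.61618158556877)

    def test_boundary_skew_floors_sigma(self):
        start = xg.moment_start(xg.SampleStats(n=100, M=600.0, S=200.0, t=2.0))
        assert start.tau == pytest.approx(200.0)
        assert start.sigma == pytest.approx(0.05 * 200.0)

    def test_nonpositive_skew_gives_gaussian_dominant_start(self):
        start = xg.moment_start(xg.SampleStats(n=100, M=600.0, S=200.0, t=-0.3))
        assert start.tau == pytest.approx(20.0)
        assert start.sigma == pytest.approx(math.sqrt(200.0**2 - 20.0**2))
        assert start.mu == pytest.approx(580.0)


class TestLikelihood:
    def test_single_point_value(self):
        ll = xg.log_likelihood([0.0], xg.ExGaussParams(0, 1, 1))
        assert ll == pytest.approx(-1.3410216450092634, rel=1e-12)

    def test_duplication_doubles(self, rng):
        p = xg.ExGaussParams(450, 60, 230)
        x = xg.sample_exgauss(p, 50, seed=rng)
        assert xg.log_likelihood(np.tile(x, 2), p) == pytest.approx(
            2 * xg.log_likelihood(x, p), rel=1e-12
        )

    def test_log_domain_agrees_with_naive_product(self, rng):
        p = xg.ExGaussParams(450, 60, 230)
        x = xg.sample_exgauss(p, 200, seed=rng)
        naive = float(np.sum(np.log(xg.exgauss_pdf(x, p))))
        assert xg.log_likelihood(x, p) == pytest.approx(naive, rel=1e-9)


class TestGradient:
    @pytest.mark.parametrize("p", PARAM_GRID[1:])
    def test_matches_finite_differences(self, p, rng):
        x = xg.sample_exgauss(p, 300, seed=rng)
        g = xg.log_likelihood_gradient(x, p)
        theta = p.as_array()
        for j in range(3):
            h = 1e-6 * max(abs(theta[j]), 1.0)
            hi, lo = theta.copy(), theta.copy()
            hi[j] += h
            lo[j] -= h
            fd = (
                xg.log_likelihood(x, xg.ExGaussParams(*hi))
                - xg.log_likelihood(x, xg.ExGaussParams(*lo))
            ) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=1e-5)

    def test_translation_invariance(self, rng):
        p = xg.ExGaussParams(450, 60, 230)
        x = xg.sample_exgauss(p, 200, seed=rng)
        g1 = xg.log_likelihood_gradient(x, p)
        g2 = xg.log_likelihood_gradient(x + 1000.0, xg.ExGaussParams(1450, 60, 230))
        np.testing.assert_allclose(g1, g2, rtol=1e-7, atol=1e-9)


class TestFit:
    def test_recovers_truth_within_asymptotic_error(self):
        truth = xg.ExGaussParams(400.0, 50.0, 200.0)
        x = xg.sample_exgauss(truth, 5000, seed=314)
        fit = xg.fit_mle(x)
        assert fit.converged
        assert fit.gradient_norm < 1e-8
        cov = np.linalg.inv(-xg.numerical_hessian(x, fit.params))
        se = np.sqrt(np.diag(cov))
        np.testing.assert_array_less(
            np.abs(fit.params.as_array() - truth.as_array()), 3 * se
        )

    def test_ascent_never_loses_likelihood(self):
        x = xg.sample_exgauss(xg.ExGaussParams(450, 60, 230), 400, seed=5)
        fit = xg.fit_mle(x)
        assert fit.log_likelihood >= xg.log_likelihood(x, fit.start)

    def test_translation_equivariance(self):
        x = xg.sample_exgauss(xg.ExGaussParams(450, 60, 230), 800, seed=77)
        a, b = xg.fit_mle(x), xg.fit_mle(x + 500.0)
        assert b.params.mu - a.params.mu == pytest.approx(500.0, abs=1e-6)
        assert b.params.sigma == pytest.approx(a.params.sigma, abs=1e-6)
        assert b.params.tau == pytest.approx(a.params.tau, abs=1e-6)

    def test_explicit_start_is_honoured(self):
        x = xg.sample_exgauss(xg.ExGaussParams(450, 60, 230), 400, seed=6)
        start = xg.ExGaussParams(600.0, 100.0, 100.0)
        fit = xg.fit_mle(x, start=start)
        assert fit.start == start
        assert fit.converged

    def test_small_or_constant_samples_refused(self):
        with pytest.raises(InsufficientDataError):
            xg.fit_mle(np.arange(9, dtype=float) + 300)
        with pytest.raises(InsufficientDataError):
            xg.fit_mle(np.full(50, 400.0))

    def test_dispersion_shrinks_with_sample_size(self):
        truth = xg.ExGaussParams(450.0, 60.0, 230.0)
        spread = {}
        for n in (250, 4000):
            mus = [
                xg.fit_mle(xg.sample_exgauss(truth, n, seed=1000 * n + k)).params.mu
                for k in range(12)
            ]
            spread[n] = np.std(mus)
        # 16x the data should shrink the sd about 4x; allow wide slack
        assert spread[4000] < 0.6 * spread[250]


class TestSampling:
    def test_moment_identities_at_large_n(self):
        x = xg.sample_exgauss(xg.ExGaussParams(0, 1, 1), 1_000_000, seed=13)
        assert abs(x.mean() - 1.0) < 3 * x.std() / 1000.0
        sd_se = x.std() / math.sqrt(2 * (x.size - 1))
        assert abs(x.std() - math.sqrt(2.0)) < 4 * sd_se

    def test_seeded_reproducibility(self):
        p = xg.ExGaussParams(450, 60, 230)
        np.testing.assert_array_equal(
            xg.sample_exgauss(p, 100, seed=21), xg.sample_exgauss(p, 100, seed=21)
        )

    def test_ks_of_sample_against_generator(self):
        p = xg.ExGaussParams(450, 60, 230)
        n = 1000
        crit = 1.63 / math.sqrt(n)  # asymptotic 1% point of the KS null
        exceed = sum(
            xg.ks_statistic(xg.sample_exgauss(p, n, seed=40_000 + k), p) > crit
            for k in range(200)
        )
        assert exceed <= 6  # binomial(200, 0.01) upper tail
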