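import numpy as np
import pytest
from scipy.stats import nbinom, poisson

from countgp.experiments import nb_oracle_log_pmf, zinb_oracle_log_pmf
from countgp.likelihoods import (
    LikelihoodSpec,
    nb_log_pmf,
    poisson_log_pmf,
    transform_counts,
    variational_expectation,
    zinb_log_pmf,
)


class TestNB:
    def test_zero_count_closed_form(self):
        # first Gamma factor is 1 at y=0
        assert np.isclose(nb_log_pmf(0, 5.0, 2.0), 2.0 * (np.log(2.0) - np.log(7.0)))

    def test_matches_gamma_recurrence_oracle(self):
        ys = np.arange(0, 11)
        got = nb_log_pmf(ys, 3.0, 2.0)
        want = np.array([nb_oracle_log_pmf(int(t), 3.0, 2.0) for t in ys])
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_matches_scipy_parameterization(self, rng):
        for _ in range(10):
            mu, r = rng.uniform(0.5, 30), rng.uniform(0.2, 10)
            y = np.arange(0, 25)
            np.testing.assert_allclose(
                nb_log_pmf(y, mu, r), nbinom.logpmf(y, r, r / (r + mu)), atol=1e-10)

    def test_sums_to_one(self):
        y = np.arange(0, 5000)
        assert abs(np.exp(nb_log_pmf(y, 3.0, 2.0)).sum() - 1.0) < 1e-8

    def test_poisson_limit(self):
        y = np.arange(0, 60)
        tv = 0.5 * np.abs(np.exp(nb_log_pmf(y, 4.0, 1e6)) - poisson.pmf(y, 4.0)).sum()
        assert tv < 1e-4

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_log_pmf(-1, 3.0, 2.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1.5, 3.0, 2.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1, -3.0, 2.0)

    def test_no_overflow_at_extremes(self):
        vals = [nb_log_pmf(10**6, 10**6, 0.5), nb_log_pmf(0, 10**6, 2.0),
                zinb_log_pmf(10**6, 10**6, 0.5, 1.0),
                poisson_log_pmf(10**6, 10**6)]
        assert np.all(np.isfinite(vals))

    def test_variance_identity_on_samples(self, rng):
        """Sampled moments match mu and mu + alpha mu^2 for alpha = 1/r."""
        mu, alpha = 5.0, 2.0
        r = 1.0 / alpha
        y = rng.negative_binomial(r, r / (r + mu), size=10**6)
        assert abs(y.mean() - mu) / mu < 0.01
        assert abs(y.var() - (mu + alpha * mu**2)) / (mu + alpha * mu**2) < 0.03


class TestZINB:
    def test_kappa_to_zero_reduces_to_nb(self):
        ys = np.arange(0, 20)
        np.testing.assert_allclose(zinb_log_pmf(ys, 4.0, 1.5, 1e-10),
                                   nb_log_pmf(ys, 4.0, 1.5), atol=1e-8)

    def test_half_dropout_at_mu_equals_kappa(self):
        mu = kappa = 3.0
        p0 = np.exp(zinb_log_pmf(0, mu, 2.0, kappa))
        want = 0.5 + 0.5 * np.exp(nb_log_pmf(0, mu, 2.0))
        assert np.isclose(p0, want)

    def test_total_mass_random_params(self, rng):
        for _ in range(5):
            mu, r, k = rng.uniform(0.2, 8), rng.uniform(0.3, 5), rng.uniform(0.2, 5)
            y = np.arange(0, 3000)
            assert abs(np.exp(zinb_log_pmf(y, mu, r, k)).sum() - 1.0) < 1e-8

    def test_matches_oracle(self, rng):
        for _ in range(5):
            mu, r, k = rng.uniform(0.5, 20), rng.uniform(0.3, 8), rng.uniform(0.3, 8)
            ys = np.arange(0, 30)
            got = zinb_log_pmf(ys, mu, r, k)
            want = [zinb_oracle_log_pmf(int(t), mu, r, k) for t in ys]
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_zero_mass_dominates_nb(self, rng):
        for _ in range(20):
            mu, r, k = rng.uniform(0.2, 30), rng.uniform(0.2, 10), rng.uniform(0.1, 10)
            assert zinb_log_pmf(0, mu, r, k) >= nb_log_pmf(0, mu, r)


class TestVariationalExpectation:
    def test_degenerate_gaussian_equals_log_density(self):
        spec = LikelihoodSpec("negative_binomial", alpha=0.5)
        got = variational_expectation(spec, np.array([3]), np.array([1.2]),
                                      np.array([0.0]))
        want = nb_log_pmf(3, np.exp(1.2), 2.0)
        assert np.isclose(got[0], want)

    def test_gaussian_closed_form(self):
        spec = LikelihoodSpec("gaussian", variance=0.7, transform="none")
        y, m, v = np.array([1.3]), np.array([0.4]), np.array([0.2])
        got = variational_expectation(spec, y, m, v)
        want = -0.5 * np.log(2 * np.pi * 0.7) - (0.2 + (1.3 - 0.4) ** 2) / 1.4
        assert np.isclose(got[0], want)

    def test_quadrature_order_convergence(self, rng):
        spec = LikelihoodSpec("negative_binomial", alpha=0.8)
        y = rng.poisson(5.0, 10).astype(float)
        m = rng.normal(1.5, 0.3, 10)
        v = rng.uniform(0.01, 0.5, 10)
        lo = variational_expectation(spec, y, m, v, order=20)
        hi = variational_expectation(spec, y, m, v, order=200)
        assert np.abs(lo - hi).max() < 1e-6

    def test_order_too_small_rejected(self):
        spec = LikelihoodSpec("negative_binomial")
        with pytest.raises(ValueError, match="order"):
            variational_expectation(spec, np.array([1]), np.array([0.0]),
                                    np.array([0.1]), order=2)


class TestTransforms:
    def test_values_at_zero(self):
        assert transform_counts(np.array([0]), "log1p")[0] == 0.0
        assert np.isclose(transform_counts(np.array([0]), "anscombe")[0],
                          2 * np.sqrt(0.375))

    @pytest.mark.parametrize("transform", ["log1p", "anscombe"])
    def test_strictly_increasing(self, transform, rng):
        y = np.sort(rng.integers(0, 1000, 50))
        t = transform_counts(y, transform)
        assert np.all(np.diff(t)[np.diff(y) > 0] > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_counts(np.array([-1]), "log1p")
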