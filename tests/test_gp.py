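import itertools

import numpy as np
import pytest

from countgp.gp import (
    CountsDataset,
    bic,
    credible_region,
    fit_gp,
    predict_latent,
    safe_mode_refit,
    select_inducing_points,
)
from countgp.kernels import KernelSpec, eval_kernel
from countgp.likelihoods import LikelihoodSpec


class TestGaussianExact:
    def test_log_ml_matches_independent_oracle(self, rng):
        """Fitted-path marginal equals a slogdet/solve evaluation."""
        from countgp.gp import _gauss_log_ml

        for _ in range(10):
            n = int(rng.integers(8, 20))
            x = np.sort(rng.uniform(0, 1, n))
            ks = KernelSpec("rbf", lengthscale=float(rng.uniform(0.1, 0.8)),
                            variance=float(rng.uniform(0.2, 2.0)))
            noise = float(rng.uniform(0.05, 0.5))
            y = rng.standard_normal(n)
            got = _gauss_log_ml(ks, x[:, None], y, noise)
            Ky = eval_kernel(ks, x) + noise * np.eye(n)
            _, logdet = np.linalg.slogdet(Ky)
            want = -0.5 * y @ np.linalg.solve(Ky, y) - 0.5 * logdet \
                - 0.5 * n * np.log(2 * np.pi)
            assert abs(got - want) < 1e-6

    def test_sparse_bound_below_full(self, rng):
        from countgp.gp import _gauss_log_ml, _titsias_bound

        x = np.sort(rng.uniform(0, 1, 40))
        ks = KernelSpec("rbf", lengthscale=0.3, variance=1.0)
        y = rng.standard_normal(40)
        full = _gauss_log_ml(ks, x[:, None], y, 0.2)
        Z = select_inducing_points(x[:, None], 6, kernel=ks)
        assert _titsias_bound(ks, x[:, None], Z, y, 0.2) <= full + 1e-6


class TestCountFits:
    def test_constant_data_gives_zero_llr(self):
        x = np.repeat(np.linspace(0, 1, 11), 2)
        y = np.full(22, 17)
        alt = fit_gp(y, x)
        null = fit_gp(y, x, kernel=KernelSpec("constant"))
        assert abs(alt.log_ml - null.log_ml) < 0.5
        # fitted latent mean close to log of the constant
        m, _ = predict_latent(alt, x[:, None])
        assert np.abs(m + alt.mean_offset - np.log(17)).max() < 0.3

    def test_lengthscale_recovery(self, rng):
        """Median recovered lengthscale near the generative value."""
        ks = KernelSpec("rbf", lengthscale=0.3, variance=1.0)
        hats = []
        for rep in range(12):
            r = np.random.default_rng(100 + rep)
            x = np.sort(r.uniform(0, 1, 200))
            K = eval_kernel(ks, x) + 1e-8 * np.eye(200)
            f = np.linalg.cholesky(K) @ r.standard_normal(200) + 3.0
            alpha = 0.1
            y = r.negative_binomial(1 / alpha, 1 / (1 + alpha * np.exp(f)))
            fit = fit_gp(y, x, seed=rep)
            hats.append(fit.kernel.lengthscale)
        assert 0.15 <= np.median(hats) <= 0.6

    def test_translation_invariance_stationary(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 1, 20))
        y = rng.poisson(8.0, 20)
        init = dict(k_lengthscale=0.3, k_variance=0.8, l_alpha=0.4)
        a = fit_gp(y, x, init=init, optimize=False)
        b = fit_gp(y, x + 7.3, init=init, optimize=False)
        assert abs(a.log_ml - b.log_ml) < 1e-5

    def test_scale_factors_absorb_mean_scaling(self):
        rng = np.random.default_rng(5)
        x = np.repeat(np.linspace(0, 1, 11), 2)
        f = 1.2 * np.sin(5 * x) + 3
        y1 = rng.negative_binomial(10, 10 / (10 + np.exp(f)))
        y10 = y1 * 10
        def llr(y, s):
            alt = fit_gp(y, x, scale_factors=s, seed=0)
            null = fit_gp(y, x, kernel=KernelSpec("constant"), scale_factors=s, seed=0)
            return alt.log_ml - null.log_ml
        l1 = llr(y1, np.ones(22))
        l10 = llr(y10, np.full(22, 10.0))
        assert abs(l1 - l10) < max(2.0, 0.2 * abs(l1))

    def test_elbo_trace_monotone(self):
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0, 1, 30))
        y = rng.poisson(np.exp(1.5 * np.sin(6 * x) + 2))
        fit = fit_gp(y, x, likelihood=LikelihoodSpec("negative_binomial"))
        tr = fit.elbo_trace
        assert tr is not None and np.all(np.diff(tr) >= -1e-4)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            fit_gp([1, 2, 3], [0.0, 0.5, 1.0])


class TestSparse:
    def test_sparse_elbo_below_full_same_hypers(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 1, 80))
        y = rng.negative_binomial(2, 2 / (2 + np.exp(1.5 * np.sin(6 * x) + 2)))
        init = dict(k_lengthscale=0.25, k_variance=1.0, l_alpha=0.5)
        full = fit_gp(y, x, init=init, optimize=False)
        sp = fit_gp(y, x, sparse=True, M=8, init=init, optimize=False)
        assert sp.log_ml <= full.log_ml + 1e-6

    def test_sparse_requires_m_below_n(self):
        with pytest.raises(ValueError, match="M"):
            fit_gp(np.arange(10), np.linspace(0, 1, 10), sparse=True, M=10)


class TestInducingPoints:
    def test_m_equals_n_returns_inputs(self, rng):
        X = rng.uniform(0, 1, (9, 2))
        for method in ("mdpp", "kmeans"):
            np.testing.assert_array_equal(select_inducing_points(X, 9, method), X)

    def test_m1_ties_broken_by_lowest_index(self):
        # stationary kernel: all diagonals equal, first point wins
        X = np.linspace(0, 1, 5)[:, None]
        Z = select_inducing_points(X, 1, "mdpp",
                                   kernel=KernelSpec("rbf", lengthscale=0.3))
        assert np.allclose(Z[0], X[0])

    def test_m2_matches_exhaustive_determinant_search(self, rng):
        # sorted 1-D inputs: the greedy chain starting from the lowest-index
        # (leftmost) point coincides with the exhaustive optimum
        X = np.sort(rng.uniform(0, 1, 5))[:, None]
        ks = KernelSpec("rbf", lengthscale=0.4)
        K = eval_kernel(ks, X)
        best, best_det = None, -1
        for pair in itertools.combinations(range(5), 2):
            det = np.linalg.det(K[np.ix_(pair, pair)])
            if det > best_det:
                best, best_det = set(pair), det
        Z = select_inducing_points(X, 2, "mdpp", kernel=ks)
        chosen = {int(np.argmin(np.abs(X[:, 0] - z))) for z in Z[:, 0]}
        assert chosen == best

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            select_inducing_points(np.zeros((4, 1)), 5)


class TestBIC:
    def test_log_n_identity(self):
        fit = fit_gp(np.array([3, 4, 5, 3]), np.linspace(0, 1, 4))
        fit.log_ml = 0.0
        assert np.isclose(bic(fit, N=int(np.e**1) or 1, d=1), np.log(int(np.e)))
        assert np.isclose(bic(fit, N=100, d=1), np.log(100))

    def test_penalty_monotone_in_d(self):
        fit = fit_gp(np.array([3, 4, 5, 3]), np.linspace(0, 1, 4))
        fit.log_ml = -10.0
        assert bic(fit, N=50, d=3) > bic(fit, N=50, d=2)

    def test_selects_periodic_kernel_on_periodic_data(self):
        """Model selection sanity: periodic beats linear on periodic latents."""
        wins = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            x = np.repeat(np.linspace(0, 1, 11), 2)
            f = 1.5 * np.sin(4 * np.pi * x) + 3
            y = rng.negative_binomial(10, 10 / (10 + np.exp(f)))
            fits = {}
            for fam in ("periodic", "linear"):
                fit = fit_gp(y, x, kernel=KernelSpec(fam), seed=rep)
                fits[fam] = bic(fit)
            wins += fits["periodic"] < fits["linear"]
        assert wins >= 0.8 * reps


class TestSafeMode:
    def test_good_fit_returned_unchanged(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0, 1, 30))
        y = rng.poisson(np.exp(1.5 * np.sin(6 * x) + 2))
        fit = fit_gp(y, x)
        out = safe_mode_refit(fit, seed=0)
        assert out is fit and out.n_restarts_used == 0

    def test_one_sided_fit_detected_and_restarted(self):
        """A posterior median below ~all observations triggers restarts."""
        from countgp.gp import _one_sided_fraction

        rng = np.random.default_rng(4)
        x = np.repeat(np.linspace(0, 1, 15), 2)
        f = 2.5 * np.sin(4 * np.pi * x) + 2
        y = rng.negative_binomial(10, 10 / (10 + np.exp(f)))
        bad = fit_gp(y, x, init=dict(k_lengthscale=1e3, k_variance=1e-4),
                     optimize=False)
        bad._state["m"] = bad._state["m"] - 5.0  # push the median under the data
        assert _one_sided_fraction(bad) >= 0.9
        bad.log_ml = -1e4
        fixed = safe_mode_refit(bad, max_restarts=5, seed=1)
        assert fixed.log_ml > -1e4
        assert fixed.n_restarts_used >= 1

    def test_non_converged_fit_restarted(self):
        rng = np.random.default_rng(9)
        x = np.repeat(np.linspace(0, 1, 15), 2)
        y = rng.negative_binomial(10, 10 / (10 + np.exp(1.5 * np.sin(5 * x) + 2)))
        bad = fit_gp(y, x, optimize=False)
        bad.converged = False
        bad.log_ml = -np.inf
        fixed = safe_mode_refit(bad, max_restarts=5, seed=2)
        assert np.isfinite(fixed.log_ml)


class TestCredibleRegion:
    def test_shapes_and_refusal(self):
        rng = np.random.default_rng(6)
        x = np.repeat(np.linspace(0, 1, 11), 2)
        y = rng.negative_binomial(5, 5 / (5 + np.exp(1.5 * np.sin(5 * x) + 2)))
        fit = fit_gp(y, x)
        grid, mean, lo, hi = credible_region(fit, grid_size=50, n_samples=60, seed=0)
        assert grid.shape == mean.shape == lo.shape == hi.shape == (50,)
        assert np.all(hi >= lo - 1e-9)
        fit.converged = False
        with pytest.raises(RuntimeError):
            credible_region(fit)

    def test_nb_band_wider_than_poisson(self):
        """Var = mu + alpha mu^2 >= mu: NB band dominates Poisson pointwise."""
        rng = np.random.default_rng(7)
        x = np.repeat(np.linspace(0, 1, 11), 2)
        y = rng.poisson(np.exp(1.2 * np.sin(5 * x) + 3))
        init = dict(k_lengthscale=0.3, k_variance=0.8)
        nb = fit_gp(y, x, likelihood=LikelihoodSpec("negative_binomial"),
                    init=dict(l_alpha=2.0, **init), optimize=False)
        po = fit_gp(y, x, likelihood=LikelihoodSpec("poisson"), init=init,
                    optimize=False)
        _, _, lo_nb, hi_nb = credible_region(nb, 40, 200, seed=1, smooth=False)
        _, _, lo_po, hi_po = credible_region(po, 40, 200, seed=1, smooth=False)
        assert np.mean((hi_nb - lo_nb) >= (hi_po - lo_po)) > 0.9

    def test_empirical_coverage(self):
        """[5, 95] band holds ~90% of held-out replicate counts."""
        hits = tot = 0
        for rep in range(40):
            rng = np.random.default_rng(300 + rep)
            x = np.repeat(np.linspace(0, 1, 11), 2)
            f = rng.uniform(0.8, 1.8) * np.sin(rng.uniform(2, 6) * x) + 3
            alpha = 0.3
            mu = np.exp(f)
            y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
            y_new = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
            fit = fit_gp(y, x, seed=rep)
            grid, _, lo, hi = credible_region(fit, grid_size=50, n_samples=100,
                                              seed=rep, smooth=False)
            idx = np.searchsorted(grid, x).clip(0, 49)
            hits += np.sum((y_new >= lo[idx]) & (y_new <= hi[idx]))
            tot += len(y_new)
        assert 0.82 <= hits / tot <= 0.97


class TestCountsDataset:
    def test_validation(self):
        with pytest.raises(ValueError):
            CountsDataset(counts=np.array([[1, -2]]), coords=[0.0, 1.0])
        with pytest.raises(ValueError):
            CountsDataset(counts=np.array([[1, 2]]), coords=[0.0])
        ds = CountsDataset(counts=np.array([[1, 2], [0, 3]]), coords=[0.0, 1.0],
                           scale_factors=np.array([1.0, 2.0]))
        assert ds.n_genes == 2 and ds.n_samples == 2
        assert np.allclose(ds.gene_scale(1), [1.0, 2.0])
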