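import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from countgp.gp import CountsDataset
from countgp.likelihoods import LikelihoodSpec
from countgp.simulate import SimulationDesign, simulate_timecourse
from countgp.testing import (
    chi2_pvalues,
    one_sample_test,
    permutation_test,
    qvalues,
    two_sample_test,
)


class TestChi2:
    def test_zero_llr_gives_p_one(self):
        assert chi2_pvalues([0.0], df=1)[0] == 1.0

    def test_uses_twice_the_log_ratio(self):
        # chi2_1 95th percentile: 2*llr = 3.841 -> p ~ 0.05
        p = chi2_pvalues([3.841 / 2], df=1)[0]
        assert abs(p - 0.05) < 1e-3

    def test_negative_llr_clamped(self):
        assert chi2_pvalues([-5.0], df=2)[0] == 1.0

    def test_df_validated(self):
        with pytest.raises(ValueError):
            chi2_pvalues([1.0], df=0)


class TestQvalues:
    def test_all_ones(self):
        assert np.all(qvalues(np.ones(30)) == 1.0)

    def test_empty(self):
        assert qvalues(np.array([])).size == 0

    def test_pi0_near_one_under_null(self, rng):
        p = rng.uniform(0, 1, 2000)
        q = qvalues(p)
        # with pi0 = 1 by construction, q ~ BH; pi0-hat within [0.8, 1]
        bh = multipletests(p, method="fdr_bh")[1]
        ratio = np.median(q / np.clip(bh, 1e-12, None))
        assert 0.8 <= ratio <= 1.001

    def test_ordering_matches_bh(self, rng):
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(0, 1, 500)])
        q = qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.array_equal(np.argsort(q, kind="stable"),
                              np.argsort(bh, kind="stable"))
        assert np.all(q <= bh + 1e-12)  # pi0-hat <= 1 shrinks q below BH

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_p(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 100)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))


def _single_gene_dataset(y, x):
    return CountsDataset(counts=np.asarray(y)[None, :], coords=np.asarray(x))


class TestOneSample:
    def test_constant_gene_has_small_llr(self):
        """Null simulation: mu = 20, alpha = 0.05, N = 22."""
        x = np.repeat(np.linspace(0, 1, 11), 2)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = rng.negative_binomial(20, 20 / 21.0, 22)  # r=20 => alpha=0.05
            tab = one_sample_test(_single_gene_dataset(y, x), seed=seed)
            hits += tab["llr"].iloc[0] < 1.0
        assert hits >= 0.9 * n_seeds

    def test_strong_sine_gene_detected(self):
        """High amplitude, low dispersion: llr > 5 nearly always."""
        x = np.repeat(np.linspace(0, 1, 11), 2)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            f = 2.0 * np.sin(5 * x + 1.0) + 3.0
            y = rng.negative_binomial(20, 20 / (20 + np.exp(f)))
            tab = one_sample_test(_single_gene_dataset(y, x), seed=seed)
            hits += tab["llr"].iloc[0] > 5.0
        assert hits >= 0.9 * n_seeds

    def test_identical_counts_give_zero_llr(self):
        x = np.repeat(np.linspace(0, 1, 11), 2)
        tab = one_sample_test(_single_gene_dataset(np.full(22, 9), x))
        assert abs(tab["llr"].iloc[0]) < 0.05

    def test_nestedness_negative_llrs_rare(self, small_timecourse):
        ds, _ = small_timecourse
        tab = one_sample_test(ds, seed=0)
        llr = tab["llr"].to_numpy()
        assert np.mean(llr < -0.01) < 0.02

    def test_determinism(self, small_timecourse):
        ds, _ = small_timecourse
        a = one_sample_test(ds, seed=3)
        b = one_sample_test(ds, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_table_columns(self, small_timecourse):
        ds, _ = small_timecourse
        tab = one_sample_test(ds, seed=0)
        for col in ("gene", "llr", "p_value", "q_value", "is_de",
                    "alpha_hat", "lengthscale_hat", "converged"):
            assert col in tab.columns
        assert len(tab) == ds.n_genes


class TestTwoSample:
    @staticmethod
    def _paired_dataset(y_a, y_b, x):
        labels = np.array(["A"] * len(y_a) + ["B"] * len(y_b))
        return CountsDataset(counts=np.concatenate([y_a, y_b])[None, :],
                             coords=np.concatenate([x, x]), labels=labels)

    def test_equal_trajectories_give_small_llr(self):
        """Two independent replicates of one latent: no divergence signal.

        (A literal copy of condition A would give a *negative* ratio — the
        duplicated noise makes the shared model strictly better — so the
        no-difference case is generated as independent draws.)
        """
        rng = np.random.default_rng(0)
        x = np.repeat(np.linspace(0, 1, 11), 2)
        mu = np.exp(1.5 * np.sin(5 * x) + 2)
        y_a = rng.negative_binomial(10, 10 / (10 + mu))
        y_b = rng.negative_binomial(10, 10 / (10 + mu))
        tab = two_sample_test(self._paired_dataset(y_a, y_b, x), seed=0)
        assert tab["llr"].iloc[0] < 4.0

    def test_diverging_pair_exceeds_one_sample_signal(self):
        rng = np.random.default_rng(1)
        x = np.repeat(np.linspace(0, 1, 11), 2)
        y_a = rng.negative_binomial(20, 20 / 30.0, 22)  # constant at mu=10
        f_b = 1.8 * np.sin(5 * x) + np.log(10.0)
        y_b = rng.negative_binomial(20, 20 / (20 + np.exp(f_b)))
        tab2 = two_sample_test(self._paired_dataset(y_a, y_b, x), seed=1)
        tab1 = one_sample_test(_single_gene_dataset(y_a, x), seed=1)
        assert tab2["llr"].iloc[0] > 2.0
        assert tab2["llr"].iloc[0] > tab1["llr"].iloc[0]

    def test_nb_flags_divergence_gaussian_misses(self):
        """High-dispersion diverging pair: NB llr exceeds Gaussian llr in
        most replicates (the two-sample motivating example)."""
        x = np.repeat(np.linspace(0, 1, 11), 2)
        nb_wins = 0
        reps = 11
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            f_a = np.full_like(x, 3.0)
            f_b = 3.0 + 2.0 * x  # steadily diverging condition
            r = 0.7
            y_a = rng.negative_binomial(r, r / (r + np.exp(f_a)))
            y_b = rng.negative_binomial(r, r / (r + np.exp(f_b)))
            ds = self._paired_dataset(y_a, y_b, x)
            nb = two_sample_test(ds, likelihood=LikelihoodSpec("negative_binomial"),
                                 seed=rep)["llr"].iloc[0]
            ga = two_sample_test(ds, likelihood=LikelihoodSpec("gaussian"),
                                 seed=rep)["llr"].iloc[0]
            nb_wins += chi2.sf(2 * max(nb, 0), 3) < chi2.sf(2 * max(ga, 0), 3)
        assert nb_wins > reps / 2

    def test_requires_two_labels(self, small_timecourse):
        ds, _ = small_timecourse
        with pytest.raises(ValueError, match="labels"):
            two_sample_test(ds)


class TestPermutation:
    def test_pvalues_respect_addone_bounds_and_determinism(self):
        ds, _ = simulate_timecourse(SimulationDesign(
            n_genes=6, dispersion_level="low", expression_level="high", seed=3))
        B = 2
        a = permutation_test(ds, B=B, seed=5)
        b = permutation_test(ds, B=B, seed=5)
        pd.testing.assert_frame_equal(a, b)
        K = B * ds.n_genes
        p = a["p_value"].to_numpy()
        ok = np.isfinite(p)
        assert np.all(p[ok] >= 1.0 / (1.0 + K) - 1e-12)
        assert np.all(p[ok] <= 1.0)

    def test_b_validated(self, small_timecourse):
        ds, _ = small_timecourse
        with pytest.raises(ValueError):
            permutation_test(ds, B=0)
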