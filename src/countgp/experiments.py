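"""Benchmark experiments on synthetic data.

Each function generates its own data from a seed, runs the package's
fitting and testing machinery, and returns a small dict of summary
numbers.  They power both the validation test suite and the
reproduction script, so the problem sizes are chosen to finish on a
single CPU in minutes; the methods note records the sizes used.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest, spearmanr
from sklearn.metrics import roc_auc_score

from .branching import branching_posterior
from .gp import _gauss_log_ml, _titsias_bound, select_inducing_points
from .kernels import KernelSpec, eval_kernel
from .likelihoods import LikelihoodSpec, nb_log_pmf, zinb_log_pmf
from .simulate import SimulationDesign, simulate_branching, simulate_spatial, simulate_timecourse
from .spatial import fit_scale_factors, sv_pipeline
from .testing import one_sample_test, permutation_test

__all__ = [
    "nb_oracle_log_pmf",
    "zinb_oracle_log_pmf",
    "likelihood_correctness",
    "gaussian_marginal_agreement",
    "roc_benchmark",
    "sparse_full_concordance",
    "branching_recovery",
    "null_calibration",
    "spatial_null_calibration",
    "spatial_detection",
    "normalization_experiment",
]


# ---------------------------------------------------------------------------
# independent oracles (product-form recurrences, no log-gamma)
# ---------------------------------------------------------------------------


def nb_oracle_log_pmf(y: int, mu: float, r: float) -> float:
    """NB log pmf via the term-by-term Gamma recurrence.

    Gamma(y+r)/(Gamma(y+1) Gamma(r)) = prod_{j=0}^{y-1} (r+j)/(j+1); the
    product is accumulated in log space term by term, an evaluation path
    independent of the log-gamma implementation.
    """
    acc = 0.0
    for j in range(int(y)):
        acc += np.log(r + j) - np.log(j + 1.0)
    return acc + r * (np.log(r) - np.log(r + mu)) + y * (np.log(mu) - np.log(r + mu))


def zinb_oracle_log_pmf(y: int, mu: float, r: float, kappa: float) -> float:
    psi = kappa / (kappa + mu)
    p = (1.0 - psi) * np.exp(nb_oracle_log_pmf(y, mu, r))
    if y == 0:
        p += psi
    return float(np.log(p))


def likelihood_correctness(seed: int = 0) -> dict:
    """Max deviations of the count log-pmfs from independent oracles.

    Also checks total probability mass and the NB -> Poisson limit
    (total-variation distance at r = 1e6).
    """
    rng = np.random.default_rng(seed)
    max_nb = 0.0
    max_zinb = 0.0
    for _ in range(30):
        mu = float(rng.uniform(0.2, 50.0))
        r = float(rng.uniform(0.1, 20.0))
        kappa = float(rng.uniform(0.1, 20.0))
        ys = np.arange(0, 40)
        nb = nb_log_pmf(ys, mu, r)
        zb = zinb_log_pmf(ys, mu, r, kappa)
        nb_o = np.array([nb_oracle_log_pmf(int(t), mu, r) for t in ys])
        zb_o = np.array([zinb_oracle_log_pmf(int(t), mu, r, kappa) for t in ys])
        max_nb = max(max_nb, float(np.abs(nb - nb_o).max()))
        max_zinb = max(max_zinb, float(np.abs(zb - zb_o).max()))
    ys = np.arange(0, 3000)
    mass_nb = float(np.exp(nb_log_pmf(ys, 3.0, 2.0)).sum())
    mass_zinb = float(np.exp(zinb_log_pmf(ys, 3.0, 2.0, 1.5)).sum())
    from scipy.stats import poisson as _pois

    ys = np.arange(0, 60)
    tv = 0.5 * float(np.abs(np.exp(nb_log_pmf(ys, 4.0, 1e6)) - _pois.pmf(ys, 4.0)).sum())
    return dict(
        nb_log_pmf_max_abs_err=max_nb,
        zinb_log_pmf_max_abs_err=max_zinb,
        nb_mass_deficit=abs(1.0 - mass_nb),
        zinb_mass_deficit=abs(1.0 - mass_zinb),
        nb_poisson_limit_tv=tv,
    )


def gaussian_marginal_agreement(n_datasets: int = 50, seed: int = 0) -> dict:
    """Exact-marginal agreement and the sparse lower-bound property.

    For random small Gaussian-likelihood datasets, compares the package's
    log marginal likelihood with an independently coded N(0, K + s2 I)
    density, and measures the worst-case excess of the Titsias sparse
    bound over the full marginal (must be <= ~0).
    """
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    max_gap = -np.inf
    for _ in range(n_datasets):
        n = int(rng.integers(10, 26))
        x = np.sort(rng.uniform(0, 1, n))
        ks = KernelSpec("rbf", lengthscale=float(rng.uniform(0.1, 0.6)),
                        variance=float(rng.uniform(0.3, 2.0)))
        noise = float(rng.uniform(0.05, 0.5))
        K = eval_kernel(ks, x[:, None])
        L = np.linalg.cholesky(K + (noise + 1e-10) * np.eye(n))
        y = L @ rng.standard_normal(n)
        lml = _gauss_log_ml(ks, x[:, None], y, noise)
        # independent oracle: direct quadratic form + slogdet
        sgn, logdet = np.linalg.slogdet(K + noise * np.eye(n))
        oracle = -0.5 * y @ np.linalg.solve(K + noise * np.eye(n), y) \
            - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)
        max_diff = max(max_diff, abs(lml - oracle))
        M = max(3, n // 4)
        Z = select_inducing_points(x[:, None], M, method="mdpp", kernel=ks)
        bound = _titsias_bound(ks, x[:, None], Z, y, noise)
        max_gap = max(max_gap, bound - lml)
    return dict(gaussian_log_ml_max_abs_diff=float(max_diff),
                sparse_bound_max_excess=float(max_gap))


def _auroc(table, truth) -> float:
    llr = np.nan_to_num(np.clip(table["llr"].to_numpy(), 0.0, None))
    return float(roc_auc_score(truth["is_dynamic"].to_numpy(), llr))


def roc_benchmark(dispersion_level: str, n_genes: int = 100, seed: int = 0,
                  likelihoods=("negative_binomial", "gaussian", "poisson"),
                  expression_level: str | None = None) -> dict:
    """One-sample-test AUROCs per likelihood family on time-course data.

    The high-dispersion regime is generated at low expression (zeros and
    skewness are what separates count models from the Gaussian); the
    low-dispersion regime at high expression (where the Poisson's
    variance-equals-mean restriction binds).
    """
    if expression_level is None:
        expression_level = "low" if dispersion_level == "high" else "high"
    ds, truth = simulate_timecourse(SimulationDesign(
        n_genes=n_genes, dispersion_level=dispersion_level,
        expression_level=expression_level, seed=seed))
    out = {}
    for fam in likelihoods:
        lik = (LikelihoodSpec("gaussian", transform="log1p")
               if fam == "gaussian" else LikelihoodSpec(fam))
        table = one_sample_test(ds, likelihood=lik, seed=seed)
        key = {"negative_binomial": "nb", "gaussian": "gaussian",
               "poisson": "poisson"}[fam]
        out[f"auroc_{key}_{dispersion_level}_dispersion"] = round(_auroc(table, truth), 4)
    return out


def sparse_full_concordance(n_genes: int = 50, n_cells: int = 400,
                            seed: int = 0, outer_maxfev: int = 40) -> dict:
    """Spearman correlation of per-gene LLRs: full vs sparse (M = 5% N)."""
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0, 1, n_cells))
    ds, truth = simulate_timecourse(SimulationDesign(
        n_genes=n_genes, timepoints=x, replicates=1,
        dispersion_level="high", expression_level="high", seed=seed,
        fraction_dynamic=0.5))
    t_full = one_sample_test(ds, seed=seed, outer_maxfev=outer_maxfev)
    t_sparse = one_sample_test(ds, sparse=True, seed=seed,
                               outer_maxfev=outer_maxfev)
    a = np.clip(t_full["llr"].to_numpy(), 0, None)
    b = np.clip(t_sparse["llr"].to_numpy(), 0, None)
    ok = np.isfinite(a) & np.isfinite(b)
    rho = float(spearmanr(a[ok], b[ok]).statistic)
    return dict(sparse_full_llr_spearman=round(rho, 4), n_cells=n_cells,
                n_genes=int(ok.sum()))


def branching_recovery(n_reps: int = 25, n_cells: int = 120,
                       x_b_true: float = 0.5, seed: int = 0) -> dict:
    """Fraction of replicates with MAP branch time within 0.1 of truth."""
    hits = 0
    worst_norm = 0.0
    for rep in range(n_reps):
        ds, truth = simulate_branching(n_cells, x_b_true=x_b_true,
                                       seed=seed * 1000 + rep)
        res = branching_posterior(ds, n_grid=25, seed=seed * 1000 + rep)
        hits += abs(res.map_branch_point - x_b_true) <= 0.1
        worst_norm = max(worst_norm, abs(res.posterior.sum() - 1.0))
    return dict(branch_map_hit_rate=hits / n_reps,
                branch_posterior_norm_err=worst_norm, n_reps=n_reps)


def null_calibration(n_genes: int = 200, seed: int = 0, B_perm: int = 3,
                     n_perm_genes: int = 50) -> dict:
    """p-value uniformity under constant-gene simulations.

    chi2 branch: constant genes at moderate mean/dispersion, KS test of
    the p-values against U[0,1] and the rejection rate at p < 0.05.
    Permutation branch: dynamic-free spatial-free 1-D data with pooled
    permutation nulls.
    """
    ds, truth = simulate_timecourse(SimulationDesign(
        n_genes=n_genes, fraction_dynamic=0.0, dispersion_level="low",
        expression_level="high", seed=seed))
    table = one_sample_test(ds, seed=seed)
    p = table["p_value"].to_numpy()
    p = p[np.isfinite(p)]
    ks_p = float(kstest(p, "uniform").pvalue)
    rej = float(np.mean(p < 0.05))
    dsp, _ = simulate_timecourse(SimulationDesign(
        n_genes=n_perm_genes, fraction_dynamic=0.0, dispersion_level="low",
        expression_level="high", seed=seed + 1))
    pt = permutation_test(dsp, B=B_perm, seed=seed + 1)
    pp = pt["p_value"].to_numpy()
    perm_rej = float(np.mean(pp[np.isfinite(pp)] < 0.05))
    return dict(chi2_null_ks_pvalue=round(ks_p, 4),
                chi2_null_rejection_rate=round(rej, 4),
                perm_null_rejection_rate=round(perm_rej, 4),
                n_null_genes=int(p.size))


def spatial_null_calibration(n_genes: int = 40, n_locations: int = 100,
                             seed: int = 0, fdr_level: float = 0.05) -> dict:
    """SV call rate at the FDR threshold on all-flat spatial data."""
    ds, _ = simulate_spatial(n_genes, n_locations, pattern_fraction=0.0,
                             seed=seed)
    table = sv_pipeline(ds, normalize=True, fdr_level=fdr_level, seed=seed)
    return dict(sv_flat_call_rate=float(table["is_de"].mean()),
                n_genes=len(table))


def spatial_detection(n_genes: int = 100, n_locations: int = 100,
                      seed: int = 0) -> dict:
    """AUROC of the SV pipeline's LLR ranking on half-patterned data."""
    ds, truth = simulate_spatial(n_genes, n_locations, pattern_fraction=0.5,
                                 seed=seed)
    table = sv_pipeline(ds, normalize=False, seed=seed)
    keep = truth["gene"].isin(table["gene"]).to_numpy()
    llr = np.nan_to_num(np.clip(table["llr"].to_numpy(), 0, None))
    auc = float(roc_auc_score(truth.loc[keep, "is_pattern"], llr))
    return dict(sv_detection_auroc=round(auc, 4), n_genes=len(table))


def normalization_experiment(n_genes: int = 30, n_locations: int = 100,
                             seed: int = 0, fdr_level: float = 0.05,
                             beta_reps: int = 50) -> dict:
    """Scale-normalization effectiveness on size-confounded flat genes.

    Flat genes multiplied by a smooth spatial size factor should be called
    spatially variable en masse without normalization and near the nominal
    FDR with it; also reports relative error of the recovered NB-regression
    slope on proportional data.
    """
    ds, _ = simulate_spatial(n_genes, n_locations, pattern_fraction=0.0,
                             seed=seed, confounding=True)
    t_off = sv_pipeline(ds, normalize=False, fdr_level=fdr_level, seed=seed)
    t_on = sv_pipeline(ds, normalize=True, fdr_level=fdr_level, seed=seed)
    rng = np.random.default_rng(seed)
    errs = []
    beta_true = 0.02
    for _ in range(beta_reps):
        T = rng.uniform(200.0, 2000.0, 260)
        r = 5.0
        yv = rng.negative_binomial(r, r / (r + beta_true * T))
        if yv.sum() == 0:
            continue
        fitn = fit_scale_factors(yv, T)
        errs.append(abs(fitn.beta - beta_true) / beta_true)
    return dict(
        sv_confounded_rate_unnormalized=float(t_off["is_de"].mean()),
        sv_confounded_rate_normalized=float(t_on["is_de"].mean()),
        beta_median_rel_err=float(np.median(errs)),
        n_genes=len(t_on),
    )
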