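"""Differential-expression tests across genes.

One-sample test: per gene, a dynamic GP (rbf by default) is compared with a
constant-latent model under the same likelihood family; the statistic is
the log-likelihood ratio LLR = L_dyn - L_const.  The models are nested
because the constant model is the infinite-lengthscale limit of the rbf
GP, so the LLR is non-negative up to optimizer tolerance and 2*LLR is
referred to a chi-squared distribution (using twice the log ratio, the
correct Wilks statistic).

Two-sample test: three fits — one GP per condition plus a shared GP
treating the conditions as replicates; LLR = (L_A + L_B) - L_shared.

FDR control uses Storey q-values (pi0 estimated on a lambda grid with a
cubic smoother).  A permutation null is also available: spatial or
temporal coordinates are shuffled (one shared permutation per round across
genes) and per-gene p-values are computed against the pooled null
statistics with the add-one estimator.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .gp import CountsDataset, fit_gp, safe_mode_refit
from .kernels import KernelSpec
from .likelihoods import LikelihoodSpec

logger = logging.getLogger(__name__)

__all__ = [
    "one_sample_test",
    "two_sample_test",
    "chi2_pvalues",
    "qvalues",
    "permutation_test",
]


def chi2_pvalues(llr, df: int = 2):
    """Upper-tail chi-squared p-values of 2*LLR with ``df`` degrees of freedom.

    Negative LLRs (optimizer noise in nested comparisons) are clamped to 0,
    giving p = 1.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    llr = np.clip(np.asarray(llr, dtype=float), 0.0, None)
    return chi2.sf(2.0 * llr, df)


def qvalues(p, lambdas=None, pi0: Optional[float] = None):
    """Storey q-values with the lambda-grid / cubic-smoother pi0 estimate.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a grid,
    smoothed by a cubic polynomial, and read off at the largest lambda;
    q-values are then the monotone step-down transform of pi0 * p * m / rank.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.size < 4 or m < 20:
            pi0 = 1.0
        else:
            pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambdas.max()))
    pi0 = float(np.clip(pi0, 1e-8, 1.0))
    order = np.argsort(p)[::-1]  # largest p first
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order):
        rank = m - rank_from_top
        val = min(pi0 * p[idx] * m / rank, prev)
        q[idx] = val
        prev = val
    return q


def _gene_seed(seed: int, i: int) -> int:
    return int((seed * 1_000_003 + i) % (2**31 - 1))


def _fit_llr(y, coords, kernel, likelihood, *, sparse, M, scale, seed, safe_mode,
             init=None, outer_maxfev=60):
    """Dynamic-vs-constant fit pair; returns (llr, alt_fit, null_fit)."""
    alt = fit_gp(y, coords, kernel=kernel, likelihood=likelihood, sparse=sparse,
                 M=M, scale_factors=scale, seed=seed, init=init,
                 outer_maxfev=outer_maxfev)
    null = fit_gp(y, coords, kernel=KernelSpec("constant", variance=kernel.variance),
                  likelihood=likelihood, scale_factors=scale, seed=seed,
                  outer_maxfev=outer_maxfev)
    if safe_mode:
        alt = safe_mode_refit(alt, seed=seed)
        null = safe_mode_refit(null, seed=seed + 1)
    llr = alt.log_ml - null.log_ml
    if llr < 0 and alt.converged and null.converged:
        # the constant optimum lies on the boundary (l -> inf) of the
        # dynamic family; re-start the dynamic fit from there
        span = float(np.ptp(np.asarray(coords, float)))
        retry_init = {"k_variance": null.kernel.variance}
        if "lengthscale" in kernel.free_names:
            retry_init["k_lengthscale"] = max(span, 1.0) * 900.0
        for nm in likelihood.free_names:
            retry_init["l_" + nm] = getattr(null.likelihood, nm)
        alt2 = fit_gp(y, coords, kernel=kernel, likelihood=likelihood, sparse=sparse,
                      M=M, scale_factors=scale, seed=seed, init=retry_init,
                      outer_maxfev=min(outer_maxfev, 20))
        if alt2.log_ml > alt.log_ml:
            alt = alt2
            llr = alt.log_ml - null.log_ml
    return llr, alt, null


def _llr_table(dataset: CountsDataset, kernel, likelihood, *, sparse, M, seed,
               safe_mode, outer_maxfev=60, kernel_init=None) -> pd.DataFrame:
    rows = []
    for i in range(dataset.n_genes):
        y = dataset.counts[i]
        scale = dataset.gene_scale(i) if dataset.scale_factors is not None else None
        gseed = _gene_seed(seed, i)
        try:
            llr, alt, null = _fit_llr(
                y, dataset.coords, kernel, likelihood, sparse=sparse, M=M,
                scale=scale, seed=gseed, safe_mode=safe_mode, init=kernel_init,
                outer_maxfev=outer_maxfev,
            )
            conv = bool(alt.converged and null.converged)
            rows.append(dict(
                gene=dataset.gene_names[i], llr=llr if conv else np.nan,
                alpha_hat=getattr(alt.likelihood, "alpha", np.nan)
                if alt.likelihood.is_count else np.nan,
                lengthscale_hat=alt.kernel.lengthscale
                if "lengthscale" in alt.kernel.free_names else np.nan,
                converged=conv,
                n_restarts=alt.n_restarts_used + null.n_restarts_used,
            ))
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("gene %s failed: %s", dataset.gene_names[i], exc)
            rows.append(dict(gene=dataset.gene_names[i], llr=np.nan,
                             alpha_hat=np.nan, lengthscale_hat=np.nan,
                             converged=False, n_restarts=0))
    return pd.DataFrame(rows)


def _finalize(table: pd.DataFrame, df: int, fdr_level: float) -> pd.DataFrame:
    ok = table["converged"] & table["llr"].notna()
    n_failed = int((~ok).sum())
    if n_failed:
        logger.info("%d genes excluded from FDR (non-converged)", n_failed)
    p = np.full(len(table), np.nan)
    q = np.full(len(table), np.nan)
    p[ok] = chi2_pvalues(table.loc[ok, "llr"].to_numpy(), df=df)
    if ok.any():
        q[ok.to_numpy()] = qvalues(p[ok.to_numpy()])
    table = table.copy()
    table["p_value"] = p
    table["q_value"] = q
    table["is_de"] = (table["q_value"] <= fdr_level).fillna(False)
    cols = ["gene", "llr", "p_value", "q_value", "is_de",
            "alpha_hat", "lengthscale_hat", "converged", "n_restarts"]
    return table[cols]


def one_sample_test(
    dataset: CountsDataset,
    kernel: Optional[KernelSpec] = None,
    likelihood: Optional[LikelihoodSpec] = None,
    *,
    sparse: bool = False,
    M: Optional[int] = None,
    df: int = 2,
    fdr_level: float = 0.05,
    seed: int = 0,
    safe_mode: bool = False,
    outer_maxfev: int = 60,
) -> pd.DataFrame:
    """Dynamic-vs-constant likelihood-ratio test for every gene.

    Returns a table with per-gene llr, p_value (chi2 of 2*LLR with ``df``
    degrees of freedom), Storey q_value, the FDR call at ``fdr_level``, and
    fit diagnostics.  Genes whose fits never converge carry NaN statistics
    and are excluded from the FDR computation.
    """
    kernel = kernel or KernelSpec("rbf")
    likelihood = likelihood or LikelihoodSpec("negative_binomial")
    table = _llr_table(dataset, kernel, likelihood, sparse=sparse, M=M,
                       seed=seed, safe_mode=safe_mode, outer_maxfev=outer_maxfev)
    return _finalize(table, df, fdr_level)


def two_sample_test(
    dataset: CountsDataset,
    kernel: Optional[KernelSpec] = None,
    likelihood: Optional[LikelihoodSpec] = None,
    *,
    df: int = 3,
    fdr_level: float = 0.05,
    seed: int = 0,
    safe_mode: bool = False,
    outer_maxfev: int = 60,
) -> pd.DataFrame:
    """Condition-A-vs-B likelihood-ratio test.

    Fits one GP per condition plus a shared GP pooling both conditions as
    replicates; LLR = (L_A + L_B) - L_shared.  Requires exactly two label
    values on the dataset.
    """
    kernel = kernel or KernelSpec("rbf")
    likelihood = likelihood or LikelihoodSpec("negative_binomial")
    if dataset.labels is None:
        raise ValueError("two-sample test requires per-sample labels")
    levels = pd.unique(dataset.labels)
    if len(levels) != 2:
        raise ValueError(f"exactly two condition labels required, got {list(levels)}")
    mask_a = dataset.labels == levels[0]
    mask_b = ~mask_a
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("one of the conditions is empty")
    rows = []
    for i in range(dataset.n_genes):
        y = dataset.counts[i]
        gseed = _gene_seed(seed, i)
        try:
            fits = []
            for mask in (mask_a, mask_b, np.ones_like(mask_a, dtype=bool)):
                f = fit_gp(y[mask], dataset.coords[mask], kernel=kernel,
                           likelihood=likelihood, seed=gseed,
                           outer_maxfev=outer_maxfev)
                if safe_mode:
                    f = safe_mode_refit(f, seed=gseed)
                fits.append(f)
            fa, fb, fs = fits
            conv = all(f.converged for f in fits)
            llr = fa.log_ml + fb.log_ml - fs.log_ml
            rows.append(dict(gene=dataset.gene_names[i], llr=llr if conv else np.nan,
                             alpha_hat=getattr(fs.likelihood, "alpha", np.nan)
                             if fs.likelihood.is_count else np.nan,
                             lengthscale_hat=fs.kernel.lengthscale
                             if "lengthscale" in fs.kernel.free_names else np.nan,
                             converged=conv,
                             n_restarts=sum(f.n_restarts_used for f in fits)))
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("gene %s failed: %s", dataset.gene_names[i], exc)
            rows.append(dict(gene=dataset.gene_names[i], llr=np.nan,
                             alpha_hat=np.nan, lengthscale_hat=np.nan,
                             converged=False, n_restarts=0))
    return _finalize(pd.DataFrame(rows), df, fdr_level)


def permutation_test(
    dataset: CountsDataset,
    B: int = 100,
    kernel: Optional[KernelSpec] = None,
    likelihood: Optional[LikelihoodSpec] = None,
    *,
    sparse: bool = False,
    M: Optional[int] = None,
    pool: bool = True,
    fdr_level: float = 0.05,
    seed: int = 0,
    outer_maxfev: int = 60,
) -> pd.DataFrame:
    """One-sample test with p-values from a permuted coordinate null.

    Each of the B rounds applies one shared random permutation of the
    coordinates to all genes and recomputes the LLR.  Per-gene p-values use
    the add-one estimator p = (1 + #{null >= observed}) / (1 + K) with the
    null statistics pooled across genes by default (K = B * n_genes).
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    kernel = kernel or KernelSpec("rbf")
    likelihood = likelihood or LikelihoodSpec("negative_binomial")
    obs = _llr_table(dataset, kernel, likelihood, sparse=sparse, M=M, seed=seed,
                     safe_mode=False, outer_maxfev=outer_maxfev)
    if pool and B * dataset.n_genes < 20.0 / fdr_level:
        logger.warning("B=%d gives a coarse null for FDR level %.3g", B, fdr_level)
    rng = np.random.default_rng(seed)
    null_llrs = []
    for b in range(B):
        perm = rng.permutation(dataset.n_samples)
        permuted = CountsDataset(
            counts=dataset.counts, coords=dataset.coords[perm],
            gene_names=dataset.gene_names, scale_factors=dataset.scale_factors,
        )
        tb = _llr_table(permuted, kernel, likelihood, sparse=sparse, M=M,
                        seed=_gene_seed(seed, 7919 + b), safe_mode=False,
                        outer_maxfev=outer_maxfev)
        null_llrs.append(np.clip(tb["llr"].to_numpy(), 0.0, None))
    null_llrs = np.asarray(null_llrs)  # B x G
    obs_llr = np.clip(obs["llr"].to_numpy(), 0.0, None)
    p = np.full(len(obs), np.nan)
    for i in range(len(obs)):
        if not np.isfinite(obs_llr[i]):
            continue
        pool_vals = null_llrs if pool else null_llrs[:, i]
        pool_vals = pool_vals[np.isfinite(pool_vals)]
        p[i] = (1.0 + np.sum(pool_vals >= obs_llr[i])) / (1.0 + pool_vals.size)
    table = obs.copy()
    table["p_value"] = p
    ok = np.isfinite(p)
    q = np.full(len(obs), np.nan)
    if ok.any():
        q[ok] = qvalues(p[ok])
    table["q_value"] = q
    table["is_de"] = pd.Series(q <= fdr_level, index=table.index).fillna(False)
    cols = ["gene", "llr", "p_value", "q_value", "is_de",
            "alpha_hat", "lengthscale_hat", "converged", "n_restarts"]
    return table[cols]
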