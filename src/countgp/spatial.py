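"""Spatially-variable-gene pipeline.

Workflow: filter low-count genes (total < 3) and low-count locations
(total < 10), learn per-gene location scale factors by zero-intercept NB
regression of the gene's counts on the location totals (identity link,
k_i = beta * T_i), then run the one-sample dynamic-vs-constant test with a
2-D isotropic rbf kernel and NB likelihood, with the scale factors
multiplying the count mean.  Significance is assessed by chi-squared
p-values of 2*LLR with Storey q-values at 5% FDR, or by the permuted
coordinate null.

The scale normalization absorbs spatially structured total-count (size)
variation which would otherwise make almost every gene look spatially
variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

from .gp import CountsDataset
from .kernels import KernelSpec
from .likelihoods import LikelihoodSpec, nb_log_pmf
from .testing import _finalize, _llr_table, permutation_test

logger = logging.getLogger(__name__)

__all__ = ["SpatialNormalization", "filter_spatial", "fit_scale_factors", "sv_pipeline"]


@dataclass
class SpatialNormalization:
    """Zero-intercept NB regression fit y_i ~ NB(beta * T_i, r)."""

    beta: float
    r: float
    scale_factors: np.ndarray  # k_i = beta * T_i

    def __post_init__(self) -> None:
        if np.any(self.scale_factors <= 0):
            raise ValueError("scale factors must be positive")


def filter_spatial(counts, coords, min_gene_total: int = 3,
                   min_location_total: int = 10, gene_names=None) -> CountsDataset:
    """Drop genes with total < ``min_gene_total``, then locations with
    total < ``min_location_total`` (each filter applied once, in that order).
    """
    counts = np.asarray(counts)
    coords = np.asarray(coords, dtype=float)
    if gene_names is None:
        gene_names = [f"gene_{i}" for i in range(counts.shape[0])]
    gene_keep = counts.sum(axis=1) >= min_gene_total
    counts = counts[gene_keep]
    names = [g for g, k in zip(gene_names, gene_keep) if k]
    loc_keep = counts.sum(axis=0) >= min_location_total
    counts = counts[:, loc_keep]
    coords = coords[loc_keep]
    if counts.size == 0:
        raise ValueError("filtering removed all genes or locations")
    return CountsDataset(counts=counts, coords=coords, gene_names=names)


def fit_scale_factors(gene_counts, location_totals) -> SpatialNormalization:
    """Maximum-likelihood fit of y_i ~ NB(mean = beta * T_i, r), beta > 0.

    beta is parameterized on the log scale to stay positive; the NB size r
    is fitted jointly.  An all-zero gene has no defined slope and raises.
    """
    y = np.asarray(gene_counts, dtype=float)
    T = np.asarray(location_totals, dtype=float)
    if np.any(T <= 0):
        raise ValueError("location totals must be positive")
    if y.sum() == 0:
        raise ValueError("all-zero gene: slope beta is undefined")
    b0 = max(y.sum() / T.sum(), 1e-12)

    def nll(p):
        beta, r = np.exp(p)
        return -np.sum(nb_log_pmf(y, beta * T, r))

    res = minimize(nll, np.log([b0, 1.0]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxfev": 600})
    beta, r = np.exp(res.x)
    return SpatialNormalization(beta=float(beta), r=float(r),
                                scale_factors=beta * T)


def sv_pipeline(
    dataset: CountsDataset,
    *,
    normalize: bool = True,
    min_gene_total: int = 3,
    min_location_total: int = 10,
    likelihood: Optional[LikelihoodSpec] = None,
    fdr_method: str = "chi2",
    fdr_level: float = 0.05,
    df: int = 2,
    B: int = 100,
    sparse: bool = False,
    M: Optional[int] = None,
    seed: int = 0,
    outer_maxfev: int = 60,
) -> pd.DataFrame:
    """Full spatially-variable-gene detection run.

    Filter -> per-gene NB-regression scale factors -> one-sample test with
    a 2-D rbf kernel (lengthscale initialized at half the median pairwise
    distance) -> chi2 or permutation p-values -> q-values at ``fdr_level``.
    Returns the test table with the fitted slope ``beta`` per gene.
    """
    ds = filter_spatial(dataset.counts, dataset.coords, min_gene_total,
                        min_location_total, dataset.gene_names)
    likelihood = likelihood or LikelihoodSpec("negative_binomial")
    totals = ds.counts.sum(axis=0).astype(float)
    betas = np.full(ds.n_genes, np.nan)
    if normalize:
        sf = np.ones((ds.n_genes, ds.n_samples))
        for i in range(ds.n_genes):
            try:
                norm = fit_scale_factors(ds.counts[i], totals)
                sf[i] = norm.scale_factors
                betas[i] = norm.beta
            except ValueError as exc:
                logger.warning("gene %s: %s (left unnormalized)", ds.gene_names[i], exc)
        ds.scale_factors = sf

    med = np.median(pdist(ds.coords)) if ds.n_samples > 1 else 1.0
    kernel = KernelSpec("rbf", lengthscale=max(med / 2.0, 1e-6))
    kinit = {"k_lengthscale": max(med / 2.0, 1e-6)}
    if fdr_method == "chi2":
        table = _llr_table(ds, kernel, likelihood, sparse=sparse, M=M, seed=seed,
                           safe_mode=False, outer_maxfev=outer_maxfev,
                           kernel_init=kinit)
        table = _finalize(table, df, fdr_level)
    elif fdr_method == "perm":
        table = permutation_test(ds, B=B, kernel=kernel, likelihood=likelihood,
                                 sparse=sparse, M=M, fdr_level=fdr_level,
                                 seed=seed, outer_maxfev=outer_maxfev)
    else:
        raise ValueError("fdr_method must be 'chi2' or 'perm'")
    table = table.copy()
    table["beta"] = betas
    return table
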