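"""Branching-point inference for a single gene.

Two latent functions f (trunk) and g (diverging branch) share a stationary
base kernel and are constrained to cross at a branching point x_b.  The
joint covariance over function values is

    cov(f(x), f(x')) = cov(g(x), g(x')) = k(x, x')
    cov(f(x), g(x')) = k(x, x_b) k(x_b, x') / k(x_b, x_b),

the rank-1 cross term that forces correlation 1 at x = x_b.  Trunk
observations always follow f; branch-lineage observations follow f before
x_b and g after it.  The base-kernel hyper-parameters and likelihood
parameters are fitted once by two separate GP regressions (one per
lineage) and then frozen; the branching time is the only remaining unknown
and its posterior is evaluated on a grid as the normalized per-grid-point
model likelihood (a histogram approximation, adequate for a 1-D
parameter).  For count likelihoods the per-grid-point likelihood is the
variational bound with only the variational distribution re-optimized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_solve
from scipy.special import logsumexp

from .gp import CountsDataset, count_log_ml_fixed, fit_gp
from .kernels import KernelSpec, eval_kernel, safe_cholesky
from .likelihoods import LikelihoodSpec, transform_counts

__all__ = ["BranchingResult", "branching_covariance", "branching_posterior"]


@dataclass
class BranchingResult:
    """Grid posterior over the branching time of one gene."""

    grid: np.ndarray
    posterior: np.ndarray
    map_branch_point: float
    kernel: KernelSpec
    likelihood: LikelihoodSpec
    log_likelihoods: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.posterior.sum(), 1.0, atol=1e-9):
            raise ValueError("posterior must sum to 1")


def branching_covariance(x_f, x_g, x_b: float, kernel: KernelSpec) -> np.ndarray:
    """Joint covariance of [f(x_f), g(x_g)] for two GPs crossing at x_b."""
    x_f = np.asarray(x_f, dtype=float).reshape(-1, 1)
    x_g = np.asarray(x_g, dtype=float).reshape(-1, 1)
    xb = np.array([[float(x_b)]])
    kbb = float(eval_kernel(kernel, xb, xb)[0, 0])
    if kbb <= 0:
        raise ValueError("k(x_b, x_b) = 0: degenerate branch point")
    Kff = eval_kernel(kernel, x_f, x_f)
    Kgg = eval_kernel(kernel, x_g, x_g)
    kf_b = eval_kernel(kernel, x_f, xb)[:, 0]
    kg_b = eval_kernel(kernel, x_g, xb)[:, 0]
    Kfg = np.outer(kf_b, kg_b) / kbb
    top = np.hstack([Kff, Kfg])
    bot = np.hstack([Kfg.T, Kgg])
    return np.vstack([top, bot])


def _joint_cov(x_all, on_g: np.ndarray, x_b: float, kernel: KernelSpec) -> np.ndarray:
    """Joint covariance in the original sample order given a g-assignment mask."""
    x_all = np.asarray(x_all, dtype=float).reshape(-1, 1)
    xb = np.array([[float(x_b)]])
    kbb = float(eval_kernel(kernel, xb, xb)[0, 0])
    if kbb <= 0:
        raise ValueError("k(x_b, x_b) = 0: degenerate branch point")
    K = eval_kernel(kernel, x_all, x_all)
    kb = eval_kernel(kernel, x_all, xb)[:, 0]
    cross = np.outer(kb, kb) / kbb
    diff = on_g[:, None] != on_g[None, :]
    return np.where(diff, cross, K)


def _gauss_marginal_fixed(K, yc, noise):
    n = len(yc)
    L, _ = safe_cholesky(K + noise * np.eye(n), rel_jitter=1e-10)
    a = cho_solve((L, True), yc)
    return float(-0.5 * yc @ a - np.log(np.diag(L)).sum() - 0.5 * n * np.log(2 * np.pi))


def branching_posterior(
    dataset: CountsDataset,
    *,
    gene: int = 0,
    grid: Optional[np.ndarray] = None,
    n_grid: int = 50,
    kernel: Optional[KernelSpec] = None,
    likelihood: Optional[LikelihoodSpec] = None,
    trunk_label: str = "trunk",
    subsample: Optional[float] = None,
    seed: int = 0,
) -> BranchingResult:
    """Posterior over the branching time for one gene.

    ``dataset`` must carry per-cell lineage labels with two values, one of
    them ``trunk_label``.  If ``kernel``/``likelihood`` carry unfitted
    defaults, shared hyper-parameters are first estimated by fitting a
    separate GP regression to each lineage and combining them (geometric
    mean of lengthscale/amplitude, mean of likelihood parameters), then
    frozen across the grid.  ``subsample`` optionally keeps a random
    fraction of cells for tractability.
    """
    if dataset.labels is None:
        raise ValueError("branching requires per-cell lineage labels")
    labels = np.asarray(dataset.labels)
    levels = np.unique(labels)
    if len(levels) != 2 or trunk_label not in levels:
        raise ValueError(f"need two lineage labels including {trunk_label!r}")
    y = dataset.counts[gene].astype(float)
    x = dataset.coords[:, 0]
    if subsample is not None:
        rng = np.random.default_rng(seed)
        keep = rng.random(len(y)) < subsample
        y, x, labels = y[keep], x[keep], labels[keep]
    is_trunk = labels == trunk_label

    likelihood = likelihood or LikelihoodSpec("negative_binomial")
    kernel = kernel or KernelSpec("rbf")

    # shared hyper-parameters from per-lineage fits; a lineage whose fit
    # collapsed onto the constant solution (amplitude ~ 0, lengthscale at
    # the upper bound) carries no information about the shared dynamics and
    # is dropped when the other lineage's fit is healthy
    span = float(np.ptp(x)) or 1.0
    fits = []
    for mask in (is_trunk, ~is_trunk):
        fits.append(fit_gp(y[mask].astype(int), x[mask], kernel=kernel,
                           likelihood=likelihood, seed=seed))
    healthy = [f for f in fits
               if f.kernel.variance > 1e-3 and
               ("lengthscale" not in f.kernel.free_names
                or f.kernel.lengthscale < 5.0 * span)]
    use = healthy or fits
    kw = dict(variance=float(np.exp(np.mean(np.log([f.kernel.variance
                                                    for f in use])))))
    if "lengthscale" in kernel.free_names:
        kw["lengthscale"] = float(np.exp(np.mean(np.log(
            [f.kernel.lengthscale for f in use]))))
    kernel = kernel.with_params(**kw)
    lik_kw = {nm: float(np.mean([getattr(f.likelihood, nm) for f in use]))
              for nm in likelihood.free_names}
    likelihood = likelihood.with_params(**lik_kw)

    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid + 1)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty branching grid")

    if likelihood.family == "gaussian":
        y_t = transform_counts(y, likelihood.transform)
        yc = y_t - y_t.mean()
        scale = None
    else:
        mu0 = float(np.log(max(y.mean(), 1e-3)))
        scale = np.full(len(y), np.exp(mu0))

    lls = np.empty(grid.size)
    warm = None
    for j, xb in enumerate(grid):
        on_g = (~is_trunk) & (x > xb)
        K = _joint_cov(x, on_g, xb, kernel)
        if likelihood.family == "gaussian":
            lls[j] = _gauss_marginal_fixed(K, yc, likelihood.variance)
        else:
            lls[j], warm = count_log_ml_fixed(K, y, likelihood, scale=scale,
                                              x0=warm, maxiter=80)
    if not np.any(np.isfinite(lls)):
        raise FloatingPointError("all grid likelihoods are -inf; cannot normalize")
    post = np.exp(lls - logsumexp(lls))
    post = post / post.sum()
    return BranchingResult(
        grid=grid, posterior=post,
        map_branch_point=float(grid[int(np.argmax(post))]),
        kernel=kernel, likelihood=likelihood, log_likelihoods=lls,
    )
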