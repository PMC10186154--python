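"""Per-gene GP fitting with Gaussian or count likelihoods.

The latent function f(x) is given a zero-mean GP prior with one of the
kernels in :mod:`countgp.kernels`.  For the Gaussian observation model the
log marginal likelihood p(y) = ∫ p(y|f) N(f|0,K) df is available in closed
form and hyper-parameters are optimized directly on it.  For count
likelihoods (NB / ZINB / Poisson, log link) the marginal is intractable and
we maximize an evidence lower bound (ELBO) instead:

* full inference uses the Opper–Archambeau parameterization of the optimal
  Gaussian posterior, q(f) = N(m, (K^-1 + W)^-1) with W diagonal, giving 2N
  free variational parameters;
* sparse inference uses a whitened inducing-point posterior q(u) = N(m, S)
  at M < N inducing locations (O(N M^2) per evaluation), with the Titsias
  collapsed bound in the conjugate Gaussian case.

Expectations of the count log-likelihoods under the Gaussian posterior are
computed by fixed-order Gauss–Hermite quadrature.  Hyper-parameters are
optimized in log space: an outer derivative-free search (Nelder–Mead, a
handful of parameters) wraps an inner quasi-Newton solve of the variational
parameters, warm-started between outer evaluations.

The count mean is mu_i = s_i * exp(f_i), where s_i folds together any
user-supplied scale factor k_i and a fixed empirical offset exp(f0) with
f0 = log(mean(y_i / k_i)); the offset plays the role of a constant prior
mean so the zero-mean latent only has to model relative changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.signal import savgol_filter
from scipy.stats import nbinom, poisson

from .kernels import KernelSpec, eval_kernel, kernel_grads, safe_cholesky
from .likelihoods import (
    LikelihoodSpec,
    gauss_hermite,
    log_density,
    log_density_df,
    transform_counts,
)

__all__ = [
    "CountsDataset",
    "GPFit",
    "fit_gp",
    "select_inducing_points",
    "safe_mode_refit",
    "bic",
    "credible_region",
]


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class CountsDataset:
    """Gene-by-sample counts with per-sample coordinates.

    counts : (n_genes, n_samples) non-negative integers
    coords : (n_samples,) or (n_samples, 2) float positions (time,
        pseudotime, or 2-D spatial locations)
    gene_names / sample_names : optional identifiers
    labels : optional per-sample condition or lineage tags
    scale_factors : optional (n_genes, n_samples) or (n_samples,) positive
        multipliers k_i on the count mean
    """

    counts: np.ndarray
    coords: np.ndarray
    gene_names: Optional[Sequence[str]] = None
    sample_names: Optional[Sequence[str]] = None
    labels: Optional[np.ndarray] = None
    scale_factors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples array")
        if np.any(self.counts < 0) or not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be non-negative integers")
        self.counts = np.asarray(np.round(self.counts), dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 1:
            self.coords = self.coords[:, None]
        if self.coords.shape[0] != self.counts.shape[1]:
            raise ValueError("coords length must match number of samples")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.gene_names is None:
            self.gene_names = [f"gene_{i}" for i in range(self.counts.shape[0])]
        self.gene_names = list(self.gene_names)
        if self.sample_names is None:
            self.sample_names = [f"sample_{i}" for i in range(self.counts.shape[1])]
        self.sample_names = list(self.sample_names)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.counts.shape[1]:
                raise ValueError("labels length must match number of samples")
        if self.scale_factors is not None:
            self.scale_factors = np.asarray(self.scale_factors, dtype=float)
            if np.any(self.scale_factors <= 0):
                raise ValueError("scale factors must be positive")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def gene_scale(self, i: int) -> np.ndarray:
        if self.scale_factors is None:
            return np.ones(self.n_samples)
        if self.scale_factors.ndim == 1:
            return self.scale_factors
        return self.scale_factors[i]

    def subset_samples(self, mask: np.ndarray) -> "CountsDataset":
        sf = self.scale_factors
        if sf is not None:
            sf = sf[mask] if sf.ndim == 1 else sf[:, mask]
        return CountsDataset(
            counts=self.counts[:, mask],
            coords=self.coords[mask],
            gene_names=self.gene_names,
            sample_names=[s for s, keep in zip(self.sample_names, mask) if keep],
            labels=None if self.labels is None else self.labels[mask],
            scale_factors=sf,
        )


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class GPFit:
    """A fitted single-gene GP model.

    ``log_ml`` is the exact log marginal likelihood for Gaussian likelihoods
    and the converged ELBO otherwise; both are used interchangeably wherever
    a marginal likelihood is required (LLR, BIC).
    """

    kernel: KernelSpec
    likelihood: LikelihoodSpec
    log_ml: float
    converged: bool
    n_restarts_used: int = 0
    inducing_points: Optional[np.ndarray] = None
    method: str = "exact"  # exact | titsias | vgp | svgp
    X: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    scale: Optional[np.ndarray] = None  # effective per-sample mean scale
    mean_offset: float = 0.0
    elbo_trace: Optional[np.ndarray] = None
    _state: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# Gaussian likelihood: exact marginal and Titsias collapsed bound
# ---------------------------------------------------------------------------


def _gauss_log_ml(kspec: KernelSpec, X, yc, noise, with_grads=False):
    """Closed-form log N(yc | 0, K + noise*I) and gradients in log-params."""
    n = len(yc)
    K = eval_kernel(kspec, X)
    Ky = K + noise * np.eye(n)
    L, jit = safe_cholesky(Ky, rel_jitter=1e-10)
    a = cho_solve((L, True), yc)
    lml = -0.5 * yc @ a - np.log(np.diag(L)).sum() - 0.5 * n * np.log(2 * np.pi)
    if not with_grads:
        return lml
    Kinv = cho_solve((L, True), np.eye(n))
    outer = np.outer(a, a)
    grads = []
    for dK in kernel_grads(kspec, X):
        grads.append(0.5 * np.sum(outer * dK) - 0.5 * np.sum(Kinv * dK))
    # noise term, d(noise*I)/dlog noise = noise*I
    grads.append(0.5 * noise * (a @ a) - 0.5 * noise * np.trace(Kinv))
    return lml, np.array(grads)


def _titsias_bound(kspec: KernelSpec, X, Z, yc, noise):
    """Titsias' collapsed sparse-GP lower bound for Gaussian noise (dense)."""
    n = len(yc)
    Kzz = eval_kernel(kspec, Z)
    Lz, _ = safe_cholesky(Kzz)
    Kfz = eval_kernel(kspec, X, Z)
    V = solve_triangular(Lz, Kfz.T, lower=True)  # M x N
    Qnn = V.T @ V
    kdiag = np.diag(eval_kernel(kspec, X))
    Qy = Qnn + noise * np.eye(n)
    L, _ = safe_cholesky(Qy, rel_jitter=1e-10)
    a = cho_solve((L, True), yc)
    bound = (
        -0.5 * yc @ a
        - np.log(np.diag(L)).sum()
        - 0.5 * n * np.log(2 * np.pi)
        - 0.5 * np.sum(np.clip(kdiag - np.diag(Qnn), 0.0, None)) / noise
    )
    return bound


# ---------------------------------------------------------------------------
# count likelihoods: variational inner solvers
# ---------------------------------------------------------------------------


def _quad_terms(spec, y, s, m, v, t, w):
    """Sum of E_q[log p], and gradients w.r.t. q means/variances."""
    rt = np.sqrt(2.0 * np.clip(v, 1e-12, None))
    f = m[:, None] + rt[:, None] * t
    lp = log_density(spec, y[:, None], f, s[:, None])
    d1 = log_density_df(spec, y[:, None], f, s[:, None])
    psi = lp @ w
    gmu = d1 @ w
    gv = (d1 * t) @ w / rt
    return psi.sum(), gmu, gv


def _vgp_solve(K, y, spec, s, order=20, x0=None, maxiter=60, gtol=None, ftol=1e-6):
    """Full variational fit with q(f) = N(m, (K^-1 + W)^-1), W = diag(w).

    Solved by the damped fixed-point iteration of the Opper–Archambeau
    scheme: at the optimum W = -2 dE/dv and m satisfies the Newton
    condition m = Sigma (g_mu + W m).  Each candidate step is accepted only
    if the ELBO does not decrease (halving the step otherwise), so the
    returned trace is monotone.  ``gtol`` is accepted for interface
    symmetry with the sparse solver and ignored.

    Returns (elbo, params, q_mean, q_var, trace, state); ``params`` is
    [m, log W] and can warm-start a later call.
    """
    n = len(y)
    if gtol is not None:
        ftol = gtol
    L, jit = safe_cholesky(K)
    t, w_q = gauss_hermite(order)
    eye = np.eye(n)
    trace: list[float] = []

    def evaluate(m, W):
        Wh = np.sqrt(W)
        B = eye + Wh[:, None] * K * Wh[None, :]
        Lb = np.linalg.cholesky(B)
        V = solve_triangular(Lb, Wh[:, None] * K, lower=True)
        vdiag = np.clip(np.diag(K) - np.einsum("ij,ij->j", V, V), 1e-12, None)
        psi, gmu, gv = _quad_terms(spec, y, s, m, vdiag, t, w_q)
        alpha_m = cho_solve((L, True), m)
        kl = 0.5 * (m @ alpha_m - W @ vdiag + 2.0 * np.log(np.diag(Lb)).sum())
        return psi - kl, gmu, gv, (Wh, Lb, V, vdiag)

    def sigma_dot(aux, z):
        Wh, Lb, V, _ = aux
        u = solve_triangular(Lb, Wh * (K @ z), lower=True)
        return K @ z - V.T @ u

    if x0 is None:
        m = np.zeros(n)
        W = np.ones(n)
    else:
        m, W = x0[:n].copy(), np.exp(np.clip(x0[n:], -18.0, 15.0))
    elbo, gmu, gv, aux = evaluate(m, W)
    trace.append(elbo)
    for _ in range(maxiter):
        W_t = np.clip(-2.0 * gv, 1e-8, 1e8)
        m_t = sigma_dot(aux, gmu + W * m)
        step = 1.0
        accepted = False
        for _ls in range(8):
            m_new = m + step * (m_t - m)
            W_new = np.exp(np.log(W) + step * (np.log(W_t) - np.log(W)))
            try:
                e_new, gmu_n, gv_n, aux_n = evaluate(m_new, W_new)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if np.isfinite(e_new) and e_new >= elbo - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        delta = e_new - elbo
        m, W, elbo, gmu, gv, aux = m_new, W_new, e_new, gmu_n, gv_n, aux_n
        trace.append(elbo)
        if delta < ftol:
            break
    Wh, Lb, V, vdiag = aux
    state = {"m": m, "Wh": Wh, "Lb": Lb, "Kchol": L, "jitter": jit}
    params = np.concatenate([m, np.log(W)])
    return elbo, params, m, vdiag, np.array(trace), state


def _const_solve(y, spec, s, sf2, order=20, x0=None, maxiter=200, gtol=1e-8):
    """Variational fit of the constant-latent model f(x) = c, c ~ N(0, sf2).

    Equivalent to the full GP with the constant kernel (and to the rbf
    kernel in the infinite-lengthscale limit) but with a scalar latent, so
    it costs O(N) instead of O(N^3) per evaluation.
    """
    t, w_q = gauss_hermite(order)

    def negelbo(p):
        mc, vc = p[0], np.exp(np.clip(p[1], -30.0, 30.0))
        psi, gmu, gv = _quad_terms(spec, y, s, np.full_like(y, mc), np.full_like(y, vc), t, w_q)
        kl = 0.5 * (mc**2 / sf2 + vc / sf2 - 1.0 - np.log(vc / sf2))
        g_m = gmu.sum() - mc / sf2
        g_v = gv.sum() - 0.5 * (1.0 / sf2 - 1.0 / vc)
        return -(psi - kl), -np.array([g_m, g_v * vc])

    if x0 is None:
        x0 = np.array([0.0, np.log(min(sf2, 1.0))])
    res = minimize(negelbo, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol})
    mc, vc = res.x[0], float(np.exp(np.clip(res.x[1], -30.0, 30.0)))
    state = {"mc": mc, "vc": vc}
    return -res.fun, res.x, mc, vc, state


def _pack_chol(Ls, tril_idx):
    raw = Ls[tril_idx].copy()
    M = Ls.shape[0]
    diag_pos = np.cumsum(np.arange(1, M + 1)) - 1
    raw[diag_pos] = np.log(np.diag(Ls))
    return raw


def _unpack_chol(raw, M, tril_idx):
    Ls = np.zeros((M, M))
    Ls[tril_idx] = raw
    diag = np.exp(np.clip(np.diag(Ls), -20.0, 10.0))
    Ls[np.diag_indices(M)] = diag
    return Ls


def _svgp_solve(A, kdiag, y, spec, s, order=20, x0=None, maxiter=250, gtol=1e-6):
    """Whitened sparse variational fit, q(eps) = N(m, S), f = A eps + r.

    A = Kfz Lz^{-T} is the whitened projection; the residual conditional
    variance kdiag - rowsum(A^2) is part of each marginal q(f_i).
    """
    n, M = A.shape
    t, w_q = gauss_hermite(order)
    tril_idx = np.tril_indices(M)
    resid = np.clip(kdiag - np.sum(A**2, axis=1), 0.0, None)
    trace: list[float] = []
    diag_pos = np.cumsum(np.arange(1, M + 1)) - 1

    def negelbo(p):
        m = p[:M]
        Ls = _unpack_chol(p[M:], M, tril_idx)
        mu = A @ m
        ALs = A @ Ls
        v = np.clip(resid + np.sum(ALs**2, axis=1), 1e-12, None)
        psi, gmu, gv = _quad_terms(spec, y, s, mu, v, t, w_q)
        ldiag = np.diag(Ls)
        kl = 0.5 * (m @ m + np.sum(Ls**2) - M) - np.log(ldiag).sum()
        elbo = psi - kl
        g_m = A.T @ gmu - m
        G_L = 2.0 * (A.T @ (gv[:, None] * ALs)) - Ls
        G_L[np.diag_indices(M)] += 1.0 / ldiag
        g_raw = G_L[tril_idx]
        g_raw[diag_pos] *= ldiag  # chain rule through log-diagonal
        grad = np.concatenate([g_m, g_raw])
        trace.append(elbo)
        return -elbo, -grad

    if x0 is None:
        x0 = np.concatenate([np.zeros(M), _pack_chol(np.eye(M), tril_idx)])
    res = minimize(
        negelbo, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol},
    )
    m = res.x[:M]
    Ls = _unpack_chol(res.x[M:], M, tril_idx)
    mu = A @ m
    v = np.clip(resid + np.sum((A @ Ls) ** 2, axis=1), 1e-12, None)
    state = {"m": m, "Ls": Ls}
    return -res.fun, res.x, mu, v, np.array(trace), state


def count_log_ml_fixed(K, y, likelihood, scale=None, order=20, x0=None, maxiter=250):
    """ELBO of a count-likelihood GP with a *given* covariance matrix.

    Hyper-parameters are frozen inside K and ``likelihood``; only the
    variational distribution is optimized.  Used by the branching-point
    grid search, where the joint covariance is assembled externally.
    """
    y = np.asarray(y, dtype=float)
    s = np.ones_like(y) if scale is None else np.asarray(scale, dtype=float)
    elbo, params, m, v, trace, state = _vgp_solve(
        np.asarray(K, dtype=float), y, likelihood, s, order=order, x0=x0,
        maxiter=maxiter,
    )
    return elbo, params


# ---------------------------------------------------------------------------
# inducing-point selection
# ---------------------------------------------------------------------------


def select_inducing_points(coords, M, method="mdpp", kernel=None, seed=0, eps=1e-12):
    """Choose M inducing locations among (or summarizing) the inputs.

    ``mdpp`` greedily maximizes the determinant of the kernel submatrix
    (greedy MAP of an M-determinantal point process, computed by pivoted
    Cholesky; ties broken by lowest index; stops early if the determinant
    increment falls below ``eps``).  ``kmeans`` returns cluster centers.
    M = N returns the inputs unchanged for either method.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 1 <= M <= n:
        raise ValueError(f"M must be in [1, {n}], got {M}")
    if M == n:
        return X.copy()
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=M, n_init=4, random_state=seed).fit(X)
        return km.cluster_centers_
    if method != "mdpp":
        raise ValueError(f"unknown inducing method {method!r}")
    if kernel is None:
        from scipy.spatial.distance import pdist

        med = np.median(pdist(X)) if n > 1 else 1.0
        kernel = KernelSpec("rbf", lengthscale=max(med, 1e-6), variance=1.0)
    K = eval_kernel(kernel, X)
    # pivoted Cholesky: residual conditional variances are the greedy scores
    d = np.diag(K).astype(float).copy()
    Lrows = np.zeros((M, n))
    chosen: list[int] = []
    for j in range(M):
        i = int(np.argmax(d))  # argmax takes the lowest index on ties
        if d[i] <= eps:
            break
        chosen.append(i)
        Lrows[j] = (K[i] - Lrows[:j].T @ Lrows[:j, i]) / np.sqrt(d[i])
        d = d - Lrows[j] ** 2
        d[chosen] = -np.inf
    return X[np.array(chosen, dtype=int)]


# ---------------------------------------------------------------------------
# main fitting entry point
# ---------------------------------------------------------------------------

_BOUNDS_LOG = {
    "alpha": (np.log(1e-4), np.log(100.0)),
    "kappa": (np.log(1e-3), np.log(1e6)),
}


def _hyper_bounds(kspec: KernelSpec, lspec: LikelihoodSpec, span: float, yvar: float):
    names, lo, hi = [], [], []
    for nm in kspec.free_names:
        names.append("k_" + nm)
        if nm == "lengthscale":
            lo.append(np.log(max(span, 1e-6) * 1e-2))
            hi.append(np.log(max(span, 1e-6) * 1e3))
        elif nm == "variance":
            lo.append(np.log(1e-6))
            hi.append(np.log(1e4))
        else:  # period
            lo.append(np.log(max(span, 1e-6) * 0.05))
            hi.append(np.log(max(span, 1e-6) * 4.0))
    for nm in lspec.free_names:
        names.append("l_" + nm)
        if nm == "variance":
            v = max(yvar, 1e-4)
            lo.append(np.log(v * 1e-4))
            hi.append(np.log(v * 1e2))
        else:
            b = _BOUNDS_LOG[nm]
            lo.append(b[0])
            hi.append(b[1])
    return names, np.array(lo), np.array(hi)


def _apply_theta(kspec, lspec, names, theta):
    kw_k, kw_l = {}, {}
    for nm, th in zip(names, theta):
        val = float(np.exp(th))
        if nm.startswith("k_"):
            kw_k[nm[2:]] = val
        else:
            kw_l[nm[2:]] = val
    return kspec.with_params(**kw_k), lspec.with_params(**kw_l)


def fit_gp(
    y,
    x,
    kernel: Optional[KernelSpec] = None,
    likelihood: Optional[LikelihoodSpec] = None,
    *,
    sparse: bool = False,
    M: Optional[int] = None,
    inducing_method: str = "mdpp",
    scale_factors=None,
    init: Optional[dict] = None,
    optimize: bool = True,
    outer_maxfev: int = 60,
    quad_order: int = 20,
    seed: int = 0,
) -> GPFit:
    """Fit a GP to one gene's observations.

    Parameters
    ----------
    y, x
        Counts (or counts to be transformed, for Gaussian likelihoods) and
        their 1-D or 2-D coordinates.
    kernel, likelihood
        Starting specs; free hyper-parameters are optimized unless
        ``optimize=False``.  Defaults: rbf kernel, NB likelihood.
    sparse, M, inducing_method
        Sparse inducing-point inference with M locations (default
        ceil(0.05 N)) chosen by the M-DPP greedy algorithm or k-means.
    scale_factors
        Per-sample positive multipliers k_i entering the count mean as
        mu_i = k_i * exp(f_i); ignored for Gaussian likelihoods.
    init
        Optional {hyper-name: value} overrides of the default
        initialization, e.g. ``{"k_lengthscale": 10.0, "l_alpha": 0.5}``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if n < 4:
        raise ValueError("at least 4 samples are required")
    if X.shape[0] != n:
        raise ValueError("y and x must have equal length")
    kernel = kernel or KernelSpec("rbf")
    likelihood = likelihood or LikelihoodSpec("negative_binomial")
    span = float(np.ptp(X[:, 0])) if X.shape[0] > 1 else 1.0
    if X.shape[1] > 1:
        span = float(np.median([np.ptp(X[:, j]) for j in range(X.shape[1])]))

    if sparse:
        if M is None:
            M = int(np.ceil(0.05 * n))
        if not 1 <= M < n:
            raise ValueError("sparse fitting requires 1 <= M < N")
        Z = select_inducing_points(X, M, method=inducing_method, seed=seed)
    else:
        Z = None

    is_count = likelihood.is_count
    if is_count:
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("count likelihoods require non-negative integer y")
        k_i = np.ones(n) if scale_factors is None else np.asarray(scale_factors, float)
        if np.any(k_i <= 0):
            raise ValueError("scale factors must be positive")
        mu0 = float(np.log(max(np.mean(y / k_i), 1e-3)))
        s_eff = k_i * np.exp(mu0)
        y_work = y
        yvar = float(np.var(np.log1p(y)))
    else:
        y_t = transform_counts(y, likelihood.transform) if likelihood.transform != "none" else y
        mu0 = float(np.mean(y_t))
        y_work = y_t - mu0
        s_eff = np.ones(n)
        yvar = float(np.var(y_work))

    # --- initialization -----------------------------------------------------
    init = dict(init or {})
    start = {}
    for nm in kernel.free_names:
        if nm == "lengthscale":
            start["k_lengthscale"] = span / 3.0 if span > 0 else 1.0
        elif nm == "variance":
            start["k_variance"] = max(yvar, 0.01)
        else:
            start["k_period"] = span / 2.0 if span > 0 else 1.0
    for nm in likelihood.free_names:
        if nm == "alpha":
            start["l_alpha"] = 1.0
        elif nm == "kappa":
            start["l_kappa"] = max(float(np.mean(y)), 0.1)
        else:
            start["l_variance"] = max(yvar, 1e-4)
    start.update(init)
    names, lo, hi = _hyper_bounds(kernel, likelihood, span, yvar)
    theta0 = np.array([np.log(start[nm]) for nm in names])
    theta0 = np.clip(theta0, lo, hi)

    best = {"val": -np.inf, "theta": theta0, "inner": None}
    warm = {"x0": None}

    # --- objective over hyper-parameters ------------------------------------
    if not is_count:

        def neg_lml(theta):
            theta = np.clip(theta, lo, hi)
            ks, ls = _apply_theta(kernel, likelihood, names, theta)
            try:
                if sparse:
                    val = _titsias_bound(ks, X, Z, y_work, ls.variance)
                    grads = None
                else:
                    val, grads = _gauss_log_ml(ks, X, y_work, ls.variance, with_grads=True)
            except np.linalg.LinAlgError:
                return (np.inf, np.zeros_like(theta)) if not sparse else np.inf
            if val > best["val"]:
                best.update(val=val, theta=theta.copy())
            if sparse:
                return -val
            return -val, -grads

        if optimize:
            if sparse:
                minimize(neg_lml, theta0, method="Nelder-Mead",
                         bounds=list(zip(lo, hi)),
                         options={"maxfev": outer_maxfev, "xatol": 1e-3, "fatol": 1e-5})
            else:
                minimize(neg_lml, theta0, jac=True, method="L-BFGS-B",
                         bounds=list(zip(lo, hi)), options={"maxiter": 200})
        # evaluate at the best theta (also covers optimize=False)
        neg_lml(best["theta"] if optimize else theta0)
        ks, ls = _apply_theta(kernel, likelihood, names, best["theta"])
        converged = np.isfinite(best["val"])
        fit = GPFit(
            kernel=ks, likelihood=ls, log_ml=float(best["val"]), converged=bool(converged),
            inducing_points=Z, method="titsias" if sparse else "exact",
            X=X, y=y, scale=None, mean_offset=mu0,
        )
        fit._state = {"y_work": y_work}
        return fit

    # --- count likelihoods ---------------------------------------------------
    if kernel.family == "constant":
        # scalar-latent shortcut: f(x) = c with c ~ N(0, sf2)
        cbest = {"val": -np.inf, "theta": theta0, "state": None, "ks": None, "ls": None}
        cwarm = {"x0": None}

        def neg_elbo_c(theta):
            theta = np.clip(theta, lo, hi)
            ks, ls = _apply_theta(kernel, likelihood, names, theta)
            elbo, params, mc, vc, st = _const_solve(
                y_work, ls, s_eff, ks.variance, order=quad_order, x0=cwarm["x0"]
            )
            cwarm["x0"] = params
            if elbo > cbest["val"]:
                cbest.update(val=elbo, theta=theta.copy(), state=st, ks=ks, ls=ls)
            return -elbo

        if optimize and outer_maxfev > 0:
            minimize(neg_elbo_c, theta0, method="Nelder-Mead",
                     bounds=list(zip(lo, hi)),
                     options={"maxfev": outer_maxfev, "xatol": 1e-2, "fatol": 1e-3})
        else:
            neg_elbo_c(theta0)
        fit = GPFit(
            kernel=cbest["ks"], likelihood=cbest["ls"], log_ml=float(cbest["val"]),
            converged=bool(np.isfinite(cbest["val"])), method="const",
            X=X, y=y, scale=s_eff, mean_offset=mu0,
        )
        fit._state = dict(cbest["state"])
        return fit

    trace_store = {"trace": None, "state": None}

    def neg_elbo(theta, inner_maxiter=60, inner_gtol=1e-4):
        theta = np.clip(theta, lo, hi)
        ks, ls = _apply_theta(kernel, likelihood, names, theta)
        try:
            if sparse:
                Kzz = eval_kernel(ks, Z)
                Lz, _ = safe_cholesky(Kzz)
                Kfz = eval_kernel(ks, X, Z)
                A = solve_triangular(Lz, Kfz.T, lower=True).T
                kdiag = np.diag(eval_kernel(ks, X)).copy()
                elbo, params, m, v, trace, st = _svgp_solve(
                    A, kdiag, y_work, ls, s_eff, order=quad_order,
                    x0=warm["x0"], maxiter=inner_maxiter, gtol=inner_gtol,
                )
                st.update(A=A, Lz=Lz, kdiag=kdiag)
            else:
                K = eval_kernel(ks, X)
                elbo, params, m, v, trace, st = _vgp_solve(
                    K, y_work, ls, s_eff, order=quad_order,
                    x0=warm["x0"], maxiter=inner_maxiter, gtol=inner_gtol,
                )
        except np.linalg.LinAlgError:
            return np.inf
        warm["x0"] = params
        if elbo > best["val"]:
            best.update(val=elbo, theta=theta.copy(), inner=params.copy())
            trace_store["trace"] = trace
            trace_store["state"] = st
        return -elbo

    if optimize and outer_maxfev > 0:
        # the dispersion direction has a second basin ("constant latent +
        # inflated alpha"); start once from each side unless the caller
        # pinned alpha explicitly
        starts = [theta0]
        if "l_alpha" in names and "l_alpha" not in init:
            alt = theta0.copy()
            alt[names.index("l_alpha")] = np.log(0.05)
            starts.append(np.clip(alt, lo, hi))
        fev = max(outer_maxfev // len(starts), 10)
        for th0 in starts:
            warm["x0"] = None
            minimize(neg_elbo, th0, method="Nelder-Mead",
                     bounds=list(zip(lo, hi)),
                     options={"maxfev": fev, "xatol": 1e-2, "fatol": 1e-3})
        # polish the variational parameters at the selected hyper-parameters
        warm["x0"] = best["inner"]
        neg_elbo(best["theta"], inner_maxiter=400, inner_gtol=1e-6)
    else:
        neg_elbo(theta0, inner_maxiter=400, inner_gtol=1e-6)

    ks, ls = _apply_theta(kernel, likelihood, names, best["theta"])
    converged = np.isfinite(best["val"])
    fit = GPFit(
        kernel=ks, likelihood=ls, log_ml=float(best["val"]), converged=bool(converged),
        inducing_points=Z, method="svgp" if sparse else "vgp",
        X=X, y=y, scale=s_eff, mean_offset=mu0,
        elbo_trace=trace_store["trace"],
    )
    fit._state = dict(trace_store["state"] or {})
    fit._state["theta_names"] = names
    return fit


# ---------------------------------------------------------------------------
# posterior prediction, safe mode, BIC, credible regions
# ---------------------------------------------------------------------------


def predict_latent(fit: GPFit, Xnew):
    """Posterior mean and variance of the latent f at new inputs."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim == 1:
        Xnew = Xnew[:, None]
    X = fit.X
    Ks = eval_kernel(fit.kernel, Xnew, X)
    kss = np.diag(eval_kernel(fit.kernel, Xnew)).copy()
    st = fit._state
    if fit.method == "exact":
        noise = fit.likelihood.variance
        Ky = eval_kernel(fit.kernel, X) + noise * np.eye(len(fit.y))
        L, _ = safe_cholesky(Ky, rel_jitter=1e-10)
        a = cho_solve((L, True), st["y_work"])
        mean = Ks @ a
        V = solve_triangular(L, Ks.T, lower=True)
        var = np.clip(kss - np.sum(V**2, axis=0), 1e-12, None)
        return mean, var
    if fit.method == "vgp":
        Kchol, m, Wh, Lb = st["Kchol"], st["m"], st["Wh"], st["Lb"]
        mean = Ks @ cho_solve((Kchol, True), m)
        # cov* = K** - K*f Wh B^-1 Wh Kf*
        U = solve_triangular(Lb, Wh[:, None] * Ks.T, lower=True)
        var = np.clip(kss - np.sum(U**2, axis=0), 1e-12, None)
        return mean, var
    if fit.method == "svgp":
        A_new = solve_triangular(st["Lz"], eval_kernel(fit.kernel, fit.inducing_points, Xnew), lower=True).T
        m, Ls = st["m"], st["Ls"]
        mean = A_new @ m
        resid = np.clip(kss - np.sum(A_new**2, axis=1), 0.0, None)
        var = np.clip(resid + np.sum((A_new @ Ls) ** 2, axis=1), 1e-12, None)
        return mean, var
    if fit.method == "const":
        nnew = Xnew.shape[0]
        return np.full(nnew, st["mc"]), np.full(nnew, st["vc"])
    raise ValueError(f"cannot predict from method {fit.method!r}")


def bic(fit: GPFit, N: Optional[int] = None, d: Optional[int] = None) -> float:
    """Bayesian information criterion d*ln(N) - 2*log_ml.

    N defaults to the number of observations in the fit and d to the number
    of optimized hyper-parameters (kernel + likelihood).
    """
    if N is None:
        N = len(fit.y)
    if d is None:
        d = len(fit.kernel.free_names) + len(fit.likelihood.free_names)
    if N < 1 or d < 1:
        raise ValueError("N and d must be positive")
    return d * np.log(N) - 2.0 * fit.log_ml


def _posterior_median_counts(fit: GPFit):
    mean_f, _ = predict_latent(fit, fit.X)
    lik = fit.likelihood
    if lik.family == "gaussian":
        return mean_f + fit.mean_offset  # median = mean, transformed scale
    mu = fit.scale * np.exp(np.clip(mean_f, -45, 45))
    if lik.family == "poisson":
        return poisson.ppf(0.5, mu)
    r = 1.0 / max(lik.alpha, 1e-8)
    return nbinom.ppf(0.5, r, r / (r + mu))


def _one_sided_fraction(fit: GPFit) -> float:
    """Fraction of observations on the majority side of the posterior median."""
    med = _posterior_median_counts(fit)
    if fit.likelihood.family == "gaussian":
        obs = transform_counts(fit.y, fit.likelihood.transform)
    else:
        obs = fit.y
    above = np.sum(obs > med)
    below = np.sum(obs < med)
    m = max(above, below)
    tot = above + below
    return m / tot if tot else 0.0


def safe_mode_refit(fit: GPFit, max_restarts: int = 5, seed: int = 0, threshold: float = 0.9) -> GPFit:
    """Detect numerical failures or suspected local optima and restart.

    A fit is suspect when it did not converge, its objective is not finite,
    or the posterior predictive median lies strictly on one side of at least
    ``threshold`` of the observations.  Restarts redraw the free
    hyper-parameters log-uniformly within their bounds; the fit with the
    highest objective is returned.
    """
    ok = fit.converged and np.isfinite(fit.log_ml)
    if ok and _one_sided_fraction(fit) < threshold:
        return fit
    rng = np.random.default_rng(seed)
    span = float(np.ptp(fit.X[:, 0])) if len(fit.y) > 1 else 1.0
    yvar = float(np.var(np.log1p(fit.y)))
    names, lo, hi = _hyper_bounds(fit.kernel, fit.likelihood, span, yvar)
    best = fit
    used = fit.n_restarts_used
    for _ in range(max_restarts):
        used += 1
        theta = rng.uniform(lo, hi)
        init = {nm: float(np.exp(t)) for nm, t in zip(names, theta)}
        try:
            cand = fit_gp(
                fit.y, fit.X, kernel=fit.kernel, likelihood=fit.likelihood,
                sparse=fit.method in ("svgp", "titsias"),
                M=None if fit.inducing_points is None else len(fit.inducing_points),
                init=init, seed=seed,
            )
        except (np.linalg.LinAlgError, ValueError):
            continue
        if np.isfinite(cand.log_ml) and (not np.isfinite(best.log_ml) or cand.log_ml > best.log_ml):
            best = cand
        if best.converged and np.isfinite(best.log_ml) and _one_sided_fraction(best) < threshold:
            break
    best.n_restarts_used = used
    if not np.isfinite(best.log_ml):
        best.converged = False
    return best


def credible_region(fit: GPFit, grid_size: int = 100, n_samples: int = 100, seed: int = 0,
                    smooth: bool = True):
    """Posterior predictive mean curve and [5%, 95%] band on a regular grid.

    Draws ``n_samples`` latent functions on ``grid_size`` equally spaced
    1-D inputs, exponentiates them into count-distribution means, draws
    counts, and returns the pointwise mean with 5th/95th percentiles.  The
    mean is smoothed with a cubic Savitzky–Golay filter and the band edges
    with LOWESS.
    """
    if not fit.converged:
        raise RuntimeError("refusing to draw credible regions from a non-converged fit")
    if fit.X.shape[1] != 1:
        raise ValueError("credible regions are defined for 1-D inputs")
    rng = np.random.default_rng(seed)
    grid = np.linspace(fit.X[:, 0].min(), fit.X[:, 0].max(), grid_size)
    Ks = eval_kernel(fit.kernel, grid[:, None], fit.X)
    Kss = eval_kernel(fit.kernel, grid[:, None])
    mean_f, _ = predict_latent(fit, grid[:, None])
    # joint posterior covariance on the grid
    st = fit._state
    if fit.method == "exact":
        Ky = eval_kernel(fit.kernel, fit.X) + fit.likelihood.variance * np.eye(len(fit.y))
        L, _ = safe_cholesky(Ky, rel_jitter=1e-10)
        V = solve_triangular(L, Ks.T, lower=True)
        cov = Kss - V.T @ V
    elif fit.method == "vgp":
        U = solve_triangular(st["Lb"], st["Wh"][:, None] * Ks.T, lower=True)
        cov = Kss - U.T @ U
    else:  # svgp
        A_new = solve_triangular(st["Lz"], eval_kernel(fit.kernel, fit.inducing_points, grid[:, None]), lower=True).T
        cov = Kss - A_new @ A_new.T + (A_new @ st["Ls"]) @ (A_new @ st["Ls"]).T
    Lc, _ = safe_cholesky(cov, rel_jitter=1e-8)
    eps = rng.standard_normal((n_samples, grid_size))
    f_samp = mean_f[None, :] + eps @ Lc.T

    lik = fit.likelihood
    if lik.family == "gaussian":
        draws = f_samp + fit.mean_offset + rng.standard_normal(f_samp.shape) * np.sqrt(lik.variance)
    else:
        mu = np.exp(np.clip(f_samp + fit.mean_offset, -45, 45))
        if lik.family == "poisson":
            draws = rng.poisson(mu).astype(float)
        else:
            r = 1.0 / max(lik.alpha, 1e-8)
            draws = rng.negative_binomial(r, r / (r + mu)).astype(float)
            if lik.family == "zinb":
                psi = lik.kappa / (lik.kappa + mu)
                draws = np.where(rng.uniform(size=mu.shape) < psi, 0.0, draws)
    mean_curve = draws.mean(axis=0)
    lo_curve = np.percentile(draws, 5, axis=0)
    hi_curve = np.percentile(draws, 95, axis=0)
    if smooth and grid_size >= 7:
        window = min(grid_size // 2 * 2 - 1, 15)
        mean_curve = savgol_filter(mean_curve, window_length=max(window, 5), polyorder=3)
        from statsmodels.nonparametric.smoothers_lowess import lowess

        lo_curve = lowess(lo_curve, grid, frac=0.3, return_sorted=False)
        hi_curve = lowess(hi_curve, grid, frac=0.3, return_sorted=False)
    return grid, mean_curve, lo_curve, hi_curve
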