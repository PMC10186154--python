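"""Observation models for counts: NB, ZINB, Poisson, and Gaussian.

Count likelihoods use a logarithmic link: the latent GP function f models
log mu, so the count mean is mu = s * exp(f) where s is an optional
per-sample scale factor.  The negative binomial is parameterized by mean mu
and r = 1/alpha failures, so Var[y] = mu + alpha * mu^2; alpha -> 0 recovers
the Poisson.  The zero-inflated NB mixes in extra mass at zero with a
Michaelis-Menten dropout probability psi(mu) = kappa / (kappa + mu), which
decreases with the mean: highly expressed genes drop out rarely.

The Gaussian family operates on transformed counts (log1p or Anscombe) with
an identity link and is exact under GP regression; it exists mainly as the
baseline the count likelihoods are compared against.

All densities are evaluated in log space via log-gamma functions so they
stay finite for counts and means up to at least 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln, logsumexp

FAMILIES = ("negative_binomial", "zinb", "poisson", "gaussian")
TRANSFORMS = ("log1p", "anscombe", "none")


@dataclass(frozen=True)
class LikelihoodSpec:
    """Observation-model family and its parameters.

    ``alpha`` is the NB/ZINB dispersion (dimensionless, >= 0); ``kappa`` the
    ZINB dropout scale in mean-count units (> 0); ``variance`` the Gaussian
    noise variance on the transformed scale; ``transform`` how raw counts are
    mapped to the Gaussian scale.
    """

    family: str
    alpha: float = 1.0
    kappa: float = 1.0
    variance: float = 1.0
    transform: str = "log1p"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown likelihood family {self.family!r}")
        if self.family in ("negative_binomial", "zinb") and self.alpha < 0:
            raise ValueError("dispersion alpha must be non-negative")
        if self.family == "zinb" and not self.kappa > 0:
            raise ValueError("dropout scale kappa must be positive")
        if self.family == "gaussian":
            if not self.variance > 0:
                raise ValueError("noise variance must be positive")
            if self.transform not in TRANSFORMS:
                raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def is_count(self) -> bool:
        return self.family != "gaussian"

    @property
    def free_names(self) -> tuple[str, ...]:
        if self.family == "negative_binomial":
            return ("alpha",)
        if self.family == "zinb":
            return ("alpha", "kappa")
        if self.family == "gaussian":
            return ("variance",)
        return ()

    def with_params(self, **kw: float) -> "LikelihoodSpec":
        return replace(self, **kw)


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(y, np.round(y)):
        raise ValueError("counts must be integers")
    return np.asarray(y, dtype=float)


def nb_log_pmf(y, mu, r):
    """Log pmf of NB(y; mu, r) with mean mu and r = 1/alpha failures.

    log NB = lgamma(y+r) - lgamma(y+1) - lgamma(r)
             + r*(log r - log(r+mu)) + y*(log mu - log(r+mu)).
    """
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(mu <= 0) or np.any(r <= 0):
        raise ValueError("mu and r must be positive")
    log_rm = np.log(r + mu)
    return (
        gammaln(y + r)
        - gammaln(y + 1.0)
        - gammaln(r)
        + r * (np.log(r) - log_rm)
        + y * (np.log(mu) - log_rm)
    )


def poisson_log_pmf(y, mu):
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    return y * np.log(mu) - mu - gammaln(y + 1.0)


def zinb_log_pmf(y, mu, r, kappa):
    """Log pmf of the zero-inflated NB with dropout psi = kappa/(kappa+mu).

    P(y) = psi * 1[y=0] + (1 - psi) * NB(y; mu, r).
    """
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(np.asarray(kappa) <= 0):
        raise ValueError("kappa must be positive")
    y, mu, r, kappa = np.broadcast_arrays(y, mu, np.asarray(r, float), np.asarray(kappa, float))
    log_psi = np.log(kappa) - np.log(kappa + mu)
    log_1mpsi = np.log(mu) - np.log(kappa + mu)
    lp_nb = nb_log_pmf(y, mu, r)
    out = log_1mpsi + lp_nb
    zero = y == 0
    if np.any(zero):
        stacked = np.stack([log_psi, log_1mpsi + lp_nb])
        out = np.where(zero, logsumexp(stacked, axis=0), out)
    return out


def transform_counts(y, transform: str = "log1p"):
    """Variance-stabilizing maps for the Gaussian observation model.

    ``log1p``: log(y + 1); ``anscombe``: 2*sqrt(y + 3/8) (the Poisson-family
    Anscombe transform).  Both are strictly increasing on y >= 0.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if transform == "log1p":
        return np.log1p(y)
    if transform == "anscombe":
        return 2.0 * np.sqrt(y + 0.375)
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# log-density and derivative w.r.t. the latent f, used by the variational
# machinery.  For count families f is log-mean (mu = s exp(f)); for the
# Gaussian f is the mean on the transformed scale and s is ignored.
# ---------------------------------------------------------------------------

_CLIP_F = 45.0  # exp(45) ~ 3.5e19; keeps mu finite in float64


def _mu_of_f(f, s):
    return s * np.exp(np.clip(f, -_CLIP_F, _CLIP_F))


def log_density(spec: LikelihoodSpec, y, f, s=1.0):
    """log p(y | f) for latent value(s) f; broadcasts over f."""
    if spec.family == "gaussian":
        return -0.5 * np.log(2.0 * np.pi * spec.variance) - 0.5 * (y - f) ** 2 / spec.variance
    mu = _mu_of_f(f, s)
    if spec.family == "poisson":
        return poisson_log_pmf(y, mu)
    r = 1.0 / max(spec.alpha, 1e-8)
    if spec.family == "negative_binomial":
        return nb_log_pmf(y, mu, r)
    return zinb_log_pmf(y, mu, r, spec.kappa)


def log_density_df(spec: LikelihoodSpec, y, f, s=1.0):
    """d/df log p(y | f), needed for gradients of quadrature expectations."""
    if spec.family == "gaussian":
        return (y - f) / spec.variance
    mu = _mu_of_f(f, s)
    if spec.family == "poisson":
        return y - mu
    r = 1.0 / max(spec.alpha, 1e-8)
    nb_d1 = y - (y + r) * mu / (r + mu)
    if spec.family == "negative_binomial":
        return nb_d1
    kappa = spec.kappa
    psi = kappa / (kappa + mu)
    u = 1.0 - psi
    out = psi + nb_d1  # y > 0 branch: d/df[log(1-psi)] = psi
    y_arr = np.broadcast_to(y, out.shape)
    zero = y_arr == 0
    if np.any(zero):
        q0 = np.exp(r * (np.log(r) - np.log(r + mu)))
        p0 = psi + u * q0
        d1_zero = u * (-psi * (1.0 - q0) - q0 * r * mu / (r + mu)) / p0
        out = np.where(zero, d1_zero, out)
    return out


def gauss_hermite(order: int = 20):
    """Nodes/weights for E_{N(m,v)}[g(f)] ≈ sum_k w_k g(m + sqrt(2v) t_k)."""
    if order < 3:
        raise ValueError("quadrature order must be at least 3")
    t, w = np.polynomial.hermite.hermgauss(order)
    return t, w / np.sqrt(np.pi)


def variational_expectation(spec: LikelihoodSpec, y, q_mean, q_var, order: int = 20):
    """E_{N(f | q_mean, q_var)}[log p(y | f)] by Gauss-Hermite quadrature.

    Vectorized over samples; ``q_var = 0`` returns the log density at
    f = q_mean exactly.  The Gaussian family has the closed form
    -0.5*log(2 pi s2) - (var + (y - m)^2) / (2 s2) and skips quadrature.
    """
    y = np.asarray(y, dtype=float)
    m = np.asarray(q_mean, dtype=float)
    v = np.asarray(q_var, dtype=float)
    if np.any(v < 0):
        raise ValueError("q_var must be non-negative")
    if spec.family == "gaussian":
        s2 = spec.variance
        return -0.5 * np.log(2.0 * np.pi * s2) - 0.5 * (v + (y - m) ** 2) / s2
    t, w = gauss_hermite(order)
    f = m[..., None] + np.sqrt(2.0 * np.clip(v, 0.0, None))[..., None] * t
    lp = log_density(spec, y[..., None], f)
    return lp @ w
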