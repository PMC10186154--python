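"""Covariance functions on 1-D and 2-D inputs.

Four stationary-or-simpler families are supported:

* ``rbf`` — squared exponential, k(x, x') = sf2 * exp(-||x - x'||^2 / (2 l^2)),
  isotropic in any input dimension (a single shared lengthscale).
* ``linear`` — k(x, x') = sf2 * <x, x'>.
* ``periodic`` — MacKay's periodic kernel,
  k(x, x') = sf2 * exp(-2 sin^2(pi |x - x'| / p) / l^2), 1-D inputs.
* ``constant`` — k(x, x') = sf2 everywhere.  This is the covariance of a
  random constant function and serves as the null model in the
  dynamic-vs-constant likelihood-ratio tests: an RBF kernel converges to it
  in the infinite-lengthscale limit, which is what makes those tests nested.

All evaluation goes through :func:`eval_kernel`, which returns a dense
covariance matrix; :func:`safe_cholesky` adds an escalating diagonal jitter
before factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

FAMILIES = ("rbf", "linear", "periodic", "constant")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus hyper-parameters.

    Parameters
    ----------
    family
        One of ``rbf``, ``linear``, ``periodic``, ``constant``.
    lengthscale
        l > 0, in input units (rbf, periodic).
    variance
        Amplitude sf2 >= 0, the marginal variance of the function (all).
    period
        p > 0, in input units (periodic only).
    """

    family: str
    lengthscale: float = 1.0
    variance: float = 1.0
    period: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family in ("rbf", "periodic") and not self.lengthscale > 0:
            raise ValueError("lengthscale must be positive")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.family == "periodic" and not self.period > 0:
            raise ValueError("period must be positive")

    @property
    def free_names(self) -> tuple[str, ...]:
        """Names of the hyper-parameters optimized for this family."""
        if self.family == "rbf":
            return ("lengthscale", "variance")
        if self.family == "periodic":
            return ("lengthscale", "variance", "period")
        return ("variance",)

    def with_params(self, **kw: float) -> "KernelSpec":
        return replace(self, **kw)


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("coordinates must be a vector or an (n, d) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("coordinates must be finite")
    return X


def eval_kernel(spec: KernelSpec, X, X2=None) -> np.ndarray:
    """Evaluate the covariance matrix k(X, X2) of shape ``(|X|, |X2|)``.

    Inputs may be 1-D vectors or (n, d) arrays; both arguments must have the
    same dimensionality.  The rbf family uses the Euclidean distance in any
    dimension; the periodic family is defined on 1-D inputs only.
    """
    X = _as_2d(X)
    X2 = X if X2 is None else _as_2d(X2)
    if X.shape[1] != X2.shape[1]:
        raise ValueError(
            f"dimension mismatch: inputs have {X.shape[1]} and {X2.shape[1]} columns"
        )
    sf2 = spec.variance
    if spec.family == "constant":
        return np.full((X.shape[0], X2.shape[0]), sf2)
    if spec.family == "linear":
        return sf2 * (X @ X2.T)
    if spec.family == "rbf":
        d2 = cdist(X, X2, "sqeuclidean")
        return sf2 * np.exp(-0.5 * d2 / spec.lengthscale**2)
    # periodic
    if X.shape[1] != 1:
        raise ValueError("periodic kernel is defined on 1-D inputs")
    d = np.abs(X - X2.T)
    s = np.sin(np.pi * d / spec.period)
    return sf2 * np.exp(-2.0 * s**2 / spec.lengthscale**2)


def kernel_grads(spec: KernelSpec, X) -> list[np.ndarray]:
    """Gradients of k(X, X) with respect to log hyper-parameters.

    Returned in the order of :attr:`KernelSpec.free_names`; used by the
    exact-marginal-likelihood optimizer for Gaussian observation models.
    """
    X = _as_2d(X)
    K = eval_kernel(spec, X)
    if spec.family == "constant" or spec.family == "linear":
        return [K.copy()]
    if spec.family == "rbf":
        d2 = cdist(X, X, "sqeuclidean")
        return [K * d2 / spec.lengthscale**2, K.copy()]
    # periodic: k = sf2 exp(-2 s^2 / l^2), s = sin(pi d / p)
    d = np.abs(X - X.T)
    arg = np.pi * d / spec.period
    s = np.sin(arg)
    dK_dlogl = K * (4.0 * s**2 / spec.lengthscale**2)
    # d/dlog p: ds/dlogp = cos(arg) * (-arg)
    dK_dlogp = K * (-4.0 * s / spec.lengthscale**2) * np.cos(arg) * (-arg)
    return [dK_dlogl, K.copy(), dK_dlogp]


def safe_cholesky(K: np.ndarray, rel_jitter: float = 1e-6, max_jitter: float = 1e-2):
    """Lower Cholesky factor of K plus an escalating relative jitter.

    The jitter starts at ``rel_jitter`` times the mean diagonal and is
    escalated tenfold up to ``max_jitter`` (relative) on failure.

    Returns
    -------
    (L, jitter_used) or raises :class:`numpy.linalg.LinAlgError` once the
    ceiling is exceeded.
    """
    n = K.shape[0]
    scale = float(np.mean(np.diag(K)))
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0
    jit = rel_jitter
    while True:
        try:
            L = np.linalg.cholesky(K + jit * scale * np.eye(n))
            return L, jit * scale
        except np.linalg.LinAlgError:
            jit *= 10.0
            if jit > max_jitter * 10.0:
                raise
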