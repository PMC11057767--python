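"""Linear-model machinery in original and canonical coordinates.

The model is ``y = X beta + e`` with zero intercept, ``E[e] = 0`` and
``Var[e] = sigma^2 I``.  Writing ``X'X = U diag(lambda) U'`` with
orthogonal ``U``, the rotated design ``Z = X U`` has orthogonal columns
(``Z'Z = diag(lambda)``), and ``alpha = U' beta`` are the canonical
coefficients.  Ridge estimation with biasing parameter(s) ``k`` is then
coordinate-wise::

    alpha_hat(k)_w = (Z'y)_w / (lambda_w + k_w)

All shrinkage-rule and bootstrap machinery in the rest of the package
operates in this canonical frame; :func:`to_original_space` rotates a fit
back to the natural predictor scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import (
    DegreesOfFreedomError,
    InvalidDataError,
    SingularityError,
)

__all__ = [
    "RegressionData",
    "CanonicalDecomposition",
    "CoefficientEstimate",
    "NoiseEstimate",
    "decompose",
    "decompose_matrix",
    "ols_alpha",
    "ridge_alpha",
    "sigma2_hat",
    "theoretical_mse",
    "to_original_space",
]

#: eigenvalues below RCOND * lambda_max are treated as zero for OLS
RCOND = 1e-10


@dataclass(frozen=True)
class RegressionData:
    """An (n x p) design matrix paired with a length-n response.

    No intercept column: the model assumes a zero intercept, so real-data
    workflows must center ``y`` and ``X`` before constructing this object
    (see :mod:`bqridge.data`).
    """

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        if X.ndim != 2:
            raise InvalidDataError("X must be a 2-d array")
        n, p = X.shape
        if p < 1 or n <= p:
            raise InvalidDataError(
                f"need n > p >= 1, got n={n}, p={p} (residual variance uses n-p df)"
            )
        if y.shape[0] != n:
            raise InvalidDataError(f"len(y)={y.shape[0]} does not match n={n}")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise InvalidDataError("non-finite entries in X or y")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class CanonicalDecomposition:
    """Eigenstructure of X'X and the rotated design Z = XU.

    ``lambdas`` are sorted descending; each column of ``U`` has its
    largest-magnitude entry positive so the decomposition is deterministic.
    """

    U: np.ndarray
    lambdas: np.ndarray
    Z: np.ndarray

    @property
    def p(self) -> int:
        return self.lambdas.shape[0]

    @property
    def rank_tolerance(self) -> float:
        return RCOND * max(float(self.lambdas[0]), np.finfo(float).tiny)


@dataclass(frozen=True)
class CoefficientEstimate:
    """A coefficient vector plus the ridge parameter(s) that produced it."""

    alpha: np.ndarray
    k_used: np.ndarray
    space: str = "canonical"  # {"canonical", "original"}

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float).ravel()
        k = np.asarray(self.k_used, dtype=float).ravel()
        if k.size == 1 and alpha.size > 1:
            k = np.full(alpha.size, float(k[0]))
        if k.size != alpha.size:
            raise InvalidDataError("k_used length does not match alpha length")
        if (k < 0).any():
            raise InvalidDataError("ridge parameters must be non-negative")
        if self.space not in ("canonical", "original"):
            raise InvalidDataError(f"unknown coefficient space {self.space!r}")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "k_used", k)


@dataclass(frozen=True)
class NoiseEstimate:
    """Residual mean square sigma2 = RSS / (n - p)."""

    sigma2: float
    df: int = field(default=0)


def decompose_matrix(X: np.ndarray) -> CanonicalDecomposition:
    """Eigendecomposition of X'X with the rotated design Z = XU.

    Eigenvalues are returned descending.  The sign of each eigenvector is
    fixed so that its largest-magnitude entry is positive, which makes the
    decomposition (and everything derived from it) reproducible across
    platforms and LAPACK builds.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise InvalidDataError("non-finite entries in X")
    XtX = X.T @ X
    lam, U = np.linalg.eigh(XtX)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    U = U[:, order]
    # sign convention: largest-|entry| of each column positive
    pivot = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[pivot, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    return CanonicalDecomposition(U=U, lambdas=lam, Z=X @ U)


def decompose(data: RegressionData) -> CanonicalDecomposition:
    """Canonical decomposition of a dataset's design matrix."""
    return decompose_matrix(data.X)


def ols_alpha(decomp: CanonicalDecomposition, y: np.ndarray) -> CoefficientEstimate:
    """Canonical OLS: alpha_hat = Lambda^{-1} Z'y.

    Raises
    ------
    SingularityError
        If any eigenvalue is below ``RCOND * lambda_max`` — OLS is not
        defined on a (numerically) rank-deficient design.
    """
    y = np.asarray(y, dtype=float).ravel()
    tol = decomp.rank_tolerance
    bad = np.nonzero(decomp.lambdas <= tol)[0]
    if bad.size:
        raise SingularityError(
            f"eigenvalue(s) at index {bad.tolist()} are numerically zero "
            f"(<= {tol:.3e}); OLS undefined"
        )
    alpha = (decomp.Z.T @ y) / decomp.lambdas
    return CoefficientEstimate(alpha=alpha, k_used=np.zeros(decomp.p))


def ridge_alpha(
    decomp: CanonicalDecomposition, y: np.ndarray, k: float | np.ndarray
) -> CoefficientEstimate:
    """Canonical ridge fit alpha_hat(k)_w = (Z'y)_w / (lambda_w + k_w).

    ``k`` may be a scalar (applied to every coordinate, the common case) or
    a length-p vector of per-coordinate biasing parameters.
    """
    y = np.asarray(y, dtype=float).ravel()
    k_arr = np.asarray(k, dtype=float).ravel()
    if (k_arr < 0).any():
        raise InvalidDataError("ridge parameter k must be non-negative")
    if k_arr.size == 1:
        k_arr = np.full(decomp.p, float(k_arr[0]))
    elif k_arr.size != decomp.p:
        raise InvalidDataError(f"k has length {k_arr.size}, expected {decomp.p}")
    denom = decomp.lambdas + k_arr
    if (denom <= 0).any():
        raise SingularityError("lambda + k is zero in some coordinate")
    alpha = (decomp.Z.T @ y) / denom
    return CoefficientEstimate(alpha=alpha, k_used=k_arr)


def sigma2_hat(
    data: RegressionData,
    alpha_ols: CoefficientEstimate,
    decomp: CanonicalDecomposition,
) -> NoiseEstimate:
    """Unbiased residual mean square sigma2_hat = sum(e_j^2) / (n - p)."""
    n, p = data.n, data.p
    if n <= p:
        raise DegreesOfFreedomError(f"n={n} <= p={p}: no residual degrees of freedom")
    resid = data.y - decomp.Z @ alpha_ols.alpha
    return NoiseEstimate(sigma2=float(resid @ resid) / (n - p), df=n - p)


def theoretical_mse(
    lambdas: np.ndarray,
    k: float | np.ndarray,
    alpha_true: np.ndarray,
    sigma2: float,
) -> float:
    """Exact MSE of the canonical ridge estimator.

    ``sigma^2 sum_w lambda_w/(lambda_w+k_w)^2  +  sum_w k_w^2 alpha_w^2/(lambda_w+k_w)^2``
    — variance plus squared bias.  At ``k = 0`` this reduces to
    ``sigma^2 sum_w 1/lambda_w``, the OLS value.
    """
    lam = np.asarray(lambdas, dtype=float).ravel()
    alpha = np.asarray(alpha_true, dtype=float).ravel()
    k_arr = np.asarray(k, dtype=float).ravel()
    if k_arr.size == 1:
        k_arr = np.full(lam.size, float(k_arr[0]))
    if not (lam.size == alpha.size == k_arr.size):
        raise InvalidDataError(
            f"dimension mismatch: lambdas {lam.size}, k {k_arr.size}, alpha {alpha.size}"
        )
    if (lam <= 0).any():
        raise SingularityError("all eigenvalues must be positive")
    if (k_arr < 0).any():
        raise InvalidDataError("ridge parameter k must be non-negative")
    denom = (lam + k_arr) ** 2
    variance = sigma2 * float(np.sum(lam / denom))
    bias2 = float(np.sum(k_arr**2 * alpha**2 / denom))
    return variance + bias2


def to_original_space(
    est: CoefficientEstimate, decomp: CanonicalDecomposition
) -> CoefficientEstimate:
    """Rotate canonical coefficients back: beta_hat = U alpha_hat."""
    if est.space != "canonical":
        raise InvalidDataError("estimate is already in original space")
    if est.alpha.size != decomp.p:
        raise InvalidDataError("coefficient length does not match decomposition")
    return CoefficientEstimate(
        alpha=decomp.U @ est.alpha, k_used=est.k_used, space="original"
    )
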