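"""Classical ridge biasing-parameter rules.

All rules are functions of the canonical OLS coefficients ``alpha_hat``,
the residual mean square ``sigma2_hat`` and (for HSL) the eigenvalues of
X'X.  Writing ``k_w = sigma2_hat / alpha_hat_w^2`` for the per-coordinate
optimum, the five scalar rules are:

========  =======================================================
HK        ``sigma2 / max_w alpha_w^2``       (min of the k_w)
HKB       ``p sigma2 / sum_w alpha_w^2``     (harmonic mean)
HSL       ``sigma2 sum (lam_w alpha_w)^2 / (sum lam_w alpha_w^2)^2``
AM        ``(1/p) sum sigma2 / alpha_w^2``   (arithmetic mean)
GM        ``sigma2 / (prod alpha_w^2)^{1/p}``(geometric mean)
========  =======================================================

whence the ordering HK <= HKB <= GM <= AM on every valid input (the
min / harmonic / geometric / arithmetic mean chain).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np

from ._errors import DegenerateCoefficientError
from .canonical import (
    CanonicalDecomposition,
    NoiseEstimate,
    RegressionData,
    decompose,
    ols_alpha,
    sigma2_hat,
)

__all__ = [
    "KEstimate",
    "k_per_coordinate",
    "k_hk",
    "k_hkb",
    "k_hsl",
    "k_am",
    "k_gm",
    "estimate_all",
    "ESTIMATOR_NAMES",
    "KRule",
]

#: coefficients smaller than this (in magnitude) are treated as zero
ALPHA_TOL = 1e-12

ESTIMATOR_NAMES = ("HK", "HKB", "HSL", "AM", "GM")

#: signature shared by every scalar rule: (alpha, lambdas, sigma2) -> k
KRule = Callable[[np.ndarray, np.ndarray, float], float]


@dataclass(frozen=True)
class KEstimate:
    """A named, non-negative scalar ridge parameter."""

    name: str
    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise DegenerateCoefficientError(f"{self.name}: negative k {self.k}")


def _as_alpha(alpha: np.ndarray) -> np.ndarray:
    return np.asarray(alpha, dtype=float).ravel()


def k_per_coordinate(alpha: np.ndarray, sigma2: float) -> np.ndarray:
    """Per-coordinate rule k_w = sigma2 / alpha_w^2 (vector valued)."""
    a = _as_alpha(alpha)
    if (np.abs(a) < ALPHA_TOL).any():
        raise DegenerateCoefficientError(
            "some alpha_w is numerically zero; per-coordinate k undefined"
        )
    return sigma2 / a**2


def k_hk(alpha: np.ndarray, sigma2: float) -> KEstimate:
    """Hoerl–Kennard: sigma2 over the largest squared coefficient.

    Equals the minimum of the per-coordinate rule, hence the most
    conservative (smallest) of the five scalar estimators.
    """
    a = _as_alpha(alpha)
    amax2 = float(np.max(a**2))
    if amax2 < ALPHA_TOL**2:
        raise DegenerateCoefficientError("all alpha_w are numerically zero")
    return KEstimate("HK", sigma2 / amax2)


def k_hkb(alpha: np.ndarray, sigma2: float) -> KEstimate:
    """Hoerl–Kennard–Baldwin: p * sigma2 / sum(alpha_w^2), the harmonic mean."""
    a = _as_alpha(alpha)
    ss = float(a @ a)
    if ss < ALPHA_TOL**2:
        raise DegenerateCoefficientError("sum of alpha_w^2 is numerically zero")
    return KEstimate("HKB", a.size * sigma2 / ss)


def k_hsl(alpha: np.ndarray, lambdas: np.ndarray, sigma2: float) -> KEstimate:
    """Hocking–Speed–Lynn: eigenvalue-weighted rule.

    k = sigma2 * sum (lambda_w alpha_w)^2 / (sum lambda_w alpha_w^2)^2;
    for p = 1 it reduces to sigma2 / alpha_1^2 independent of lambda.
    """
    a = _as_alpha(alpha)
    lam = np.asarray(lambdas, dtype=float).ravel()
    denom = float(np.sum(lam * a**2)) ** 2
    if denom < ALPHA_TOL**2:
        raise DegenerateCoefficientError("sum of lambda_w alpha_w^2 is numerically zero")
    return KEstimate("HSL", sigma2 * float(np.sum((lam * a) ** 2)) / denom)


def k_am(alpha: np.ndarray, sigma2: float) -> KEstimate:
    """Arithmetic mean of the per-coordinate rule."""
    return KEstimate("AM", float(np.mean(k_per_coordinate(alpha, sigma2))))


def k_gm(alpha: np.ndarray, sigma2: float) -> KEstimate:
    """Geometric mean of the per-coordinate rule, computed in log space.

    k = sigma2 / (prod alpha_w^2)^{1/p}; the product is evaluated as an
    exponential of a mean of logs so large p cannot under/overflow.
    """
    a = _as_alpha(alpha)
    if (np.abs(a) < ALPHA_TOL).any():
        raise DegenerateCoefficientError("some alpha_w is numerically zero")
    log_gm_alpha2 = 2.0 * float(np.mean(np.log(np.abs(a))))
    return KEstimate("GM", sigma2 * np.exp(-log_gm_alpha2))


def all_scalar_rules(
    alpha: np.ndarray, lambdas: np.ndarray, sigma2: float
) -> Dict[str, float]:
    """Evaluate the five scalar rules on prepared canonical quantities."""
    return {
        "HK": k_hk(alpha, sigma2).k,
        "HKB": k_hkb(alpha, sigma2).k,
        "HSL": k_hsl(alpha, lambdas, sigma2).k,
        "AM": k_am(alpha, sigma2).k,
        "GM": k_gm(alpha, sigma2).k,
    }


#: named scalar rules with the uniform (alpha, lambdas, sigma2) signature
RULES: Dict[str, KRule] = {
    "HK": lambda a, lam, s2: k_hk(a, s2).k,
    "HKB": lambda a, lam, s2: k_hkb(a, s2).k,
    "HSL": lambda a, lam, s2: k_hsl(a, lam, s2).k,
    "AM": lambda a, lam, s2: k_am(a, s2).k,
    "GM": lambda a, lam, s2: k_gm(a, s2).k,
}


def estimate_all(data: RegressionData) -> Dict[str, KEstimate]:
    """Decompose, fit OLS, estimate sigma2, and evaluate all five rules."""
    decomp: CanonicalDecomposition = decompose(data)
    alpha = ols_alpha(decomp, data.y)
    noise: NoiseEstimate = sigma2_hat(data, alpha, decomp)
    out: Dict[str, KEstimate] = {}
    for name in ESTIMATOR_NAMES:
        try:
            out[name] = KEstimate(name, RULES[name](alpha.alpha, decomp.lambdas, noise.sigma2))
        except DegenerateCoefficientError as err:
            raise DegenerateCoefficientError(f"{name}: {err}") from err
    return out
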