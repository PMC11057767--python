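"""Collinearity diagnostics: condition number and variance inflation factors."""

from __future__ import annotations

import numpy as np

from ._errors import InvalidDataError, SingularityError
from .canonical import RCOND, decompose_matrix

__all__ = ["condition_number", "vif"]


def condition_number(X: np.ndarray) -> float:
    """Ratio lambda_max / lambda_min of the eigenvalues of X'X.

    Values in the thousands and beyond signal severe ill-conditioning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise InvalidDataError("condition number needs a matrix with p >= 2 columns")
    lam = decompose_matrix(X).lambdas
    if lam[-1] <= RCOND * max(lam[0], np.finfo(float).tiny):
        raise SingularityError("X'X is numerically singular; condition number infinite")
    return float(lam[0] / lam[-1])


def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each predictor.

    VIF_w = 1 / (1 - R^2_w) where R^2_w comes from regressing column w on
    all remaining columns plus an intercept.  Perfectly collinear columns
    yield ``inf`` rather than an error, so the caller can still report
    which predictors are involved.  VIF > 10 conventionally flags severe
    collinearity.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise InvalidDataError("VIF needs a matrix with p >= 2 columns")
    n, p = X.shape
    out = np.empty(p)
    ones = np.ones((n, 1))
    for w in range(p):
        target = X[:, w]
        others = np.hstack([ones, np.delete(X, w, axis=1)])
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = float(np.sum((target - target.mean()) ** 2))
        if tss <= 0:
            raise InvalidDataError(f"column {w} is constant; VIF undefined")
        r2 = 1.0 - float(resid @ resid) / tss
        out[w] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out
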