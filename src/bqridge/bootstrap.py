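"""Pairs-bootstrap of the ridge parameter and its quantile estimator.

The bootstrap-quantile ridge (BQR) idea: instead of using a ridge-rule
estimate ``k_hat`` directly, resample whole ``(x_j, y_j)`` cases with
replacement B times, recompute the rule on each resample to get the
bootstrap distribution ``k*(1) <= ... <= k*(B)``, and use an upper
empirical quantile ``k*_gamma`` of that distribution as the biasing
parameter.  Because every classical rule tends to under-shrink under
severe collinearity, an upper quantile of its sampling distribution
typically lands closer to the MSE-optimal amount of shrinkage.

The quantile level gamma is chosen by one of three explicit strategies
(the defining inequality ``MSE(k*_gamma) < MSE(k_hat)`` involves the true
coefficients, so it cannot be applied verbatim on data):

``fixed``
    a single user-supplied gamma;
``min_estimated_mse``
    minimise the exact ridge-MSE formula with plug-in OLS quantities
    (``alpha_hat, sigma2_hat, lambda``) over a gamma grid — the
    data-driven default for real datasets;
``oracle``
    minimise the exact formula with the *true* ``(alpha, sigma2)`` —
    available only in simulations, where it measures the headroom of the
    method free of the gamma-selection question.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple, Union

import numpy as np

from ._errors import ConfigError, InvalidDataError, UnstableBootstrapError
from .canonical import (
    RCOND,
    CanonicalDecomposition,
    CoefficientEstimate,
    RegressionData,
    decompose,
    ols_alpha,
    ridge_alpha,
    sigma2_hat,
    theoretical_mse,
)
from .kestimators import ALPHA_TOL, ESTIMATOR_NAMES, RULES, KRule

__all__ = [
    "BootstrapSettings",
    "BootstrapKDistribution",
    "BqrSelection",
    "DEFAULT_GAMMA_GRID",
    "resample_pairs",
    "bootstrap_k_distribution",
    "bootstrap_all_k_distributions",
    "empirical_quantile",
    "select_gamma",
    "bqr_fit",
]

#: default quantile-level grid; upper levels, as those are where BQR helps
DEFAULT_GAMMA_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass(frozen=True)
class BootstrapSettings:
    """Bootstrap sample count, RNG seed and gamma-grid configuration."""

    B: int = 200
    seed: int = 0
    gamma_grid: Tuple[float, ...] = DEFAULT_GAMMA_GRID
    max_redraws: Optional[int] = None  # default 10*B

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ConfigError(f"B must be >= 2, got {self.B}")
        grid = tuple(float(g) for g in self.gamma_grid)
        if not grid:
            raise ConfigError("gamma_grid must be non-empty")
        if any(not (0.0 < g < 1.0) for g in grid):
            raise ConfigError("gamma levels must lie strictly in (0, 1)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigError("gamma_grid must be strictly increasing")
        object.__setattr__(self, "gamma_grid", grid)
        if self.max_redraws is None:
            object.__setattr__(self, "max_redraws", 10 * self.B)
        elif self.max_redraws < 1:
            raise ConfigError("max_redraws must be positive")


@dataclass(frozen=True)
class BootstrapKDistribution:
    """Sorted bootstrap replicates of one ridge-parameter rule."""

    estimator_name: str
    values: np.ndarray  # ascending, length B
    n_redraws: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(v).all() or (v < 0).any():
            raise InvalidDataError("bootstrap k replicates must be finite and >= 0")
        if (np.diff(v) < 0).any():
            raise InvalidDataError("bootstrap k replicates must be sorted ascending")
        object.__setattr__(self, "values", v)

    @property
    def B(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class BqrSelection:
    """The chosen quantile level and the resulting biasing parameter."""

    gamma: float
    k_star: float
    criterion_value: float
    strategy: str


def resample_pairs(data: RegressionData, rng: np.random.Generator) -> RegressionData:
    """Draw n whole (x_j, y_j) cases with replacement (pairs bootstrap)."""
    idx = rng.integers(0, data.n, size=data.n)
    return RegressionData(X=data.X[idx], y=data.y[idx])


def _resolve_rule(rule: Union[str, KRule]) -> Tuple[str, KRule]:
    if isinstance(rule, str):
        if rule not in RULES:
            raise ConfigError(f"unknown rule {rule!r}; known: {ESTIMATOR_NAMES}")
        return rule, RULES[rule]
    return getattr(rule, "__name__", "custom"), rule


def batched_k_replicates(
    X: np.ndarray,
    y: np.ndarray,
    B: int,
    rng: np.random.Generator,
    max_redraws: int,
) -> Tuple[np.ndarray, int]:
    """B pairs-bootstrap replicates of all five scalar rules at once.

    Returns an (B, 5) array of k values in ESTIMATOR_NAMES order (unsorted,
    i.e. in draw order) and the number of degenerate resamples that were
    discarded and redrawn.  A resample is degenerate when its X*'X* is
    numerically rank deficient or some canonical OLS coefficient is exactly
    zero (which would break the mean-based rules); the same B resamples are
    shared by all five rules so between-rule comparisons see identical
    bootstrap noise.

    The heavy lifting is batched: all resampled cross-product matrices are
    eigendecomposed with one stacked LAPACK call, which is what makes
    Monte Carlo sweeps with B=200 inner resamples tractable.
    """
    n, p = X.shape
    out = np.empty((B, 5))
    filled = 0
    redraws = 0
    while filled < B:
        if redraws > max_redraws:
            raise UnstableBootstrapError(
                f"{redraws} degenerate resamples exceeded budget {max_redraws} "
                f"({redraws / (redraws + filled + 1e-12):.1%} failure fraction)"
            )
        b = B - filled
        idx = rng.integers(0, n, size=(b, n))
        Xb = X[idx]  # (b, n, p)
        yb = y[idx]  # (b, n)
        G = Xb.transpose(0, 2, 1) @ Xb
        lam, U = np.linalg.eigh(G)  # ascending per batch element
        lam = lam[:, ::-1]
        U = U[:, :, ::-1]
        Xty = np.einsum("bnp,bn->bp", Xb, yb)
        Zty = np.einsum("bpq,bp->bq", U, Xty)  # U' X'y
        ok = lam[:, -1] > RCOND * np.maximum(lam[:, 0], np.finfo(float).tiny)
        lam_safe = np.where(lam > 0, lam, 1.0)
        alpha = Zty / lam_safe
        rss = np.clip(np.einsum("bn,bn->b", yb, yb) - np.einsum("bp,bp->b", alpha, Zty), 0.0, None)
        sigma2 = rss / (n - p)
        alpha2 = alpha**2
        ok &= alpha2.min(axis=1) > ALPHA_TOL**2
        if not ok.any():
            redraws += b
            continue
        lam_ok = lam[ok]
        a2 = alpha2[ok]
        s2 = sigma2[ok]
        m = int(ok.sum())
        block = np.empty((m, 5))
        block[:, 0] = s2 / a2.max(axis=1)  # HK
        block[:, 1] = p * s2 / a2.sum(axis=1)  # HKB
        block[:, 2] = s2 * (lam_ok**2 * a2).sum(axis=1) / (lam_ok * a2).sum(axis=1) ** 2  # HSL
        block[:, 3] = s2 * (1.0 / a2).mean(axis=1)  # AM
        block[:, 4] = s2 * np.exp(-np.mean(np.log(a2), axis=1))  # GM
        out[filled : filled + m] = block
        filled += m
        redraws += b - m
    return out, redraws


def bootstrap_k_distribution(
    data: RegressionData,
    rule: Union[str, KRule],
    settings: BootstrapSettings,
    rng: Optional[np.random.Generator] = None,
) -> BootstrapKDistribution:
    """Bootstrap distribution of one ridge-parameter rule.

    ``rule`` is either one of the built-in names ("HK", "HKB", "HSL",
    "AM", "GM") — served by the fast batched path — or any callable
    ``(alpha, lambdas, sigma2) -> k`` evaluated resample by resample.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    name, fn = _resolve_rule(rule)
    if name in ESTIMATOR_NAMES:
        ks, redraws = batched_k_replicates(
            data.X, data.y, settings.B, rng, settings.max_redraws
        )
        col = ESTIMATOR_NAMES.index(name)
        return BootstrapKDistribution(name, np.sort(ks[:, col]), redraws)
    values = np.empty(settings.B)
    filled = 0
    redraws = 0
    while filled < settings.B:
        if redraws > settings.max_redraws:
            raise UnstableBootstrapError(
                f"rule {name}: {redraws} degenerate resamples exceeded budget"
            )
        sample = resample_pairs(data, rng)
        try:
            dec = decompose(sample)
            a = ols_alpha(dec, sample.y)
            s2 = sigma2_hat(sample, a, dec).sigma2
            k = float(fn(a.alpha, dec.lambdas, s2))
        except Exception:
            redraws += 1
            continue
        if not (np.isfinite(k) and k >= 0):
            redraws += 1
            continue
        values[filled] = k
        filled += 1
    return BootstrapKDistribution(name, np.sort(values), redraws)


def bootstrap_all_k_distributions(
    data: RegressionData,
    settings: BootstrapSettings,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, BootstrapKDistribution]:
    """All five built-in rules on one shared set of B resamples."""
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    ks, redraws = batched_k_replicates(data.X, data.y, settings.B, rng, settings.max_redraws)
    return {
        name: BootstrapKDistribution(name, np.sort(ks[:, j]), redraws)
        for j, name in enumerate(ESTIMATOR_NAMES)
    }


def empirical_quantile(dist: BootstrapKDistribution, gamma: float) -> float:
    """Order-statistic quantile k*(ceil(gamma * B)).

    This inverse-empirical-CDF definition satisfies
    ``P(k* < q) <= gamma <= P(k* <= q)`` on the empirical distribution and
    involves no interpolation, so it is exactly reproducible.
    """
    if not (0.0 < gamma < 1.0):
        raise InvalidDataError(f"gamma must be in (0, 1), got {gamma}")
    i = math.ceil(gamma * dist.B)
    return float(dist.values[max(i, 1) - 1])


def _grid_quantiles(dist: BootstrapKDistribution, grid: Tuple[float, ...]) -> np.ndarray:
    idx = np.maximum(np.ceil(np.asarray(grid) * dist.B).astype(int), 1) - 1
    return dist.values[idx]


def select_gamma(
    data: RegressionData,
    dist: BootstrapKDistribution,
    settings: BootstrapSettings,
    strategy: str = "min_estimated_mse",
    truth: Optional[Tuple[np.ndarray, float]] = None,
    decomp: Optional[CanonicalDecomposition] = None,
) -> BqrSelection:
    """Choose the quantile level gamma for one bootstrap distribution.

    With ``min_estimated_mse`` (or ``oracle``) the exact ridge-MSE formula
    is evaluated at each grid level's quantile using plug-in (or true)
    ``(alpha, sigma2)`` and the realized eigenvalues, and the minimising
    level is returned; ties break toward the largest gamma, i.e. toward
    more shrinkage.
    """
    grid = settings.gamma_grid
    if strategy == "fixed":
        if len(grid) != 1:
            raise ConfigError("strategy='fixed' needs a gamma_grid with exactly one level")
        g = grid[0]
        k = empirical_quantile(dist, g)
        return BqrSelection(gamma=g, k_star=k, criterion_value=float("nan"), strategy=strategy)
    if decomp is None:
        decomp = decompose(data)
    if strategy == "min_estimated_mse":
        a_ols = ols_alpha(decomp, data.y)
        alpha_ref = a_ols.alpha
        s2_ref = sigma2_hat(data, a_ols, decomp).sigma2
    elif strategy == "oracle":
        if truth is None:
            raise ConfigError("strategy='oracle' requires truth=(alpha_true, sigma2_true)")
        alpha_ref, s2_ref = np.asarray(truth[0], dtype=float), float(truth[1])
    else:
        raise ConfigError(f"unknown strategy {strategy!r}")
    best: Optional[BqrSelection] = None
    for g, k in zip(grid, _grid_quantiles(dist, grid)):
        crit = theoretical_mse(decomp.lambdas, float(k), alpha_ref, s2_ref)
        if best is None or crit <= best.criterion_value:
            best = BqrSelection(gamma=float(g), k_star=float(k), criterion_value=crit, strategy=strategy)
    assert best is not None
    return best


def bqr_fit(
    data: RegressionData,
    rule: Union[str, KRule],
    settings: BootstrapSettings,
    strategy: str = "min_estimated_mse",
    truth: Optional[Tuple[np.ndarray, float]] = None,
) -> Tuple[BqrSelection, CoefficientEstimate]:
    """End-to-end BQR: resample, quantile, select gamma, fit ridge.

    Deterministic given ``settings.seed``; returns the selection and the
    canonical-space ridge fit at the selected ``k*_gamma``.
    """
    decomp = decompose(data)
    dist = bootstrap_k_distribution(data, rule, settings)
    sel = select_gamma(data, dist, settings, strategy=strategy, truth=truth, decomp=decomp)
    est = ridge_alpha(decomp, data.y, sel.k_star)
    return sel, est
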