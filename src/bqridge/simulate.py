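"""Monte Carlo engine for comparing baseline and BQR ridge estimators.

Data-generating process
-----------------------
Collinear Gaussian predictors built from p + 1 iid standard normals::

    x_jw = sqrt(1 - rho^2) * z_jw + rho * z_j,p+1,   w = 1..p

so every column shares the common latent factor, has unit variance, and
any two predictors correlate at ``rho^2`` — an equicorrelated one-factor
design whose conditioning worsens sharply as rho -> 1.

The true coefficient vector is the unit-norm eigenvector of the realized
X'X belonging to the largest eigenvalue (so ``beta'beta = 1`` and the
canonical truth ``alpha`` loads on a single coordinate) — the standard
convention of this simulation literature, under which the signal is the
least damaged by shrinkage and the MSE comparison isolates the variance
side of the trade-off.

Errors are ``N(0, sigma^2)``, raw ``t(2)`` (infinite variance, so no
variance standardization exists; draws are used as-is), or ``F(4,16)``
standardized to zero mean and unit variance by its analytic moments.

Each of the M replications draws a fresh design, truth and error vector,
fits OLS, the five baseline ridge rules and their five BQR versions on
B shared pairs-bootstrap resamples, and accumulates the squared
canonical-coefficient error.  Empirical MSE is the average over
replications of ``sum_w (alpha_hat_w - alpha_w)^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigError, InvalidDataError
from .bootstrap import (
    BootstrapSettings,
    batched_k_replicates,
)
from .canonical import RCOND, CanonicalDecomposition, decompose_matrix, theoretical_mse
from .kestimators import ESTIMATOR_NAMES

__all__ = [
    "ScenarioConfig",
    "TrueModel",
    "ScenarioResult",
    "ERROR_DISTRIBUTIONS",
    "generate_design",
    "generate_true_coefficients",
    "generate_errors",
    "empirical_mse",
    "p_mse",
    "run_scenario",
    "case_configs",
    "run_case_grid",
    "results_to_frame",
]

ERROR_DISTRIBUTIONS = ("normal", "t2", "f4_16")

# analytic moments of F(4, 16): mean d2/(d2-2), variance
# 2 d2^2 (d1+d2-2) / (d1 (d2-2)^2 (d2-4))
_F_MEAN = 16.0 / 14.0
_F_SD = math.sqrt(2.0 * 16.0**2 * 18.0 / (4.0 * 14.0**2 * 12.0))


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid."""

    n: int
    p: int
    rho: float
    sigma2: float
    error_dist: str = "normal"
    M: int = 1000
    bootstrap: BootstrapSettings = field(default_factory=BootstrapSettings)
    strategy: str = "oracle"
    seed: int = 0
    case: str = ""

    def __post_init__(self) -> None:
        if self.n <= self.p:
            raise ConfigError(f"need n > p, got n={self.n}, p={self.p}")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError(f"rho must be in [0, 1), got {self.rho}")
        if self.sigma2 <= 0:
            raise ConfigError(f"sigma2 must be positive, got {self.sigma2}")
        if self.M < 1:
            raise ConfigError(f"M must be >= 1, got {self.M}")
        if self.error_dist not in ERROR_DISTRIBUTIONS:
            raise ConfigError(
                f"unknown error_dist {self.error_dist!r}; known: {ERROR_DISTRIBUTIONS}"
            )
        if self.strategy not in ("fixed", "min_estimated_mse", "oracle"):
            raise ConfigError(f"unknown strategy {self.strategy!r}")


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth coefficients tied to one realized design."""

    beta_true: np.ndarray
    alpha_true: np.ndarray
    lambdas: np.ndarray
    decomp: CanonicalDecomposition


@dataclass(frozen=True)
class ScenarioResult:
    """Empirical MSEs, Monte Carlo standard errors and P_MSE for one scenario."""

    mse: Dict[str, float]
    mc_se: Dict[str, float]
    p_mse: Dict[str, float]
    mean_gamma: Dict[str, float]
    config: ScenarioConfig


def generate_design(
    n: int, p: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw the one-factor collinear design matrix.

    p + 1 iid standard-normal columns ``z`` are mixed as
    ``x_jw = sqrt(1 - rho^2) z_jw + rho z_j,p+1``, so every predictor has
    unit variance and every pair of predictors has correlation rho^2.
    """
    if not (0.0 <= rho < 1.0):
        raise ConfigError(f"rho must be in [0, 1), got {rho}")
    Z = rng.standard_normal((n, p + 1))
    return np.sqrt(1.0 - rho**2) * Z[:, :p] + rho * Z[:, [p]]


def generate_true_coefficients(X: np.ndarray) -> TrueModel:
    """Unit-norm eigenvector of X'X for the largest eigenvalue as beta.

    In canonical coordinates the truth is then (up to sign convention)
    the first standard basis vector: all signal sits on the
    best-conditioned direction.
    """
    decomp = decompose_matrix(X)
    lam = decomp.lambdas
    if lam[-1] <= RCOND * max(lam[0], np.finfo(float).tiny):
        raise InvalidDataError("realized design is numerically rank deficient")
    beta = decomp.U[:, 0].copy()
    alpha = decomp.U.T @ beta
    return TrueModel(beta_true=beta, alpha_true=alpha, lambdas=lam, decomp=decomp)


def generate_errors(
    n: int, sigma2: float, error_dist: str, rng: np.random.Generator
) -> np.ndarray:
    """Draw the error vector for one replication.

    normal: N(0, sigma2).  t2: raw Student-t with 2 df (heavy tails,
    infinite variance; sigma2 is ignored).  f4_16: F(4,16) centred and
    scaled to unit variance by its analytic moments (sigma2 ignored).
    """
    if error_dist == "normal":
        return math.sqrt(sigma2) * rng.standard_normal(n)
    if error_dist == "t2":
        return rng.standard_t(2, size=n)
    if error_dist == "f4_16":
        return (rng.f(4, 16, size=n) - _F_MEAN) / _F_SD
    raise ConfigError(f"unknown error_dist {error_dist!r}")


def empirical_mse(estimates: np.ndarray, truth: np.ndarray) -> float:
    """(1/M) sum_v sum_w (alpha_hat_vw - alpha_vw)^2 over M replications."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise InvalidDataError(f"shape mismatch {est.shape} vs {tru.shape}")
    return float(np.mean(np.sum((est - tru) ** 2, axis=-1)))


def p_mse(mse_baseline: float, mse_bqr: float) -> float:
    """Percentage MSE reduction 100 * (MSE - MSE*) / MSE.

    Positive values mean the BQR version improved on its baseline;
    negative values mean deterioration.
    """
    if mse_baseline <= 0:
        raise InvalidDataError("baseline MSE must be positive")
    return 100.0 * (mse_baseline - mse_bqr) / mse_baseline


def _grid_indices(grid: Sequence[float], B: int) -> np.ndarray:
    return np.maximum(np.ceil(np.asarray(grid) * B).astype(int), 1) - 1


def run_scenario(config: ScenarioConfig, compute_bqr: bool = True) -> ScenarioResult:
    """Run one simulation scenario.

    Per replication: fresh design, truth and errors; canonical OLS; the
    five baseline ridge fits; and (when ``compute_bqr``) the five BQR fits
    sharing one set of B pairs-bootstrap resamples.  Replication seeds are
    spawned from ``config.seed`` so results do not depend on execution
    order.
    """
    n, p, M = config.n, config.p, config.M
    B = config.bootstrap.B
    grid = config.bootstrap.gamma_grid
    if config.strategy == "fixed" and len(grid) != 1:
        raise ConfigError("strategy='fixed' needs a single-level gamma_grid")
    labels = ["OLS"] + list(ESTIMATOR_NAMES)
    if compute_bqr:
        labels += [f"BQR-{name}" for name in ESTIMATOR_NAMES]
    sq_err = {lab: np.empty(M) for lab in labels}
    gamma_sum = {name: 0.0 for name in ESTIMATOR_NAMES}
    qidx = _grid_indices(grid, B)

    children = np.random.SeedSequence(config.seed).spawn(M)
    for v in range(M):
        rng = np.random.default_rng(children[v])
        # regenerate on the (measure-zero) chance of a degenerate draw
        for _attempt in range(100):
            try:
                X = generate_design(n, p, config.rho, rng)
                tm = generate_true_coefficients(X)
                break
            except InvalidDataError:
                continue
        else:  # pragma: no cover
            raise InvalidDataError(f"replication {v}: could not draw a full-rank design")
        eps = generate_errors(n, config.sigma2, config.error_dist, rng)
        y = X @ tm.beta_true + eps
        lam = tm.lambdas
        Zty = tm.decomp.Z.T @ y
        alpha_ols = Zty / lam
        resid = y - tm.decomp.Z @ alpha_ols
        s2_hat = float(resid @ resid) / (n - p)
        a2 = alpha_ols**2
        if a2.min() <= 0.0:  # pragma: no cover - measure zero
            raise InvalidDataError(f"replication {v}: exactly zero OLS coefficient")
        k_base = {
            "HK": s2_hat / a2.max(),
            "HKB": p * s2_hat / a2.sum(),
            "HSL": s2_hat * float((lam**2 * a2).sum()) / float((lam * a2).sum()) ** 2,
            "AM": s2_hat * float((1.0 / a2).mean()),
            "GM": s2_hat * float(np.exp(-np.mean(np.log(a2)))),
        }
        sq_err["OLS"][v] = float(np.sum((alpha_ols - tm.alpha_true) ** 2))
        for name in ESTIMATOR_NAMES:
            a_k = Zty / (lam + k_base[name])
            sq_err[name][v] = float(np.sum((a_k - tm.alpha_true) ** 2))
        if not compute_bqr:
            continue
        ks, _ = batched_k_replicates(X, y, B, rng, config.bootstrap.max_redraws)
        ks.sort(axis=0)
        if config.strategy == "oracle":
            alpha_ref, s2_ref = tm.alpha_true, config.sigma2
        elif config.strategy == "min_estimated_mse":
            alpha_ref, s2_ref = alpha_ols, s2_hat
        else:  # fixed
            alpha_ref, s2_ref = None, None
        for j, name in enumerate(ESTIMATOR_NAMES):
            cand = ks[qidx, j]
            if config.strategy == "fixed":
                g_sel, k_sel = grid[0], float(cand[0])
            else:
                crits = np.array(
                    [theoretical_mse(lam, float(k), alpha_ref, s2_ref) for k in cand]
                )
                # tie-break toward the largest gamma (last minimal index)
                jbest = len(crits) - 1 - int(np.argmin(crits[::-1]))
                g_sel, k_sel = grid[jbest], float(cand[jbest])
            gamma_sum[name] += g_sel
            a_k = Zty / (lam + k_sel)
            sq_err[f"BQR-{name}"][v] = float(np.sum((a_k - tm.alpha_true) ** 2))

    mse = {lab: float(np.mean(errs)) for lab, errs in sq_err.items()}
    mc_se = {
        lab: float(np.std(errs, ddof=1) / math.sqrt(M)) if M > 1 else float("nan")
        for lab, errs in sq_err.items()
    }
    pm: Dict[str, float] = {}
    mg: Dict[str, float] = {}
    if compute_bqr:
        for name in ESTIMATOR_NAMES:
            pm[name] = p_mse(mse[name], mse[f"BQR-{name}"])
            mg[name] = gamma_sum[name] / M
    return ScenarioResult(mse=mse, mc_se=mc_se, p_mse=pm, mean_gamma=mg, config=config)


_CASES = {
    "case1": dict(n=25, p=4),
    "case2": dict(n=50, p=8),
    "case3": dict(n=100, p=10),
}
_SIGMA2_GRID = (0.5, 1.0, 5.0)
_RHO_GRID = (0.70, 0.80, 0.90, 0.99)
_CASE4_P = (4, 8, 10, 16, 32)


def case_configs(
    case: str,
    M: int = 1000,
    B: int = 200,
    seed: int = 0,
    strategy: str = "oracle",
    error_dist: str = "normal",
) -> List[ScenarioConfig]:
    """Expand a named case of the study grid into scenario configs.

    Cases 1-3 cross sigma2 in {0.5, 1, 5} with rho in {0.7, 0.8, 0.9,
    0.99} at (n, p) = (25, 4), (50, 8), (100, 10); case 4 fixes n=200,
    sigma2=1, rho=0.99 and varies p in {4, 8, 10, 16, 32}.  Each scenario
    gets its own seed spawned from ``seed``.
    """
    if case not in (*_CASES, "case4"):
        raise ConfigError(f"unknown case {case!r}; known: case1..case4")
    configs: List[ScenarioConfig] = []
    if case == "case4":
        cells = [dict(n=200, p=p, sigma2=1.0, rho=0.99) for p in _CASE4_P]
    else:
        np_ = _CASES[case]
        cells = [
            dict(n=np_["n"], p=np_["p"], sigma2=s2, rho=rho)
            for rho in _RHO_GRID
            for s2 in _SIGMA2_GRID
        ]
    children = np.random.SeedSequence(seed).spawn(len(cells))
    for cell, child in zip(cells, children):
        configs.append(
            ScenarioConfig(
                n=cell["n"],
                p=cell["p"],
                rho=cell["rho"],
                sigma2=cell["sigma2"],
                error_dist=error_dist,
                M=M,
                bootstrap=BootstrapSettings(B=B, seed=int(child.generate_state(1)[0] % 2**31)),
                strategy=strategy,
                seed=int(child.generate_state(2)[1] % 2**31),
                case=case,
            )
        )
    return configs


def run_case_grid(case: str, **kwargs) -> List[ScenarioResult]:
    """Run every scenario of one named case; see :func:`case_configs`."""
    return [run_scenario(cfg) for cfg in case_configs(case, **kwargs)]


def results_to_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Tidy table: one row per (scenario, estimator, variant)."""
    rows = []
    for res in results:
        cfg = res.config
        for lab, m in res.mse.items():
            if lab == "OLS":
                est, variant = "OLS", "baseline"
            elif lab.startswith("BQR-"):
                est, variant = lab[4:], "bqr"
            else:
                est, variant = lab, "baseline"
            rows.append(
                {
                    "case": cfg.case,
                    "n": cfg.n,
                    "p": cfg.p,
                    "rho": cfg.rho,
                    "sigma2": cfg.sigma2,
                    "error_dist": cfg.error_dist,
                    "estimator": est,
                    "variant": variant,
                    "mse": m,
                    "mc_se": res.mc_se[lab],
                    "p_mse": res.p_mse.get(est) if variant == "bqr" else np.nan,
                    "mean_gamma": res.mean_gamma.get(est) if variant == "bqr" else np.nan,
                }
            )
    return pd.DataFrame(rows)


def pivot_mse_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Wide layout with one column per estimator/variant, rows by scenario."""
    frame = frame.copy()
    frame["column"] = np.where(
        frame["estimator"] == "OLS",
        "OLS",
        frame["estimator"] + np.where(frame["variant"] == "bqr", "*", ""),
    )
    return frame.pivot_table(
        index=["case", "n", "p", "rho", "sigma2", "error_dist"],
        columns="column",
        values="mse",
    )
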