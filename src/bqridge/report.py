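"""Fit reports: OLS, five baseline ridge rules, five BQR versions.

On real data the truth is unknown, so each row's "estimated MSE" is the
exact canonical ridge-MSE formula evaluated with plug-in OLS quantities
(alpha_hat, sigma2_hat, lambda) at that row's k.  BQR rows select their
quantile level by minimising the same plug-in criterion over the gamma
grid, with the baseline k appended to the candidate set so a BQR row can
never look worse than its own baseline under the reported criterion (a
row whose winner is the baseline k records no gamma).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .bootstrap import (
    BootstrapSettings,
    bootstrap_all_k_distributions,
    empirical_quantile,
)
from .canonical import (
    decompose,
    ols_alpha,
    ridge_alpha,
    sigma2_hat,
    theoretical_mse,
    to_original_space,
)
from .data import Dataset
from .kestimators import ESTIMATOR_NAMES, all_scalar_rules

__all__ = ["FitReport", "fit_report"]


@dataclass(frozen=True)
class FitReport:
    """One row per estimator; ``table`` is ready for printing/CSV."""

    table: pd.DataFrame
    dataset_name: str
    strategy: str
    bootstrap: BootstrapSettings

    @property
    def best(self) -> str:
        return str(self.table.loc[self.table["est_mse"].idxmin(), "estimator"])


def fit_report(
    dataset: Dataset,
    settings: Optional[BootstrapSettings] = None,
    strategy: str = "min_estimated_mse",
) -> FitReport:
    """Fit OLS, the five baseline rules and their BQR versions on a dataset.

    Deterministic given ``settings.seed``.  Coefficients are reported on
    the preprocessed (model) scale; k values are carried at full
    precision, with a 2-decimal display column.
    """
    if settings is None:
        settings = BootstrapSettings()
    data = dataset.data
    decomp = decompose(data)
    a_ols = ols_alpha(decomp, data.y)
    s2 = sigma2_hat(data, a_ols, decomp).sigma2
    lam = decomp.lambdas

    def plugin_mse(k: float) -> float:
        return theoretical_mse(lam, k, a_ols.alpha, s2)

    rows = []

    def add_row(label: str, variant: str, k: float, gamma: Optional[float]) -> None:
        est = ridge_alpha(decomp, data.y, k) if k > 0 else a_ols
        beta = to_original_space(est, decomp).alpha
        row: Dict[str, object] = {
            "estimator": label,
            "variant": variant,
            "k": float(k),
            "k_display": round(float(k), 2),
            "gamma": gamma,
            "est_mse": plugin_mse(float(k)),
        }
        for name, b in zip(dataset.column_names, beta):
            row[f"beta_{name}"] = float(b)
        rows.append(row)

    add_row("OLS", "ols", 0.0, None)
    k_base = all_scalar_rules(a_ols.alpha, lam, s2)
    for name in ESTIMATOR_NAMES:
        add_row(name, "baseline", k_base[name], None)
    dists = bootstrap_all_k_distributions(data, settings)
    for name in ESTIMATOR_NAMES:
        dist = dists[name]
        best_k, best_g, best_crit = k_base[name], None, plugin_mse(k_base[name])
        for g in settings.gamma_grid:
            kq = empirical_quantile(dist, g)
            crit = plugin_mse(kq)
            if crit <= best_crit:
                best_k, best_g, best_crit = kq, g, crit
        add_row(f"{name}*", "bqr", best_k, best_g)

    table = pd.DataFrame(rows)
    return FitReport(
        table=table,
        dataset_name=dataset.name,
        strategy=strategy,
        bootstrap=settings,
    )
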