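"""The bootstrap-quantile ridge (BQR) estimator on one dataset.

Resamples (x_j, y_j) pairs with replacement B=200 times, recomputes the
HK rule on each resample, and selects an upper quantile of the resulting
distribution by minimising the plug-in ridge-MSE formula over a gamma
grid.
"""

import numpy as np

import bqridge as bq

rng = np.random.default_rng(1)
X = bq.generate_design(n=25, p=4, rho=0.99, rng=rng)
truth = bq.generate_true_coefficients(X)
sigma2 = 0.5
y = X @ truth.beta_true + np.sqrt(sigma2) * rng.standard_normal(25)
data = bq.RegressionData(X=X, y=y)

settings = bq.BootstrapSettings(B=200, seed=42)
dist = bq.bootstrap_k_distribution(data, "HK", settings)
print(f"HK bootstrap distribution over B={dist.B} resamples:")
print(f"  min {dist.values[0]:.4f}, median {np.median(dist.values):.4f}, "
      f"max {dist.values[-1]:.4f}")
print("  quantiles over the gamma grid:")
for g in settings.gamma_grid:
    print(f"    gamma={g:.2f} -> k*_gamma = {bq.empirical_quantile(dist, g):.4f}")

# data-driven selection: minimise the exact MSE formula with plug-in
# OLS quantities over the grid
sel, fit = bq.bqr_fit(data, "HK", settings, strategy="min_estimated_mse")
print(f"\nselected gamma = {sel.gamma:.2f}, k*_gamma = {sel.k_star:.4f} "
      f"(plug-in estimated MSE {sel.criterion_value:.4f})")

# with the simulation truth in hand we can compare true MSEs; the oracle
# strategy picks the grid level that genuinely minimises true MSE
d = truth.decomp
sel_oracle = bq.select_gamma(
    data, dist, settings, strategy="oracle", truth=(truth.alpha_true, sigma2)
)
k_hk = bq.estimate_all(data)["HK"].k
for label, k in [("baseline HK", k_hk), ("plug-in BQR", sel.k_star),
                 ("oracle  BQR", sel_oracle.k_star)]:
    mse = bq.theoretical_mse(d.lambdas, k, truth.alpha_true, sigma2)
    print(f"true MSE at {label} k={k:.4f}:  {mse:.4f}")
print(
    "\nOn a single dataset the plug-in choice can land near the baseline;"
    "\naveraged over replications (see simulation_study.py) the upper"
    "\nbootstrap quantile shrinks harder and reduces MSE systematically."
)
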