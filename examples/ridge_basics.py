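"""Canonical-form ridge regression on a small collinear dataset.

Builds a 30x4 design whose predictors share a strong common factor, fits
OLS and ridge in canonical coordinates, and evaluates the five classical
rules for the biasing parameter k.
"""

import numpy as np

import bqridge as bq

rng = np.random.default_rng(0)
X = bq.generate_design(n=30, p=4, rho=0.95, rng=rng)
truth = bq.generate_true_coefficients(X)
y = X @ truth.beta_true + np.sqrt(0.5) * rng.standard_normal(30)
data = bq.RegressionData(X=X, y=y)

decomp = bq.decompose(data)
print("eigenvalues of X'X:", decomp.lambdas.round(3))
print("condition number:  ", round(bq.condition_number(X), 1))

alpha_ols = bq.ols_alpha(decomp, y)
s2 = bq.sigma2_hat(data, alpha_ols, decomp).sigma2
print("sigma2_hat:", round(s2, 4), "(true 0.5)")

print("\nbiasing-parameter rules (each a mean of sigma2/alpha_w^2):")
for name, est in bq.estimate_all(data).items():
    fit = bq.ridge_alpha(decomp, y, est.k)
    err = np.sum((fit.alpha - truth.alpha_true) ** 2)
    print(f"  {name:>3}: k = {est.k:7.4f}   squared alpha-error = {err:.4f}")
err_ols = np.sum((alpha_ols.alpha - truth.alpha_true) ** 2)
print(f"  OLS: k =  0.0000   squared alpha-error = {err_ols:.4f}")
print(
    "\nSmaller k shrinks less; under collinearity the small eigenvalues\n"
    "inflate the OLS variance, so every positive k above improves on OLS."
)
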