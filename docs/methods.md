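# Methods

## Model and canonical form

The package works with the zero-intercept linear model `y = Xβ + ε`,
`E[ε] = 0`, `Var(ε) = σ²Iₙ`, with an `n × p` design, `n > p ≥ 1`.
All estimation happens in canonical coordinates: `X′X = U Λ U′` with
orthogonal `U` and descending eigenvalues `λ₁ ≥ … ≥ λ_p ≥ 0`,
`Z = XU`, `α = U′β`. The ridge estimator with scalar biasing parameter
`k` is `α̂(k)_w = (Z′y)_w/(λ_w + k)`; OLS is the `k = 0` case. Its exact
MSE given `(λ, α, σ²)`,

    MSE(k) = σ² Σ λ_w/(λ_w+k)² + Σ k²α_w²/(λ_w+k)²,

is the criterion used throughout — for the oracle and plug-in quantile
selection and for real-data fit reports.

The error variance is estimated by the unbiased residual mean square
`σ̂² = Σ ε̂_j²/(n−p)` from the OLS fit. Eigenvector signs are fixed so
each column of `U` has its largest-magnitude entry positive, making every
downstream quantity reproducible across LAPACK builds. Eigenvalues below
`1e-10 · λ₁` are treated as zero: OLS then raises a singularity error
naming the offending coordinates, while ridge with `k > 0` remains
computable.

## Biasing-parameter rules

With `k_w = σ̂²/α̂_w²` the per-coordinate optimum, the five scalar rules
are HK (the minimum of the `k_w`), HKB (harmonic mean), AM (arithmetic
mean), GM (geometric mean, computed in log space so large `p` cannot
under/overflow) and HSL (eigenvalue-weighted,
`σ̂²Σ(λ_wα̂_w)²/(Σλ_wα̂_w²)²`). `α̂_max` in HK is the
largest-magnitude coefficient: only `α̂²` enters the formula, so a
signed maximum cannot be intended. The mean inequality gives the ordering
HK ≤ HKB ≤ GM ≤ AM on every valid input; all rules are invariant to sign
flips of `α̂` and scale linearly in `σ̂²`. Coefficients with
`|α̂_w| < 1e-12` raise a degeneracy error for the rules that would divide
by them (per-coordinate, AM, GM); HK, HKB and HSL stay computable while
their own denominators are nonzero.

## The bootstrap-quantile estimator

For a chosen rule, B pairs-bootstrap resamples (whole `(x_j, y_j)` cases
drawn with replacement — case resampling, not residual resampling) each
yield a replicate `k*(u)`; sorted ascending they define the empirical
distribution. The `γ`-quantile is the order statistic `k*(⌈γB⌉)` — an
inverse-empirical-CDF definition chosen because it satisfies
`P(k* < q) ≤ γ ≤ P(k* ≤ q)` exactly and involves no interpolation, so
results are bit-reproducible. Quantiles are non-decreasing in `γ` and
always lie inside `[k*(1), k*(B)]`.

Degenerate resamples — numerically rank-deficient `X*′X*`, or an exactly
zero canonical coefficient — are discarded, counted, and redrawn, up to a
budget of `10·B` before an error reports the failure fraction. The same
B resamples serve all five rules within a replication, which removes
bootstrap noise from between-rule comparisons. The batched implementation
stacks all resampled `p × p` cross-product matrices into one vectorized
eigendecomposition call, which is what keeps `M × B = 200 000`
inner fits per scenario in the seconds range.

Because the condition "pick `γ` so the BQR MSE beats the baseline MSE"
involves the unknown `(α, σ²)`, three explicit selection strategies are
provided:

* **fixed** — a single user-supplied level;
* **min_estimated_mse** — evaluate the exact MSE formula with plug-in
  `(α̂_OLS, σ̂², λ)` at each grid level's quantile and take the
  minimiser; the default for real data;
* **oracle** — the same minimisation with the true `(α, σ²)`; available
  only in simulations, where it measures the headroom of the quantile
  idea independently of how `γ` would be estimated.

The default grid is `γ ∈ {0.50, 0.55, …, 0.95}` — upper levels, since
the classical rules under-shrink and useful corrections sit in the upper
tail of the bootstrap distribution. Ties break toward the largest `γ`
(more shrinkage). Simulation tables default to oracle selection; fit
reports on data use the plug-in strategy and additionally keep the
baseline `k` in the candidate set, so a BQR row can never look worse than
its baseline under the reported criterion (such a row records no `γ`).

## Simulation design

The synthetic-data generator emulates the standard collinearity
benchmark of this literature:

* **Design.** `x_jw = (1−ρ²)^{1/2} z_jw + ρ z_{j,p+1}` with
  `z` iid N(0,1): a one-factor design with unit marginal variances and
  pairwise correlation ρ² between every pair of predictors, drawn fresh
  for each replication. ρ ∈ {0.70, 0.80, 0.90, 0.99} spans moderate to
  severe collinearity.
* **Truth.** `β` is the unit-norm eigenvector of the realized `X′X`
  belonging to `λ₁` (sign-normalized), so `β′β = 1` and the canonical
  truth is `α = e₁`: all signal rides on the best-conditioned direction.
  This is the convention of the classical simulation lineage; it makes
  shrinkage nearly bias-free and isolates the variance side of the
  trade-off that ridge targets.
* **Errors.** `normal`: N(0, σ²) with σ² ∈ {0.5, 1, 5}. `t2`: raw
  Student-t draws with 2 df — t(2) has infinite variance, so no
  variance-standardization exists and the draws are used as-is, with the
  nominal σ² ignored. `f4_16`: F(4,16) centred by its mean 16/14 and
  scaled by its analytic standard deviation, giving exactly zero mean and
  unit variance.
* **Replication.** Each scenario runs M replications (M=1000 for
  reported numbers; the test suite uses M=200 for the grid-wide BQR
  dominance check, which keeps the full suite under a minute while the
  Monte Carlo standard errors remain small relative to the effects
  tested). Per-replication seeds are spawned from the scenario seed, so
  results are independent of execution order and reproducible under
  parallel execution. Empirical MSE is `(1/M) Σ_v Σ_w (α̂_vw − α_vw)²`,
  reported with Monte Carlo standard errors; the improvement indicator is
  `P_MSE = 100·(MSE − MSE_BQR)/MSE`.

The scenario grid: cases 1–3 cross σ² and ρ at (n,p) = (25,4), (50,8),
(100,10); case 4 fixes n=200, σ²=1, ρ=0.99 and varies
p ∈ {4, 8, 10, 16, 32}.

What the generator does **not** emulate: heteroscedastic or dependent
errors, non-Gaussian predictors, structured (block or autoregressive)
correlation, contaminated/outlying cases, and truth vectors with signal
on poorly conditioned directions. Passing tests therefore demonstrate the
estimators' behaviour under the classical benchmark conditions, not
robustness on arbitrary real data.

## Numerical choices and edge cases

* Quantile definition, eigenvector sign fix, singularity threshold and
  tie-breaks as above; all chosen for exact reproducibility.
* `σ̂²` can be exactly zero (noiseless data): every rule then returns
  `k = 0` and BQR reduces to OLS.
* In the σ² → 0 *limit* the mean-based rules do **not** vanish: for null
  coordinates `α̂_w² = O(σ²)`, so the ratios `σ̂²/α̂_w²` entering AM and
  GM stay O(λ) and a residual shrinkage bias survives. HK, HKB and HSL
  do vanish with σ². This is a property of the estimators, not an
  artifact.
* Negative `k`, γ outside (0,1), mismatched dimensions, missing or
  non-numeric CSV cells all raise typed errors naming the offending
  quantity.
* Real-data preprocessing defaults to correlation form — centered
  response, centered unit-length predictors — with the scaling constants
  retained; the condition number is computed on the preprocessed matrix,
  so its value depends on that (documented) choice.

## Known limitations

* The percentage reductions achieved by BQR depend strongly on the
  γ-selection strategy and grid; the oracle numbers are an upper bound on
  what any data-driven `γ` rule can deliver over the same grid.
* VIF uses auxiliary regressions with intercepts and reports `inf` under
  perfect collinearity rather than failing, but does not identify which
  linear combination is degenerate.
* Wild/residual bootstrap variants for heteroscedastic errors, bootstrap
  confidence intervals for `β`, and generalized per-coordinate `K`
  matrices beyond the vector-valued utility rule are out of scope.
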