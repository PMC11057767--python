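import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from bqridge import (
    BootstrapKDistribution,
    BootstrapSettings,
    ConfigError,
    InvalidDataError,
    RegressionData,
    bootstrap_all_k_distributions,
    bootstrap_k_distribution,
    bqr_fit,
    decompose,
    decompose_matrix,
    empirical_quantile,
    ols_alpha,
    resample_pairs,
    ridge_alpha,
    select_gamma,
    theoretical_mse,
)
from bqridge.kestimators import k_hk
from conftest import make_collinear_data


class TestResamplePairs:
    def test_rows_are_drawn_jointly(self, rng):
        X = np.arange(12.0).reshape(6, 2)
        y = X[:, 0] * 10.0
        data = RegressionData(X=X, y=y)
        boot = resample_pairs(data, rng)
        # pairing preserved: y must still be 10x the first predictor
        np.testing.assert_allclose(boot.y, boot.X[:, 0] * 10.0)

    def test_expected_row_counts_multinomial(self):
        # each of 5 rows appears ~1/5 of the time over many resamples
        rng = np.random.default_rng(42)
        X = np.eye(5)[:, :3]
        data = RegressionData(X=X + 0.01, y=np.arange(5.0))
        counts = np.zeros(5)
        reps = 10_000
        for _ in range(reps):
            boot = resample_pairs(data, rng)
            for val in boot.y:
                counts[int(val)] += 1
        freq = counts / (5 * reps)
        se = np.sqrt(0.2 * 0.8 / (5 * reps))
        assert np.all(np.abs(freq - 0.2) < 3 * se + 1e-12)

    def test_deterministic_given_seed(self, collinear_data):
        a = resample_pairs(collinear_data, np.random.default_rng(3))
        b = resample_pairs(collinear_data, np.random.default_rng(3))
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)


class TestBootstrapDistribution:
    def test_noiseless_data_gives_all_zero(self, rng):
        X = rng.standard_normal((20, 3))
        d = decompose_matrix(X)
        data = RegressionData(X=X, y=d.Z @ np.array([1.0, -2.0, 0.7]))
        dist = bootstrap_k_distribution(data, "HK", BootstrapSettings(B=50, seed=1))
        np.testing.assert_allclose(dist.values, 0.0, atol=1e-12)

    def test_values_sorted_for_any_seed(self, collinear_data):
        for seed in range(5):
            dist = bootstrap_k_distribution(
                collinear_data, "HK", BootstrapSettings(B=64, seed=seed)
            )
            assert (np.diff(dist.values) >= 0).all()

    def test_named_and_callable_rules_agree(self, collinear_data):
        """The batched fast path and the generic per-resample loop consume
        the identical RNG stream, so the same rule gives identical values."""
        st_ = BootstrapSettings(B=32, seed=11)
        fast = bootstrap_k_distribution(collinear_data, "HK", st_)
        slow = bootstrap_k_distribution(
            collinear_data, lambda a, lam, s2: k_hk(a, s2).k, st_
        )
        np.testing.assert_allclose(fast.values, slow.values, rtol=1e-10)

    def test_shared_resamples_across_estimators(self, collinear_data):
        st_ = BootstrapSettings(B=40, seed=5)
        dists = bootstrap_all_k_distributions(collinear_data, st_)
        solo = bootstrap_k_distribution(collinear_data, "GM", st_)
        np.testing.assert_allclose(dists["GM"].values, solo.values, rtol=1e-12)

    def test_min_max_bracket_full_sample_k(self):
        # the bootstrap distribution brackets the full-sample estimate in
        # >= 95% of outer replications
        hits = 0
        outer = 100
        for seed in range(outer):
            data = make_collinear_data(n=30, p=4, rho=0.9, seed=seed)
            d = decompose(data)
            a = ols_alpha(d, data.y)
            from bqridge import sigma2_hat

            s2 = sigma2_hat(data, a, d).sigma2
            k_full = k_hk(a.alpha, s2).k
            dist = bootstrap_k_distribution(
                data, "HK", BootstrapSettings(B=200, seed=seed)
            )
            if dist.values[0] <= k_full <= dist.values[-1]:
                hits += 1
        assert hits >= 95

    def test_quantile_stabilizes_with_B(self, collinear_data):
        # successive quantile differences shrink as B grows
        qs = []
        for B in (50, 200, 800, 2000):
            dist = bootstrap_k_distribution(
                collinear_data, "HK", BootstrapSettings(B=B, seed=0)
            )
            qs.append(empirical_quantile(dist, 0.9))
        diffs = np.abs(np.diff(qs))
        assert diffs[-1] < diffs[0]


class TestEmpiricalQuantile:
    def make(self, values):
        return BootstrapKDistribution("HK", np.asarray(values, float))

    def test_order_statistic_examples(self):
        d = self.make([1, 2, 3, 4, 5])
        assert empirical_quantile(d, 0.5) == 3.0  # ceil(2.5) = 3rd
        assert empirical_quantile(d, 0.8) == 4.0  # ceil(4.0) = 4th

    def test_gamma_near_one_returns_max(self):
        d = self.make(np.arange(200.0))
        assert empirical_quantile(d, 0.9999) == 199.0

    def test_domain_errors(self):
        d = self.make([1.0, 2.0])
        for g in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(InvalidDataError):
                empirical_quantile(d, g)

    @given(
        values=st.lists(st.floats(0.0, 100.0), min_size=2, max_size=50),
        g1=st.floats(0.01, 0.99),
        g2=st.floats(0.01, 0.99),
    )
    @hsettings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_gamma(self, values, g1, g2):
        d = self.make(np.sort(values))
        lo, hi = sorted([g1, g2])
        assert empirical_quantile(d, lo) <= empirical_quantile(d, hi)
        assert d.values[0] <= empirical_quantile(d, g1) <= d.values[-1]


class TestSelectGamma:
    def test_fixed_single_level(self, collinear_data):
        st_ = BootstrapSettings(B=100, seed=2, gamma_grid=(0.9,))
        dist = bootstrap_k_distribution(collinear_data, "HK", st_)
        sel = select_gamma(collinear_data, dist, st_, strategy="fixed")
        assert sel.gamma == 0.9
        assert sel.k_star == empirical_quantile(dist, 0.9)

    def test_fixed_requires_single_level(self, collinear_data):
        st_ = BootstrapSettings(B=100, seed=2)
        dist = bootstrap_k_distribution(collinear_data, "HK", st_)
        with pytest.raises(ConfigError):
            select_gamma(collinear_data, dist, st_, strategy="fixed")

    def test_plugin_attains_grid_minimum(self, collinear_data):
        st_ = BootstrapSettings(B=200, seed=4)
        dist = bootstrap_k_distribution(collinear_data, "HK", st_)
        sel = select_gamma(collinear_data, dist, st_, strategy="min_estimated_mse")
        d = decompose(collinear_data)
        a = ols_alpha(d, collinear_data.y)
        from bqridge import sigma2_hat

        s2 = sigma2_hat(collinear_data, a, d).sigma2
        curve = [
            theoretical_mse(d.lambdas, empirical_quantile(dist, g), a.alpha, s2)
            for g in st_.gamma_grid
        ]
        assert sel.criterion_value == pytest.approx(min(curve))
        assert sel.k_star == empirical_quantile(dist, sel.gamma)

    def test_oracle_beats_baseline_in_true_mse(self):
        rng = np.random.default_rng(0)
        from bqridge import generate_design, generate_true_coefficients

        X = generate_design(25, 4, 0.95, rng)
        tm = generate_true_coefficients(X)
        sigma2 = 0.5
        y = X @ tm.beta_true + np.sqrt(sigma2) * rng.standard_normal(25)
        data = RegressionData(X=X, y=y)
        d = tm.decomp
        a = ols_alpha(d, data.y)
        from bqridge import sigma2_hat

        s2 = sigma2_hat(data, a, d).sigma2
        k_base = k_hk(a.alpha, s2).k
        st_ = BootstrapSettings(B=200, seed=1)
        dist = bootstrap_k_distribution(data, "HK", st_)
        sel = select_gamma(
            data, dist, st_, strategy="oracle", truth=(tm.alpha_true, sigma2)
        )
        mse_sel = theoretical_mse(d.lambdas, sel.k_star, tm.alpha_true, sigma2)
        mse_base = theoretical_mse(d.lambdas, k_base, tm.alpha_true, sigma2)
        assert mse_sel <= mse_base
        # and no other grid level does better, by construction
        for g in st_.gamma_grid:
            kq = empirical_quantile(dist, g)
            assert mse_sel <= theoretical_mse(d.lambdas, kq, tm.alpha_true, sigma2) + 1e-12

    def test_oracle_requires_truth(self, collinear_data):
        st_ = BootstrapSettings(B=50, seed=0)
        dist = bootstrap_k_distribution(collinear_data, "HK", st_)
        with pytest.raises(ConfigError):
            select_gamma(collinear_data, dist, st_, strategy="oracle")


class TestBqrFit:
    def test_noiseless_reduces_to_ols(self, rng):
        X = rng.standard_normal((20, 3))
        d = decompose_matrix(X)
        data = RegressionData(X=X, y=d.Z @ np.array([1.0, 2.0, -1.0]))
        sel, est = bqr_fit(data, "HK", BootstrapSettings(B=50, seed=0))
        assert sel.k_star == 0.0
        np.testing.assert_allclose(est.alpha, ols_alpha(d, data.y).alpha, atol=1e-10)

    def test_deterministic_given_seed(self, collinear_data):
        st_ = BootstrapSettings(B=100, seed=77)
        sel1, est1 = bqr_fit(collinear_data, "HKB", st_)
        sel2, est2 = bqr_fit(collinear_data, "HKB", st_)
        assert sel1 == sel2
        np.testing.assert_array_equal(est1.alpha, est2.alpha)

    def test_selected_k_within_bootstrap_range(self, collinear_data):
        st_ = BootstrapSettings(B=150, seed=9)
        dist = bootstrap_k_distribution(collinear_data, "GM", st_)
        sel, _ = bqr_fit(collinear_data, "GM", st_)
        assert dist.values[0] <= sel.k_star <= dist.values[-1]

    def test_oracle_bqr_improves_on_baseline_monte_carlo(self):
        """Paired 200-replication comparison at n=25, p=4, rho=0.99: the
        oracle-gamma BQR version of HK has smaller mean squared
        canonical-coefficient error than baseline HK."""
        from bqridge import BootstrapSettings as BS
        from bqridge import ScenarioConfig, run_scenario

        res = run_scenario(
            ScenarioConfig(
                n=25, p=4, rho=0.99, sigma2=0.5, M=200,
                bootstrap=BS(B=200, seed=1), strategy="oracle", seed=123,
            )
        )
        assert res.mse["BQR-HK"] < res.mse["HK"]
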