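"""Proportional and power-law fits: closed-form oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shootscale.exceptions import DataValidationError, NonIdentifiableError
from shootscale.regression import (
    PowerLawRegression,
    ProportionalRegression,
    fit_metrics,
    fit_ols_loglog,
    fit_proportional,
    fit_rma_loglog,
    select_method,
)


def random_loglog_data(rng, n=80, alpha=1.3, beta=2.0, sigma=0.25):
    x = np.exp(rng.uniform(0, 3, n))
    y = beta * x**alpha * np.exp(rng.normal(0, sigma, n))
    return x, y


class TestProportionalFit:
    def test_noiseless_proportionality_is_exact(self, rng):
        x = rng.uniform(1, 100, 40)
        fit = fit_proportional(x, 0.5 * x)
        assert fit.k_hat == pytest.approx(0.5, abs=1e-14)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)
        assert fit.mape == pytest.approx(0.0, abs=1e-10)

    def test_equals_geometric_mean_ratio(self, rng):
        x, y = random_loglog_data(rng, alpha=1.0, beta=0.7)
        fit = fit_proportional(x, y)
        geo = np.exp(np.mean(np.log(y / x)))
        assert fit.k_hat == pytest.approx(geo, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000), k=st.floats(0.1, 0.99))
    def test_geometric_mean_property(self, seed, k):
        r = np.random.default_rng(seed)
        x = np.exp(r.uniform(0, 4, 30))
        y = k * x * np.exp(r.normal(0, 0.3, 30))
        assert fit_proportional(x, y).k_hat == pytest.approx(
            np.exp(np.mean(np.log(y) - np.log(x))), rel=1e-12
        )

    def test_recovers_montgomery_constant_on_synthetic_leaves(self, rng):
        # multiplicative log-normal area noise around A = k L W; the 2 sigma/sqrt(n)
        # band around the generating k holds at its nominal ~95% rate
        n, k_true, sigma = 505, 0.72, 0.03
        within = 0
        for _ in range(100):
            lengths = rng.uniform(5, 30, n)
            widths = 0.15 * lengths
            areas = k_true * lengths * widths * np.exp(rng.normal(0, sigma, n))
            fit = fit_proportional(lengths * widths, areas)
            within += abs(np.log(fit.k_hat / k_true)) < 2 * sigma / np.sqrt(n)
        assert within >= 90

    def test_nonpositive_and_short_inputs_rejected(self):
        with pytest.raises(DataValidationError):
            fit_proportional([1.0, -2.0], [1.0, 1.0])
        with pytest.raises(DataValidationError):
            fit_proportional([1.0], [2.0])


class TestOLSPowerLaw:
    @pytest.mark.parametrize("alpha, beta", [(2.0, 1.0), (0.8, 3.0)])
    def test_noiseless_power_law_exact(self, rng, alpha, beta):
        x = np.exp(rng.uniform(0, 3, 30))
        fit = fit_ols_loglog(x, beta * x**alpha)
        assert fit.alpha == pytest.approx(alpha, abs=1e-12)
        assert fit.beta == pytest.approx(beta, rel=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        x, y = random_loglog_data(rng)
        fit = fit_ols_loglog(x, y)
        lx, ly = np.log(x), np.log(y)
        slope = np.sum((lx - lx.mean()) * (ly - ly.mean())) / np.sum((lx - lx.mean()) ** 2)
        intercept = ly.mean() - slope * lx.mean()
        assert fit.alpha == pytest.approx(slope, rel=1e-12)
        assert fit.gamma == pytest.approx(intercept, rel=1e-12)

    def test_zero_predictor_variance_rejected(self):
        with pytest.raises(NonIdentifiableError):
            fit_ols_loglog([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestRMAPowerLaw:
    def test_perfect_line_exact(self, rng):
        x = np.exp(rng.uniform(0, 2, 20))
        assert fit_rma_loglog(x, x**3).alpha == pytest.approx(3.0, rel=1e-12)

    def test_axis_swap_inverts_slope(self, rng):
        x, y = random_loglog_data(rng)
        assert fit_rma_loglog(x, y).alpha * fit_rma_loglog(y, x).alpha == pytest.approx(
            1.0, rel=1e-12
        )

    def test_slope_squared_is_ratio_of_ols_slopes(self, rng):
        x, y = random_loglog_data(rng)
        rma = fit_rma_loglog(x, y)
        b_yx = fit_ols_loglog(x, y).alpha
        b_xy = fit_ols_loglog(y, x).alpha
        assert rma.alpha**2 == pytest.approx(b_yx / b_xy, rel=1e-10)

    def test_attenuation_ordering(self, rng):
        x, y = random_loglog_data(rng, sigma=0.6)
        assert abs(fit_rma_loglog(x, y).alpha) >= abs(fit_ols_loglog(x, y).alpha)

    def test_rma_slope_magnitude_is_sd_ratio(self, rng):
        x, y = random_loglog_data(rng)
        fit = fit_rma_loglog(x, y)
        assert abs(fit.alpha) == pytest.approx(
            np.std(np.log(y), ddof=1) / np.std(np.log(x), ddof=1), rel=1e-12
        )

    def test_zero_correlation_reported_not_resolved(self):
        # symmetric cross: exactly zero log-scale correlation
        x = np.exp(np.array([-1.0, 1.0, -1.0, 1.0]))
        y = np.exp(np.array([-1.0, 1.0, 1.0, -1.0]))
        with pytest.raises(NonIdentifiableError, match="ambiguous"):
            fit_rma_loglog(x, y)


class TestSharedInvariances:
    @pytest.mark.parametrize("method", ["OLS", "RMA"])
    def test_rescaling_x_shifts_intercept_only(self, rng, method):
        x, y = random_loglog_data(rng)
        c = 7.3
        base = PowerLawRegression(method=method).fit(x, y)
        scaled = PowerLawRegression(method=method).fit(c * x, y)
        assert scaled.alpha_ == pytest.approx(base.alpha_, rel=1e-12)
        assert scaled.gamma_ == pytest.approx(base.gamma_ - base.alpha_ * np.log(c), rel=1e-9)

    @pytest.mark.parametrize("method", ["OLS", "RMA"])
    def test_reordering_observations_irrelevant(self, rng, method):
        x, y = random_loglog_data(rng)
        perm = rng.permutation(len(x))
        a = PowerLawRegression(method=method).fit(x, y)
        b = PowerLawRegression(method=method).fit(x[perm], y[perm])
        assert a.alpha_ == pytest.approx(b.alpha_, rel=1e-12)

    def test_log_base_changes_rmse_and_gamma_not_alpha_or_k(self, rng):
        x, y = random_loglog_data(rng)
        nat = PowerLawRegression("OLS", log_base="e").fit(x, y)
        ten = PowerLawRegression("OLS", log_base=10).fit(x, y)
        assert ten.alpha_ == pytest.approx(nat.alpha_, rel=1e-12)
        assert ten.beta_ == pytest.approx(nat.beta_, rel=1e-12)
        assert ten.rmse_ == pytest.approx(nat.rmse_ / np.log(10), rel=1e-12)
        assert ten.gamma_ == pytest.approx(nat.gamma_ / np.log(10), rel=1e-12)
        p_nat = ProportionalRegression(log_base="e").fit(x, y)
        p_ten = ProportionalRegression(log_base=10).fit(x, y)
        assert p_ten.k_ == pytest.approx(p_nat.k_, rel=1e-12)
        assert p_ten.rmse_ == pytest.approx(p_nat.rmse_ / np.log(10), rel=1e-12)

    def test_sklearn_params_round_trip(self):
        est = PowerLawRegression(method="RMA", log_base=10)
        assert PowerLawRegression(**est.get_params()).get_params() == est.get_params()
        est.set_params(method="OLS")
        assert est.method == "OLS"

    def test_predict_on_original_scale(self, rng):
        x, y = random_loglog_data(rng, alpha=1.0, beta=0.5, sigma=0.0)
        prop = ProportionalRegression().fit(x, y)
        assert prop.predict(x) == pytest.approx(y, rel=1e-12)
        pl = PowerLawRegression("OLS").fit(x, y)
        assert pl.predict(x) == pytest.approx(y, rel=1e-9)


class TestMetricsAndMethodChoice:
    def test_perfect_and_mean_predictions(self, rng):
        obs = rng.uniform(1, 10, 50)
        lobs = np.log(obs)
        rmse, r2, mape = fit_metrics(lobs, lobs, obs, obs)
        assert (rmse, r2, mape) == (0.0, 1.0, 0.0)
        const = np.full_like(lobs, lobs.mean())
        _, r2, _ = fit_metrics(lobs, const, obs, np.exp(const))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        obs_l, pred_l = rng.normal(0, 1, 60), rng.normal(0, 1, 60)
        obs_r, pred_r = np.exp(obs_l), np.exp(pred_l)
        rmse, r2, mape = fit_metrics(obs_l, pred_l, obs_r, pred_r, dof=2)
        sse = np.sum((obs_l - pred_l) ** 2)
        assert rmse == pytest.approx(np.sqrt(sse / 58), rel=1e-12)
        assert r2 == pytest.approx(1 - sse / np.sum((obs_l - obs_l.mean()) ** 2), rel=1e-12)
        assert mape == pytest.approx(100 * np.mean(np.abs(obs_r - pred_r) / obs_r), rel=1e-12)
        # r2 may be negative for a terrible predictor; it is not clamped
        assert r2 < 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataValidationError):
            fit_metrics([1.0, 2.0], [1.0], [1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "dims, expected",
        [(("area", "area"), "OLS"), (("count", "area"), "RMA"), (("mass", "area"), "RMA")],
    )
    def test_dimensional_homogeneity_rule(self, dims, expected):
        assert select_method(*dims) == expected

    def test_unknown_dimension_tag_rejected(self):
        with pytest.raises(ValueError):
            select_method("area", "volume")
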