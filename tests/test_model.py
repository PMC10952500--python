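"""Bias-slope estimators, diagnostics and the effect adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from indexbias import (
    IndexEventBias,
    adjust_effect,
    cwls_correct,
    fit_slope_ols,
    fit_slope_wls,
    regression_diagnostics,
)

from conftest import make_pairs


def normal_equations_slope(x, y, w=None, intercept=True):
    """Brute-force weighted normal equations, independent of the fit path."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
    return coef[-1]


class TestSlopeEstimators:
    def test_exact_linear_data_recovers_slope_with_zero_residuals(self):
        x = np.array([-0.3, -0.1, 0.0, 0.2, 0.5])
        pairs = make_pairs(x, -0.025 * x)
        res = fit_slope_ols(pairs)
        assert res.b == pytest.approx(-0.025, abs=1e-12)
        assert np.allclose(res.fittedvalues, -0.025 * x, atol=1e-12)
        assert res.method == "ols" and res.correction_factor == 1.0

    def test_through_origin_slope_equals_sum_ratio(self):
        x = np.array([1.0, 2.0, 3.0, -1.0, 0.5])
        y = np.array([0.2, -0.1, 0.4, 0.3, 0.0])
        res = fit_slope_ols(make_pairs(x, y), intercept=False)
        assert res.b == pytest.approx(np.sum(x * y) / np.sum(x * x), rel=1e-12)
        assert res.intercept == 0.0

    def test_equal_survival_ses_make_wls_identical_to_ols(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        pairs = make_pairs(x, y, se_gy=np.full(50, 0.37))
        ols = fit_slope_ols(pairs)
        wls = fit_slope_wls(pairs)
        assert wls.b == pytest.approx(ols.b, rel=1e-10)
        assert wls.se_b == pytest.approx(ols.se_b, rel=1e-10)

    def test_four_point_weighted_slope_matches_hand_normal_equations(self):
        x = np.array([0.1, 0.2, 0.4, 0.8])
        y = np.array([0.05, -0.02, 0.10, 0.01])
        w = np.array([4.0, 1.0, 1.0, 1.0])
        pairs = make_pairs(x, y, se_gy=1.0 / np.sqrt(w))
        res = fit_slope_wls(pairs)
        assert res.b == pytest.approx(normal_equations_slope(x, y, w), rel=1e-10)

    @settings(max_examples=40, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-2, 2), st.floats(-2, 2), st.floats(0.1, 2.0)
            ),
            min_size=4,
            max_size=10,
        ),
        intercept=st.booleans(),
    )
    def test_slopes_equal_closed_form_on_any_input(self, data, intercept):
        x, y, se = (np.array(v) for v in zip(*data))
        if np.ptp(x) < 0.1:
            return
        pairs = make_pairs(x, y, se_gy=se)
        ols = fit_slope_ols(pairs, intercept=intercept)
        wls = fit_slope_wls(pairs, intercept=intercept)
        assert ols.b == pytest.approx(
            normal_equations_slope(x, y, intercept=intercept), rel=1e-8, abs=1e-10
        )
        assert wls.b == pytest.approx(
            normal_equations_slope(x, y, w=1 / se**2, intercept=intercept),
            rel=1e-8,
            abs=1e-10,
        )

    def test_location_equivariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        res = fit_slope_ols(make_pairs(x, y))
        shifted = fit_slope_ols(make_pairs(x, y + 0.7))
        assert shifted.b == pytest.approx(res.b, rel=1e-10)
        assert shifted.intercept == pytest.approx(res.intercept + 0.7, rel=1e-9)

    def test_ci_brackets_estimate_and_p_in_unit_interval(self, rng):
        pairs = make_pairs(rng.normal(size=20), rng.normal(size=20))
        res = fit_slope_wls(pairs)
        assert res.ci_low <= res.b <= res.ci_high
        assert 0 < res.pvalue <= 1
        assert res.n_snps == 20

    def test_degenerate_design_is_fatal(self):
        with pytest.raises(ValueError, match="degenerate|variance"):
            fit_slope_ols(make_pairs([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]))
        with pytest.raises(ValueError):
            fit_slope_ols(make_pairs([1.0, 2.0], [0.1, 0.2]))


class TestCWLS:
    def test_zero_risk_se_means_no_dilution(self, rng):
        x = rng.normal(size=40)
        y = -0.02 * x + rng.normal(size=40) * 0.1
        pairs = make_pairs(x, y, se_gx=np.zeros(40))
        wls = fit_slope_wls(pairs)
        cwls = cwls_correct(wls, pairs)
        assert cwls.correction_factor == pytest.approx(1.0)
        assert cwls.b == pytest.approx(wls.b)
        assert cwls.se_b == pytest.approx(wls.se_b)

    def test_correction_factor_matches_hand_arithmetic(self):
        # beta_gx {1,2,3}, se_gx 0.5, equal weights:
        # c = (1+4+9) / ((1-0.25)+(4-0.25)+(9-0.25)) = 14/13.25
        pairs = make_pairs(
            [1.0, 2.0, 3.0], [0.1, 0.0, 0.2], se_gx=np.full(3, 0.5), se_gy=np.ones(3)
        )
        wls = fit_slope_wls(pairs)
        cwls = cwls_correct(wls, pairs)
        assert cwls.correction_factor == pytest.approx(14.0 / 13.25, rel=1e-12)
        assert cwls.b == pytest.approx(wls.b * 14.0 / 13.25, rel=1e-12)
        assert cwls.se_b == pytest.approx(wls.se_b * 14.0 / 13.25, rel=1e-12)

    def test_zero_slope_is_fixed_point(self):
        # symmetric data with exactly zero fitted slope
        pairs = make_pairs([-1.0, 0.0, 1.0], [1.0, 0.0, 1.0], se_gx=np.full(3, 0.2))
        wls = fit_slope_wls(pairs)
        assert wls.b == pytest.approx(0.0, abs=1e-14)
        cwls = cwls_correct(wls, pairs)
        assert cwls.b == pytest.approx(0.0, abs=1e-14)

    def test_dominant_measurement_error_is_fatal(self):
        pairs = make_pairs([0.1, 0.2, 0.3], [0.0, 0.1, 0.2], se_gx=np.ones(3))
        with pytest.raises(ValueError, match="measurement error"):
            IndexEventBias.from_pairs(pairs).fit("cwls")

    def test_converges_to_wls_as_risk_se_vanishes(self, rng):
        x = rng.normal(size=60)
        y = -0.03 * x + rng.normal(size=60) * 0.05
        wls_b = fit_slope_wls(make_pairs(x, y)).b
        diffs = []
        for se in (0.05, 0.01, 0.001):
            pairs = make_pairs(x, y, se_gx=np.full(60, se))
            diffs.append(abs(IndexEventBias.from_pairs(pairs).fit("cwls").b - wls_b))
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 1e-4


class TestDiagnostics:
    def test_exact_fit_gives_all_zero_residuals(self):
        x = np.linspace(-1, 1, 6)
        res = fit_slope_ols(make_pairs(x, 0.5 * x - 0.1))
        diag = regression_diagnostics(None, res)
        assert np.allclose(diag.std_residuals, 0.0)
        assert np.allclose(diag.sqrt_abs_std_residuals, 0.0)
        assert np.all(np.diff(diag.qq_theoretical) >= 0)

    def test_vector_lengths_and_qq_monotone(self, rng):
        pairs = make_pairs(rng.normal(size=25), rng.normal(size=25))
        diag = fit_slope_wls(pairs).diagnostics()
        for v in (
            diag.fitted,
            diag.std_residuals,
            diag.qq_theoretical,
            diag.qq_sample,
            diag.sqrt_abs_std_residuals,
        ):
            assert v.shape == (25,)
        assert np.all(np.diff(diag.qq_sample) >= 0)

    def test_normal_residuals_track_identity_line(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = -0.025 * x + rng.standard_normal(n)
        diag = fit_slope_ols(make_pairs(x, y)).diagnostics()
        central = (np.abs(diag.qq_theoretical) < stats.norm.ppf(0.995))
        assert np.max(np.abs(diag.qq_sample[central] - diag.qq_theoretical[central])) < 0.1

    def test_heavy_tailed_residuals_deviate_in_the_tails(self, rng):
        n = 5_000
        x = rng.normal(size=n)
        y = -0.025 * x + stats.t(df=2).rvs(size=n, random_state=rng)
        diag = fit_slope_ols(make_pairs(x, y)).diagnostics()
        # studentized t2 residuals overshoot the normal reference in both tails
        assert diag.qq_sample[-1] > diag.qq_theoretical[-1] + 0.5
        assert diag.qq_sample[0] < diag.qq_theoretical[0] - 0.5

    def test_weighted_diagnostics_use_the_fit_weights(self, rng):
        n = 200
        x = rng.normal(size=n)
        se = rng.uniform(0.5, 3.0, size=n)
        y = 0.1 * x + rng.standard_normal(n) * se
        res = fit_slope_wls(make_pairs(x, y, se_gy=se))
        diag = res.diagnostics()
        # weighting standardizes the heteroscedastic noise: spread ~ 1
        assert 0.8 < np.std(diag.std_residuals) < 1.2

    def test_too_few_points_is_fatal(self):
        res = fit_slope_ols(make_pairs([0.0, 1.0, 2.0], [0.0, 0.1, 0.1]))
        with pytest.raises(ValueError, match="at least 4"):
            res.diagnostics()


def _exact_slope():
    x = np.linspace(-1, 1, 8)
    return fit_slope_ols(make_pairs(x, -0.025 * x), intercept=False)


class TestAdjustEffect:
    @pytest.fixture
    def exact_slope(self):
        return _exact_slope()

    def test_adjustment_arithmetic(self, exact_slope):
        beta_gy_prime = math.log(0.766)
        beta_gx = math.log(5.64)
        adj = adjust_effect(beta_gy_prime, 0.0967, beta_gx, 0.089, exact_slope)
        expected = beta_gy_prime + 0.025 * beta_gx
        assert adj.beta_adj == pytest.approx(expected, rel=1e-9)
        assert adj.beta_adj == pytest.approx(-0.2233, abs=5e-4)
        assert adj.hr_adj == pytest.approx(math.exp(expected), rel=1e-9)
        assert adj.ci_low_hr < adj.hr_adj < adj.ci_high_hr

    def test_zero_slope_or_zero_risk_effect_changes_nothing(self, exact_slope):
        pairs = make_pairs([-1.0, 0.0, 1.0], [1.0, 0.0, 1.0])
        zero_slope = fit_slope_ols(pairs)
        adj = zero_slope.adjust(-0.5, 0.1, 2.0, 0.05)
        assert adj.beta_adj == pytest.approx(-0.5, abs=1e-14)
        adj2 = exact_slope.adjust(-0.5, 0.1, 0.0, 0.05)
        assert adj2.beta_adj == -0.5

    @settings(max_examples=30, deadline=None)
    @given(
        b1=st.floats(-1, 1),
        b2=st.floats(-1, 1),
        g=st.floats(-2, 2),
        lam=st.floats(-2, 2),
    )
    def test_linearity_in_survival_effect_and_risk_effect(self, b1, b2, g, lam):
        exact_slope = _exact_slope()
        left = exact_slope.adjust(b1 + lam * b2, 0.1, g, 0.05).beta_adj
        right = (
            exact_slope.adjust(b1, 0.1, g, 0.05).beta_adj
            + lam * exact_slope.adjust(b2, 0.1, 0.0, 0.05).beta_adj
            + lam * (exact_slope.adjust(0.0, 0.1, 0.0, 0.05).beta_adj)
        )
        assert left == pytest.approx(right, rel=1e-9, abs=1e-9)
        scaled_g = exact_slope.adjust(0.0, 0.1, lam * g, 0.05).beta_adj
        assert scaled_g == pytest.approx(
            lam * exact_slope.adjust(0.0, 0.1, g, 0.05).beta_adj, rel=1e-9, abs=1e-12
        )

    def test_delta_method_se(self, exact_slope):
        adj = exact_slope.adjust(-0.2, 0.1, 1.5, 0.2)
        b, se_b = exact_slope.b, exact_slope.se_b
        expected = math.sqrt(0.1**2 + b**2 * 0.2**2 + 1.5**2 * se_b**2)
        assert adj.se_adj == pytest.approx(expected, rel=1e-12)


def test_summary_mentions_method_and_slope(rng):
    pairs = make_pairs(
        rng.normal(size=12), rng.normal(size=12), se_gx=np.full(12, 0.01)
    )
    text = IndexEventBias.from_pairs(pairs).fit("cwls").summary()
    assert "cwls" in text
    assert "dilution" in text
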