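"""The 0-100 points system: rescaling, baselines, totals, and the exp axis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multinomogram import (
    Covariate,
    CovariateProfile,
    ModelSpec,
    build_scoring_chart,
    case_reading,
    category_probabilities,
    chart_S,
    exp_axis_value,
    generate_random_model,
    linear_predictors,
    points,
    random_profile,
    rescaling_factor,
    s_label_to_s,
    total_label_for_l,
    total_points,
)
from multinomogram.model_core import ModelValidationError, RangeError
from multinomogram.scoring_chart import baselines


class TestRescalingFactor:
    def test_toy_model(self, toy_model):
        # effect spans are {|0.2*10|, |1.0*1|, |-0.1*10|, |2.0*1|} = {2,1,1,2}
        assert rescaling_factor(toy_model) == pytest.approx(50.0, abs=1e-12)

    def test_span_100_gives_unit_factor(self):
        m = ModelSpec(
            categories=("a", "b"),
            covariates=(Covariate("x", "continuous", "", 0.0, 100.0),),
            intercepts=np.array([0.0]),
            coefficients=np.array([[1.0]]),
        )
        assert rescaling_factor(m) == pytest.approx(1.0)

    @given(c=st.floats(0.01, 100.0))
    @settings(deadline=None, derandomize=True)
    def test_homogeneity(self, toy_model, c):
        scaled = ModelSpec(
            categories=toy_model.categories,
            covariates=toy_model.covariates,
            intercepts=toy_model.intercepts,
            coefficients=c * toy_model.coefficients,
        )
        assert rescaling_factor(scaled) == pytest.approx(rescaling_factor(toy_model) / c, rel=1e-12)

    def test_all_zero_coefficients_rejected(self):
        m = ModelSpec(
            categories=("a", "b"),
            covariates=(Covariate("x", "binary"),),
            intercepts=np.array([1.0]),
            coefficients=np.array([[0.0]]),
        )
        with pytest.raises(ModelValidationError, match="zero"):
            rescaling_factor(m)


class TestPoints:
    def test_positive_coefficient_scale(self, toy_chart):
        # (x1, category A): beta* = 50*0.2 = 10, offset 0 -> Points = 10x
        assert points(toy_chart, 0, 0, 5.0) == pytest.approx(50.0)
        assert points(toy_chart, 0, 0, 0.0) == 0.0
        assert points(toy_chart, 0, 0, 10.0) == pytest.approx(100.0)

    def test_negative_coefficient_scale(self, toy_chart):
        # (x1, category B): beta* = -5, offset -50 -> Points = -5x + 50
        assert points(toy_chart, 0, 1, 10.0) == pytest.approx(0.0)
        assert points(toy_chart, 0, 1, 0.0) == pytest.approx(50.0)

    def test_binary_favorable_level_is_zero(self, toy_chart):
        assert points(toy_chart, 1, 0, 0.0) == 0.0  # positive beta: 0 at x=0
        m = toy_chart.model
        neg = ModelSpec(
            categories=m.categories, covariates=m.covariates,
            intercepts=m.intercepts,
            coefficients=np.array([[0.2, -1.0], [-0.1, 2.0]]),
        )
        ch = build_scoring_chart(neg)
        assert points(ch, 1, 0, 1.0) == pytest.approx(0.0)  # negative beta: 0 at x=1

    def test_out_of_range(self, toy_chart):
        with pytest.raises(RangeError):
            points(toy_chart, 0, 0, 11.0)
        assert points(toy_chart, 0, 0, 11.0, clamp=True) == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(200))
    def test_bounds_and_exact_max_span(self, seed):
        """Every points value over its range is within [0, 100] and the
        largest achieved span is exactly 100."""
        m = generate_random_model(40_000 + seed, K=2 + seed % 4, J=1 + seed % 5)
        ch = build_scoring_chart(m)
        for corner in (m.lows, m.highs):
            pts = ch.beta_star * corner - ch.point_min
            assert np.all(pts >= -1e-9) and np.all(pts <= 100.0 + 1e-9)
        assert abs(float(ch.point_span.max()) - 100.0) < 1e-9


class TestBaselines:
    def test_toy_values(self, toy_model):
        bl, bl_star, min_bl = baselines(toy_model, 50.0)
        np.testing.assert_allclose(bl, [-100.0, -100.0], atol=1e-12)
        np.testing.assert_allclose(bl_star, [0.0, 0.0], atol=1e-12)
        assert min_bl == pytest.approx(-100.0)

    def test_zero_intercepts_nonnegative_coefficients(self):
        m = ModelSpec(
            categories=("a", "b", "c"),
            covariates=(Covariate("x", "continuous", "", 0.0, 4.0),),
            intercepts=np.zeros(2),
            coefficients=np.array([[0.5], [0.25]]),
        )
        bl, bl_star, min_bl = baselines(m, rescaling_factor(m))
        np.testing.assert_allclose(bl, [0.0, 0.0], atol=1e-12)

    def test_intercept_shift_invariance(self, toy_model):
        """Adding c to every intercept shifts bl by r*c, leaves bl* alone."""
        r = rescaling_factor(toy_model)
        bl0, bls0, _ = baselines(toy_model, r)
        shifted = ModelSpec(
            categories=toy_model.categories, covariates=toy_model.covariates,
            intercepts=toy_model.intercepts + 3.5,
            coefficients=toy_model.coefficients,
        )
        bl1, bls1, _ = baselines(shifted, r)
        np.testing.assert_allclose(bl1, bl0 + r * 3.5, atol=1e-9)
        np.testing.assert_allclose(bls1, bls0, atol=1e-9)

    def test_min_bl_star_is_zero_everywhere(self):
        for seed in range(100):
            ch = build_scoring_chart(generate_random_model(seed, K=2 + seed % 4, J=2))
            assert float(ch.bl_star.min()) == pytest.approx(0.0, abs=1e-12)


class TestTotals:
    def test_toy_profile(self, toy_chart):
        totals = total_points(toy_chart, CovariateProfile([5.0, 1.0]))
        np.testing.assert_allclose(totals, [100.0, 125.0], atol=1e-10)
        l = (totals + toy_chart.min_bl) / toy_chart.r
        np.testing.assert_allclose(l, [0.0, 0.5], atol=1e-12)

    def test_minimum_profile_scores_baseline(self, toy_chart):
        # x1=10 zeroes B's x1 points but not A's; all-minimum level differs
        # per category, so use a model where the minimum is shared
        m = toy_chart.model
        pos = ModelSpec(
            categories=m.categories, covariates=m.covariates,
            intercepts=m.intercepts,
            coefficients=np.abs(m.coefficients),
        )
        ch = build_scoring_chart(pos)
        totals = total_points(ch, CovariateProfile([0.0, 0.0]))
        np.testing.assert_allclose(totals, ch.bl_star, atol=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_linear_predictor_recovery_identity(self, seed):
        """l_k = (Total_k + min_bl)/r within 1e-10 against the direct route."""
        rng = np.random.default_rng(50_000 + seed)
        m = generate_random_model(seed, K=2 + seed % 5, J=1 + seed % 6)
        ch = build_scoring_chart(m)
        prof = random_profile(m, rng)
        totals = total_points(ch, prof)
        l_direct = linear_predictors(m, prof)
        np.testing.assert_allclose((totals + ch.min_bl) / ch.r, l_direct, atol=1e-10)

    def test_delivery_case_identity(self, delivery_model, case_profile):
        ch = build_scoring_chart(delivery_model)
        totals = total_points(ch, case_profile)
        l = linear_predictors(delivery_model, case_profile)
        np.testing.assert_allclose((totals + ch.min_bl) / ch.r, l, atol=1e-10)


class TestExpAxisAndS:
    def test_toy_exp_values(self, toy_chart):
        assert exp_axis_value(toy_chart, 100.0) == pytest.approx(1.0, abs=1e-12)
        assert exp_axis_value(toy_chart, 125.0) == pytest.approx(math.exp(0.5), rel=1e-12)

    def test_toy_chart_S_and_probabilities(self, toy_chart):
        S = chart_S(toy_chart, np.array([100.0, 125.0]))
        assert S == pytest.approx(1.0 + math.exp(0.5), rel=1e-12)
        denom = 1.0 + S
        np.testing.assert_allclose(
            [1.0 / denom, math.exp(0.5) / denom, 1.0 / denom],
            [0.27407, 0.45186, 0.27407], atol=5e-6,
        )
        direct = category_probabilities(toy_chart.model, CovariateProfile([5.0, 1.0]))
        np.testing.assert_allclose(
            [1.0 / denom, math.exp(0.5) / denom, 1.0 / denom], direct.pi, rtol=1e-12
        )

    def test_single_category_unit_total(self):
        m = generate_random_model(9, K=2, J=2)
        ch = build_scoring_chart(m)
        t_unit = total_label_for_l(ch, 0.0)  # total whose exp value is 1
        if float(ch.total_range[0, 0]) <= t_unit <= float(ch.total_range[0, 1]):
            assert chart_S(ch, np.array([t_unit])) == pytest.approx(1.0, rel=1e-12)

    def test_delivery_case_S(self, delivery_model, case_profile):
        ch = build_scoring_chart(delivery_model)
        totals = total_points(ch, case_profile)
        assert chart_S(ch, totals) == pytest.approx(1.08715, abs=5e-6)

    def test_out_of_range_total(self, toy_chart):
        hi = float(toy_chart.total_range[:, 1].max())
        with pytest.raises(RangeError):
            exp_axis_value(toy_chart, hi + 10.0)

    def test_chart_S_shape_check(self, toy_chart):
        with pytest.raises(ValueError):
            chart_S(toy_chart, np.array([100.0]))


class TestTotalLabel:
    def test_anchor_at_l_zero(self, toy_chart):
        assert total_label_for_l(toy_chart, 0.0) == pytest.approx(100.0)

    def test_affine_round_trip(self, toy_chart):
        rng = np.random.default_rng(7)
        for l in rng.uniform(-5, 5, size=100):
            t = total_label_for_l(toy_chart, l)
            assert (t + toy_chart.min_bl) / toy_chart.r == pytest.approx(l, abs=1e-12)


class TestInvariances:
    def test_recentring_a_covariate_changes_nothing(self):
        """x -> x - c with alpha_k -> alpha_k + beta_jk*c leaves r, spans,
        bl*, totals and probabilities identical."""
        m = ModelSpec(
            categories=("A", "B", "ref"),
            covariates=(
                Covariate("u", "continuous", "", 2.0, 12.0),
                Covariate("v", "binary"),
            ),
            intercepts=np.array([-2.0, -1.0]),
            coefficients=np.array([[0.2, 1.0], [-0.1, 2.0]]),
        )
        c = 2.0
        shifted = ModelSpec(
            categories=m.categories,
            covariates=(Covariate("u", "continuous", "", 0.0, 10.0), m.covariates[1]),
            intercepts=m.intercepts + m.coefficients[:, 0] * c,
            coefficients=m.coefficients,
        )
        ch0, ch1 = build_scoring_chart(m), build_scoring_chart(shifted)
        assert ch1.r == pytest.approx(ch0.r, rel=1e-12)
        np.testing.assert_allclose(ch1.point_span, ch0.point_span, atol=1e-9)
        np.testing.assert_allclose(ch1.bl_star, ch0.bl_star, atol=1e-9)
        p0 = CovariateProfile([7.0, 1.0])
        p1 = CovariateProfile([5.0, 1.0])
        np.testing.assert_allclose(
            total_points(ch1, p1), total_points(ch0, p0), atol=1e-9
        )
        np.testing.assert_allclose(
            category_probabilities(shifted, p1).pi,
            category_probabilities(m, p0).pi, rtol=1e-12,
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_integer_rounding_error_bound(self, seed):
        """Rounding points and baseline to integers perturbs each linear
        predictor by at most (J+1)*0.5/r, so the probability error is
        bounded by exp((J+1)*0.5/r) - 1."""
        rng = np.random.default_rng(60_000 + seed)
        m = generate_random_model(seed, K=2 + seed % 4, J=1 + seed % 5)
        ch = build_scoring_chart(m)
        prof = random_profile(m, rng)
        exact = category_probabilities(m, prof)
        pts = np.array(
            [
                [round(points(ch, j, k, prof.x[j], clamp=True)) for j in range(m.J)]
                for k in range(m.K - 1)
            ],
            dtype=float,
        )
        totals = np.round(ch.bl_star) + pts.sum(axis=1)
        l_rounded = (totals + ch.min_bl) / ch.r
        g = sum(math.exp(v) for v in l_rounded)
        pi_rounded = np.array([math.exp(v) / (1 + g) for v in l_rounded] + [1 / (1 + g)])
        bound = math.exp((m.J + 1) * 0.5 / ch.r) - 1.0
        ref = m.reference_index
        order = [i for i in range(m.K) if i != ref] + [ref]
        assert np.max(np.abs(pi_rounded - exact.pi[order])) <= bound + 1e-12

    def test_zero_coefficient_cell_has_flat_scale(self):
        m = ModelSpec(
            categories=("A", "B", "ref"),
            covariates=(Covariate("x", "binary"), Covariate("y", "binary")),
            intercepts=np.array([0.0, 0.0]),
            coefficients=np.array([[1.0, 0.0], [0.5, 0.3]]),
        )
        ch = build_scoring_chart(m)
        assert ch.point_span[0, 1] == 0.0
        assert points(ch, 1, 0, 0.0) == 0.0 and points(ch, 1, 0, 1.0) == 0.0


class TestCaseReading:
    def test_delivery_case_reading_is_consistent(self, delivery_model, case_profile):
        ch = build_scoring_chart(delivery_model)
        cr = case_reading(ch, case_profile)
        assert cr.points.shape == (4, 7)
        np.testing.assert_allclose(cr.points.sum(axis=1) + ch.bl_star, cr.totals, atol=1e-9)
        assert cr.S == pytest.approx(float(np.exp(cr.totals / ch.r + ch.min_bl / ch.r).sum()), rel=1e-12)
        assert s_label_to_s(cr.S) == pytest.approx(
            category_probabilities(delivery_model, case_profile).s, abs=1e-10
        )
        assert cr.pi.sum() == pytest.approx(1.0, abs=1e-12)
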