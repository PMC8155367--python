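"""Model development: screening, nonlinearity diagnostics, VIF, OLS fit."""

import numpy as np
import pandas as pd
import pytest

from parkscreen import (
    InsufficientDataError,
    ValidationError,
    expected_direction,
    fit_final_model,
    load_published_model,
    lowess_diagnostic,
    quadratic_term_test,
    spearman_screen,
    vif_check,
)
from parkscreen.screening_model import evaluate


class TestExpectedDirection:
    @pytest.mark.parametrize(
        "feature,direction",
        [
            ("pegboard_time", "positive"),
            ("pegboard_pegs_dropped", "positive"),
            ("pegboard_pegs_placed", "negative"),
            ("finger_tapping_mean_velocity", "negative"),
            ("hand_rotation_mean_peak_velocity", "negative"),
            ("hand_rotation_cycles_per_second", "negative"),
            ("hand_rotation_decrement_peak_velocity", "negative"),
            ("finger_tapping_coefficient_of_variation", "positive"),
        ],
    )
    def test_catalogue(self, feature, direction):
        assert expected_direction(feature) == direction

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValidationError):
            expected_direction("shoe_size")


class TestSpearmanScreen:
    def _tables(self, feature, subscore):
        n = len(feature)
        ids = [f"P{i}" for i in range(n)]
        return (
            pd.DataFrame({"participant_id": ids, "pegboard_time": feature}),
            pd.DataFrame({"participant_id": ids, "updrs3_bradykinesia": subscore}),
        )

    def test_identical_ranks_selected_when_positive_expected(self):
        f, s = self._tables([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        (res,) = spearman_screen(f, s, {"pegboard_time": "updrs3_bradykinesia"})
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.selected

    def test_perfect_inverse_rho_minus_one_not_selected(self):
        # pegboard time is expected positive; a perfect inverse fails the
        # direction check despite |rho| = 1
        f, s = self._tables([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        (res,) = spearman_screen(f, s, {"pegboard_time": "updrs3_bradykinesia"})
        assert res.spearman_rho == pytest.approx(-1.0)
        assert not res.selected

    def test_independent_feature_not_selected(self, rng):
        n = 4000
        f, s = self._tables(rng.normal(size=n), rng.normal(size=n))
        (res,) = spearman_screen(f, s, {"pegboard_time": "updrs3_bradykinesia"})
        assert abs(res.spearman_rho) < 0.05
        assert not res.selected

    def test_monotone_transform_invariance(self, rng):
        x = rng.uniform(50, 300, 100)
        y = 0.05 * x + rng.normal(0, 2, 100)
        f1, s1 = self._tables(x, y)
        f2, _ = self._tables(np.exp(x / 100.0), y)
        (r1,) = spearman_screen(f1, s1, {"pegboard_time": "updrs3_bradykinesia"})
        (r2,) = spearman_screen(f2, s1, {"pegboard_time": "updrs3_bradykinesia"})
        assert r1.spearman_rho == pytest.approx(r2.spearman_rho, abs=1e-12)

    def test_too_few_pairs_unevaluable(self):
        f, s = self._tables([1.0, 2.0], [1.0, 2.0])
        (res,) = spearman_screen(f, s, {"pegboard_time": "updrs3_bradykinesia"})
        assert not res.selected
        assert "unevaluable" in res.note


class TestLowess:
    def test_linear_relationship_not_flagged(self, rng):
        x = rng.uniform(0, 10, 200)
        y = 2.0 + 3.0 * x + rng.normal(0, 1.0, 200)
        assert not lowess_diagnostic(x, y).curvature_flag

    def test_quadratic_relationship_flagged(self, rng):
        x = rng.uniform(0, 10, 200)
        y = (x - 5.0) ** 2 + rng.normal(0, 1.0, 200)
        assert lowess_diagnostic(x, y).curvature_flag

    def test_small_sample_rejected(self, rng):
        x = rng.uniform(0, 10, 10)
        with pytest.raises(InsufficientDataError):
            lowess_diagnostic(x, x)

    def test_constant_x_rejected(self, rng):
        with pytest.raises(ValidationError):
            lowess_diagnostic(np.full(30, 2.0), rng.normal(size=30))


class TestQuadraticTerm:
    def test_linear_truth_drops_square(self, rng):
        x = rng.uniform(0, 10, 500)
        y = 1.0 + 2.0 * x + rng.normal(0, 1.0, 500)
        keep, p = quadratic_term_test(x, y)
        assert not keep
        assert p > 0.05

    def test_quadratic_truth_keeps_square(self, rng):
        x = rng.uniform(0, 10, 500)
        y = 1.0 + 2.0 * x + 0.3 * x**2 + rng.normal(0, 1.0, 500)
        keep, p = quadratic_term_test(x, y)
        assert keep
        assert p < 0.05

    def test_published_curvature_detected_at_study_scale(self):
        # Simple regression of the motor score on hand-rotation velocity and
        # its square, as run during model development: generate from the
        # unadjusted published effect (-0.0395 linear, 0.00002 quadratic),
        # n = 275, residual SD 5.  The square term should be detected in the
        # majority of replicates at this scale.
        rng = np.random.default_rng(1234)
        detected = 0
        for _ in range(10):
            hr = rng.normal(614.2, 177.0, 275)
            y = -0.0395 * hr + 0.00002 * hr**2 + rng.normal(0, 5.0, 275)
            keep, _ = quadratic_term_test(hr, y)
            detected += keep
        assert detected >= 5

    def test_degenerate_design_rejected(self, rng):
        x = np.full(30, 3.0)
        with pytest.raises(ValidationError):
            quadratic_term_test(x, rng.normal(size=30))


class TestVif:
    @staticmethod
    def _correlated_pair(r, n=64, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        # orthonormalize so the sample correlation is exactly r
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)
        b /= b.std()
        return a, r * a + np.sqrt(1 - r**2) * b

    def test_orthogonal_predictors_have_unit_vif(self):
        x1, x2 = self._correlated_pair(0.0)
        res = vif_check(pd.DataFrame({"u": x1, "v": x2}), exempt=())
        assert all(v.vif == pytest.approx(1.0, abs=1e-10) for v in res)

    @pytest.mark.parametrize("r", [0.3, 0.5, 0.9])
    def test_closed_form_one_over_one_minus_r_squared(self, r):
        x1, x2 = self._correlated_pair(r)
        res = vif_check(pd.DataFrame({"u": x1, "v": x2}), exempt=())
        for v in res:
            assert v.vif == pytest.approx(1.0 / (1.0 - r**2), abs=1e-8)

    def test_duplicated_predictor_is_rank_deficient(self):
        x1, _ = self._correlated_pair(0.0)
        with pytest.raises(ValidationError):
            vif_check(pd.DataFrame({"u": x1, "v": x1}))

    def test_rotation_pair_exempt_from_threshold(self, rng):
        hr = rng.normal(614.2, 177.0, 300)
        df = pd.DataFrame({
            "hand_rotation_mv": hr,
            "hand_rotation_mv_squared": hr**2,
            "finger_tapping_mv": rng.normal(352.0, 115.6, 300),
        })
        res = {v.predictor: v for v in vif_check(df)}
        assert res["hand_rotation_mv"].vif > 2  # inherently collinear pair
        assert res["hand_rotation_mv"].passed  # ... but exempt
        assert res["finger_tapping_mv"].vif < 2
        assert res["finger_tapping_mv"].passed


class TestFitFinalModel:
    @staticmethod
    def _training_table(n, residual_sd, rng, model):
        hr = rng.normal(614.2, 177.0, n)
        ft = rng.normal(352.0, 115.6, n)
        peg = np.minimum(rng.normal(116.2, 47.6, n), 300.0)
        age = rng.uniform(41, 81, n)
        y = np.array([
            evaluate(model, h, f, p, a) for h, f, p, a in zip(hr, ft, peg, age)
        ]) + rng.normal(0, residual_sd, n)
        return pd.DataFrame({
            "hand_rotation_mv": hr, "finger_tapping_mv": ft,
            "pegboard_time_s": peg, "age_years": age, "updrs3_total": y,
        })

    def test_noiseless_outcome_recovered_exactly(self, rng):
        model = load_published_model("with_age")
        data = self._training_table(50, 0.0, rng, model)
        fit = fit_final_model(data)
        assert fit.coefficients.intercept == pytest.approx(model.intercept, abs=1e-7)
        for name in ("hand_rotation_mv", "hand_rotation_mv_squared",
                     "finger_tapping_mv", "pegboard_time", "age"):
            assert getattr(fit.coefficients, name) == pytest.approx(
                getattr(model, name), abs=1e-8
            )

    def test_matches_normal_equations_oracle(self, rng):
        model = load_published_model("with_age")
        data = self._training_table(50, 3.0, rng, model)
        fit = fit_final_model(data)
        X = np.column_stack([
            np.ones(len(data)), data.hand_rotation_mv,
            data.hand_rotation_mv**2, data.finger_tapping_mv,
            data.pegboard_time_s, data.age_years,
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ data.updrs3_total.to_numpy())
        assert fit.coefficients.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.coefficients.hand_rotation_mv == pytest.approx(beta[1], abs=1e-8)
        assert fit.coefficients.pegboard_time == pytest.approx(beta[4], abs=1e-8)
        assert fit.coefficients.age == pytest.approx(beta[5], abs=1e-8)

    def test_confidence_intervals_bracket_estimates(self, rng):
        model = load_published_model("with_age")
        fit = fit_final_model(self._training_table(120, 5.0, rng, model))
        lo, hi = fit.conf_int["pegboard_time_s"]
        assert lo <= fit.coefficients.pegboard_time <= hi
        lo, hi = fit.conf_int["intercept"]
        assert lo <= fit.coefficients.intercept <= hi

    def test_age_free_variant_ignores_age(self, rng):
        model = load_published_model("with_age")
        data = self._training_table(80, 2.0, rng, model)
        fit = fit_final_model(data, variant="age_free")
        assert fit.coefficients.variant == "age_free"
        assert fit.coefficients.age is None
        assert "age_years" not in fit.p_values

    def test_too_few_cases_rejected(self, rng):
        model = load_published_model("with_age")
        data = self._training_table(6, 1.0, rng, model)
        with pytest.raises(InsufficientDataError):
            fit_final_model(data)

    def test_missing_column_named(self, rng):
        model = load_published_model("with_age")
        data = self._training_table(30, 1.0, rng, model).drop(columns=["age_years"])
        with pytest.raises(ValidationError, match="age_years"):
            fit_final_model(data)
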