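import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortexdecorr.core import cd_curve
from cortexdecorr.models import (
    aic,
    aicc,
    compare_models,
    fit_linear,
    fit_polynomial,
    loo_cv_error,
    normalized_errors,
    orthogonal_distances,
    orthogonal_r_squared,
    response_model_prediction,
)


class TestOrthogonalR2:
    def test_points_on_curve_give_one(self):
        r = np.array([-0.6, -0.2, 0.1, 0.5, 0.8])
        assert orthogonal_r_squared(r, cd_curve(r), cd_curve) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_constant_curve_at_centroid_gives_zero(self):
        r = np.array([-0.5, 0.0, 0.5, 0.2, -0.2])
        d = np.array([0.3, -0.1, 0.1, -0.3, 0.0])
        curve = lambda x: np.full_like(np.asarray(x, dtype=float), d.mean())
        # vertical residuals around a flat line at the centroid's d; distances
        # orthogonal to a flat curve are vertical, so R2 = 1 - sum(dy^2)/den
        num = np.sum((d - d.mean()) ** 2)
        den = np.sum((r - r.mean()) ** 2 + (d - d.mean()) ** 2)
        assert orthogonal_r_squared(r, d, curve) == pytest.approx(1 - num / den, abs=1e-6)
        # with no spread along r the centroid-constant curve explains nothing
        r0 = np.full(5, 0.2)
        curve0 = lambda x: np.full_like(np.asarray(x, dtype=float), d.mean())
        assert orthogonal_r_squared(r0, d, curve0) == pytest.approx(0.0, abs=1e-6)

    def test_hand_points_match_fine_grid_oracle(self):
        r = np.array([-0.7, -0.3, 0.0, 0.4, 0.75])
        d = np.array([-0.5, -0.05, 0.1, 0.35, 0.3])
        grid = np.linspace(-1, 1, 20001)  # 1e-4 brute-force oracle
        f = cd_curve(grid)
        expected = np.sqrt(
            [np.min((grid - ri) ** 2 + (f - di) ** 2) for ri, di in zip(r, d)]
        )
        assert orthogonal_distances(r, d, cd_curve) == pytest.approx(expected, abs=1e-4)

    def test_identical_points_undefined(self):
        with pytest.raises(ValueError):
            orthogonal_r_squared([0.2] * 5, [0.1] * 5, cd_curve)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 5000))
    def test_orthogonal_never_exceeds_vertical_distance(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-0.95, 0.95, 6)
        d = rng.uniform(-1, 1, 6)
        orth = orthogonal_distances(r, d, cd_curve)
        vert = np.abs(cd_curve(r) - d)
        assert np.all(orth <= vert + 1e-9)


class TestFitters:
    def test_exact_cubic_recovered(self):
        r = np.linspace(-1, 1, 9)
        d = 0.1 - 0.4 * r + 0.2 * r**2 + 0.9 * r**3
        assert fit_polynomial(r, d, 3) == pytest.approx([0.1, -0.4, 0.2, 0.9], abs=1e-10)

    def test_odd_symmetric_data_kills_even_coefficients(self):
        r = np.array([0.2, 0.5, 0.8, -0.2, -0.5, -0.8])
        d = np.array([0.1, 0.4, 0.6, -0.1, -0.4, -0.6])
        coef = fit_polynomial(r, d, 3)
        assert coef[0] == pytest.approx(0.0, abs=1e-12)
        assert coef[2] == pytest.approx(0.0, abs=1e-12)

    def test_residuals_orthogonal_to_design(self, rng):
        r = rng.uniform(-1, 1, 6)
        d = rng.uniform(-1, 1, 6)
        coef = fit_polynomial(r, d, 3)
        resid = d - np.polynomial.polynomial.polyval(r, coef)
        X = np.vander(r, 4, increasing=True)
        assert X.T @ resid == pytest.approx(np.zeros(4), abs=1e-10)

    def test_all_equal_r_rejected(self):
        with pytest.raises(ValueError):
            fit_polynomial([0.3] * 6, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6], 3)

    def test_linear_fit_on_identity_line(self):
        r = np.array([-0.5, 0.0, 0.3, 0.7])
        assert fit_linear(r, r) == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_linear_fit_matches_closed_form_ols(self, rng):
        r = rng.uniform(-1, 1, 30)
        d = 0.2 + 0.7 * r + rng.normal(0, 0.05, 30)
        a1, a2 = fit_linear(r, d)
        slope = np.cov(r, d, ddof=1)[0, 1] / np.var(r, ddof=1)
        assert a2 == pytest.approx(slope, abs=1e-12)
        assert a1 == pytest.approx(d.mean() - slope * r.mean(), abs=1e-12)


class TestLooCv:
    def test_parameter_free_model_equals_plain_mean_error(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(-0.9, 0.9, 10)
        d = cd_curve(r) + rng.normal(0, 0.1, 10)
        fitter = lambda rt, dt: cd_curve
        assert loo_cv_error(r, d, fitter) == pytest.approx(
            np.abs(cd_curve(r) - d).mean()
        )

    def test_exact_cubic_has_zero_loo_error(self):
        r = np.linspace(-1, 1, 10)
        d = 0.1 + 0.5 * r - 0.3 * r**3
        fitter = lambda rt, dt: (
            lambda x: np.polynomial.polynomial.polyval(x, fit_polynomial(rt, dt, 3))
        )
        assert loo_cv_error(r, d, fitter) == pytest.approx(0.0, abs=1e-9)

    def test_matches_explicit_fold_loop(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(-1, 1, 8)
        d = rng.uniform(-1, 1, 8)
        fitter = lambda rt, dt: (
            lambda x: np.polynomial.polynomial.polyval(x, fit_polynomial(rt, dt, 1))
        )
        manual = []
        for i in range(8):
            idx = [j for j in range(8) if j != i]
            coef = fit_polynomial(r[idx], d[idx], 1)
            manual.append(abs(np.polynomial.polynomial.polyval(r[i], coef) - d[i]))
        assert loo_cv_error(r, d, fitter) == pytest.approx(np.mean(manual))


class TestNormalizationAndAic:
    def test_errors_scaled_to_unit_maximum(self):
        assert normalized_errors([1.0, 2.0, 4.0]) == pytest.approx([0.25, 0.5, 1.0])

    def test_groups_normalized_independently(self):
        out = normalized_errors([1.0, 2.0, 3.0, 30.0], groups=[0, 0, 1, 1])
        assert out == pytest.approx([0.5, 1.0, 0.1, 1.0])

    def test_all_zero_group_stays_zero(self):
        assert normalized_errors([0.0, 0.0]) == pytest.approx([0.0, 0.0])

    def test_aic_formula(self):
        assert aic(15, 1.5, 2) == pytest.approx(15 * np.log(0.1) + 4)

    def test_parameter_penalty_is_two_per_parameter(self):
        assert aic(10, 2.0, 4) - aic(10, 2.0, 0) == pytest.approx(8.0)

    def test_zero_rss_warns_and_returns_neg_inf(self):
        with pytest.warns(RuntimeWarning):
            assert aic(10, 0.0, 0) == -np.inf

    def test_aicc_exceeds_aic_for_fitted_models(self):
        assert aicc(15, 1.5, 4) == pytest.approx(aic(15, 1.5, 4) + 40 / 10)
        assert aicc(15, 1.5, 0) == aic(15, 1.5, 0)


class TestResponseModels:
    def test_equal_components_collapse_max_and_average(self):
        C = np.array([0.5, 1.0, -0.2])
        pred_max, _ = response_model_prediction(C, C, "MAX")
        pred_avg, _ = response_model_prediction(C, C, "AVERAGE")
        assert pred_max == pytest.approx(C)
        assert pred_avg == pytest.approx(C)

    @pytest.mark.parametrize("rule", ["MAX", "AVERAGE"])
    def test_generative_rule_has_zero_error_others_positive(self, rule):
        from cortexdecorr import GenerationConfig, generate_study

        cfg = GenerationConfig(
            n_subjects=1, voxels_per_ring_per_area=15, noise_sd=0.0,
            interaction_rule=rule, seed=4,
        )
        table, _ = generate_study(cfg)
        C, S, m = (table[c].to_numpy() for c in ("C", "S_N", "m_C_SN"))
        errors = {
            name: response_model_prediction(C, S, name, m)[1]
            for name in ("MAX", "AVERAGE", "CD")
        }
        assert errors[rule] == pytest.approx(0.0, abs=1e-10)
        for name, err in errors.items():
            if name != rule:
                assert err > 1e-3

    def test_cd_rule_data_have_zero_cd_error(self):
        from cortexdecorr import GenerationConfig, generate_study

        cfg = GenerationConfig(
            n_subjects=1, voxels_per_ring_per_area=15, noise_sd=0.0, d_true="auto",
            seed=4,
        )
        table, _ = generate_study(cfg)
        C, S, m = (table[c].to_numpy() for c in ("C", "S_N", "m_C_SN"))
        _, err = response_model_prediction(C, S, "CD", m)
        assert err == pytest.approx(0.0, abs=1e-9)


class TestCompareModels:
    def _scatter(self, rule, seed, n=15, noise=0.05):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-0.85, 0.85, n)
        if rule == "CD":
            d = cd_curve(r)
        elif rule == "LINEAR_IDENTITY":
            d = r.copy()
        elif rule == "LINFIT":
            d = 0.1 + 0.5 * r
        else:
            d = 0.2 - 0.3 * r - 0.6 * r**2 + 1.2 * r**3
        return r, d + rng.normal(0, noise, n)

    def test_cd_data_prefer_cd_in_majority_of_replicates(self):
        wins = sum(
            compare_models(*self._scatter("CD", 100 + rep)).best().name == "CD"
            for rep in range(20)
        )
        assert wins > 10

    def test_shallow_line_prefers_linfit_over_cd(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(-0.9, 0.9, 15)
        d = 0.5 * r + rng.normal(0, 0.03, 15)
        comp = compare_models(r, d)
        by_name = {m.name: m for m in comp.results}
        assert by_name["LINFIT"].aic < by_name["CD"].aic

    def test_six_points_still_fit_the_cubic(self):
        r = np.array([-0.8, -0.4, -0.1, 0.2, 0.5, 0.9])
        d = cd_curve(r)
        comp = compare_models(r, d)
        assert {m.name for m in comp.results} == {
            "CD", "LINEAR_IDENTITY", "POLY3", "LINFIT"
        }

    def test_pairwise_winners_cover_all_six_pairs(self):
        comp = compare_models(*self._scatter("CD", 1))
        assert len(comp.pairwise_winners) == 6
        total_wins = sum(comp.wins(m.name) for m in comp.results)
        assert total_wins == 6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compare_models([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
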