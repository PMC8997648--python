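"""Second-order fitting, elimination, effect tables, surfaces."""

import math

import numpy as np
import pytest

import ferment_screen as fs
from ferment_screen.rsm import Term, full_term_set, model_matrix_from_codes


def brute_force_ols(X, y):
    """Independent least-squares oracle via the normal equations."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(np.diag(s2 * np.linalg.inv(XtX)))
    return beta, se, beta / se


def random_small_design(rng, n_factors=3, n_runs=30):
    while True:
        codes = rng.integers(-1, 2, size=(n_runs, n_factors))
        mm = model_matrix_from_codes(codes, include_interactions=True)
        if np.linalg.matrix_rank(mm.X) == mm.X.shape[1]:
            return codes, mm


class TestModelMatrix:
    def test_full_second_order_column_count(self, design243):
        mm = fs.build_model_matrix(design243)
        assert mm.X.shape == (243, 1 + 7 + 7 + 21)

    def test_without_interactions(self, design243):
        mm = fs.build_model_matrix(design243, include_interactions=False)
        assert mm.X.shape == (243, 15)

    def test_single_factor_columns(self):
        codes = np.array([[-1], [0], [1]])
        mm = model_matrix_from_codes(codes)
        assert np.array_equal(mm.X, np.array([[1, -1, 1], [1, 0, 0], [1, 1, 1]]))

    def test_interaction_column_is_product_of_codes(self, design243):
        mm = fs.build_model_matrix(design243)
        idx = mm.terms.index(Term("interaction", 1, 4))
        expected = design243.codes[:, 1] * design243.codes[:, 4]
        assert np.array_equal(mm.X[:, idx + 1], expected)

    def test_default_fraction_supports_full_model(self, design243):
        mm = fs.build_model_matrix(design243)
        assert np.linalg.matrix_rank(mm.X) == 36

    def test_column_labels_follow_report_style(self, design243):
        labels = fs.build_model_matrix(design243).column_labels()
        assert labels[1] == "(1) RLT (L)"
        assert labels[2] == "(2) T (L)"
        assert "T (Q)" in labels
        assert "2L by 5L" in labels


class TestFitQuadratic:
    def test_noise_free_quadratic_recovered_exactly(self, design243):
        truth = fs.GroundTruth(
            intercept=0.4,
            coefficients={Term("linear", 1): 0.2, Term("quadratic", 4): -0.1,
                          Term("interaction", 2, 5): 0.05},
            noise_sd=0.0,
        )
        y = fs.make_synthetic_responses(design243, truth)
        mm = fs.build_model_matrix(design243)
        fit = fs.fit_quadratic(mm, y, codes=design243.codes)
        assert fit.intercept == pytest.approx(0.4, abs=1e-10)
        by_term = fit.term_map()
        for term, beta in truth.coefficients.items():
            assert by_term[term].estimate == pytest.approx(beta, abs=1e-10)
        for tc in fit.terms:
            if tc.term not in truth.coefficients:
                assert tc.estimate == pytest.approx(0.0, abs=1e-10)

    def test_constant_response_gives_zero_slopes_and_zero_r2(self, design243):
        mm = fs.build_model_matrix(design243)
        fit = fs.fit_quadratic(mm, np.full(243, 3.14), codes=design243.codes)
        assert all(abs(tc.estimate) < 1e-10 for tc in fit.terms)
        assert fit.r2_adj == 0.0

    def test_matches_normal_equations_oracle(self, design243, rng):
        y = rng.normal(size=243)
        mm = fs.build_model_matrix(design243)
        fit = fs.fit_quadratic(mm, y, codes=design243.codes)
        beta, se, t = brute_force_ols(mm.X, y)
        est = np.array([fit.intercept] + [tc.estimate for tc in fit.terms])
        ses = np.array([fit.intercept_se] + [tc.std_error for tc in fit.terms])
        ts = np.array([fit.intercept / fit.intercept_se]
                      + [tc.standardized_effect for tc in fit.terms])
        np.testing.assert_allclose(est, beta, rtol=1e-8)
        np.testing.assert_allclose(ses, se, rtol=1e-8)
        np.testing.assert_allclose(ts, t, rtol=1e-8)

    def test_standardized_effect_is_estimate_over_se(self, mu_fit):
        for tc in mu_fit.terms:
            assert tc.standardized_effect == pytest.approx(tc.estimate / tc.std_error)

    def test_df_residual_accounting(self, design243, rng):
        y = rng.normal(size=243)
        mm = fs.build_model_matrix(design243)
        fit = fs.fit_quadratic(mm, y, codes=design243.codes)
        assert fit.df_residual == 243 - 36

    def test_r2_adj_invariant_under_response_rescaling(self, design243):
        truth = fs.make_paperlike_truth(seed=5, noise_sd=0.02)
        y = fs.make_synthetic_responses(design243, truth)
        mm = fs.build_model_matrix(design243)
        f1 = fs.fit_quadratic(mm, y, codes=design243.codes)
        f2 = fs.fit_quadratic(mm, 24.0 * y, codes=design243.codes)
        assert f1.r2_adj == pytest.approx(f2.r2_adj, rel=1e-12)

    def test_censored_responses_must_be_excluded(self, design243):
        mm = fs.build_model_matrix(design243)
        y = np.full(243, 1.0)
        y[0] = np.nan
        with pytest.raises(ValueError):
            fs.fit_quadratic(mm, y, codes=design243.codes)

    def test_aliased_columns_dropped_and_reported(self):
        # duplicated factor column makes its quadratic/interactions collinear
        codes = np.array([[-1, -1], [0, 0], [1, 1], [-1, -1], [0, 0], [1, 1],
                          [1, 1], [0, 0], [-1, -1]])
        mm = model_matrix_from_codes(codes)
        rank = np.linalg.matrix_rank(mm.X)
        assert rank < mm.X.shape[1]
        y = np.arange(9.0)
        fit = fs.fit_quadratic(mm, y, codes=codes)
        assert len(fit.aliased) == mm.X.shape[1] - rank
        assert len(fit.terms) == rank - 1


class TestBackwardElimination:
    def test_fully_significant_model_left_unchanged(self, design243):
        truth = fs.GroundTruth(
            intercept=1.0,
            coefficients={Term("linear", 1): 1.0, Term("linear", 4): -1.0},
            noise_sd=0.01, seed=3,
        )
        y = fs.make_synthetic_responses(design243, truth)
        mm = model_matrix_from_codes(design243.codes, include_interactions=False,
                                     factors=design243.factors)
        reduced = fs.backward_eliminate(fs.fit_quadratic(mm, y, codes=design243.codes))
        assert all(tc.p_value <= 0.05 for tc in reduced.terms
                   if tc.term.kind != "linear")
        again = fs.backward_eliminate(reduced)
        assert {tc.term for tc in again.terms} == {tc.term for tc in reduced.terms}
        assert again.eliminated == reduced.eliminated

    def test_recovers_known_sparse_signal(self, design243):
        truth = fs.GroundTruth(
            intercept=0.3,
            coefficients={Term("linear", 1): 0.5, Term("linear", 4): -0.6},
            noise_sd=0.01, seed=11,
        )
        y = fs.make_synthetic_responses(design243, truth)
        mm = fs.build_model_matrix(design243)
        reduced = fs.backward_eliminate(fs.fit_quadratic(mm, y, codes=design243.codes))
        kept = {tc.term for tc in reduced.terms}
        assert Term("linear", 1) in kept and Term("linear", 4) in kept
        # at most a couple of false positives at alpha = 0.05
        assert len(kept) <= 5

    def test_elimination_is_idempotent(self, mu_fit):
        again = fs.backward_eliminate(mu_fit)
        assert [tc.term for tc in again.terms] == [tc.term for tc in mu_fit.terms]
        assert again.eliminated == mu_fit.eliminated

    def test_weak_heredity_keeps_linear_parent(self, design243):
        # strong interaction, no marginal linear effects
        truth = fs.GroundTruth(
            intercept=0.0,
            coefficients={Term("interaction", 2, 5): 1.0},
            noise_sd=0.01, seed=17,
        )
        y = fs.make_synthetic_responses(design243, truth)
        mm = fs.build_model_matrix(design243)
        reduced = fs.backward_eliminate(fs.fit_quadratic(mm, y, codes=design243.codes))
        kept = {tc.term for tc in reduced.terms}
        assert Term("interaction", 2, 5) in kept
        assert Term("linear", 2) in kept and Term("linear", 5) in kept

    def test_can_reduce_to_intercept_only(self, design243):
        y = np.full(243, 2.0)
        mm = fs.build_model_matrix(design243)
        reduced = fs.backward_eliminate(fs.fit_quadratic(mm, y, codes=design243.codes))
        assert reduced.terms == []
        assert reduced.intercept == pytest.approx(2.0)

    def test_removable_term_type_i_rate_near_alpha(self, design243):
        """Pure-noise responses: ~5% of the removable (non-linear) terms
        survive elimination at alpha = 0.05; heredity-protected linear
        terms are excluded from the count because they are retained for
        structural, not statistical, reasons."""
        rng = np.random.default_rng(99)
        mm = fs.build_model_matrix(design243)
        retained = 0
        total = 0
        reps = 120
        for _ in range(reps):
            y = rng.normal(size=243)
            reduced = fs.backward_eliminate(fs.fit_quadratic(mm, y, codes=design243.codes))
            removable = [tc for tc in reduced.terms if tc.term.kind != "linear"]
            retained += len(removable)
            total += 28
        assert retained / total == pytest.approx(0.05, abs=0.02)


class TestEffectsTable:
    def test_layout_row_count_and_bookkeeping(self, mu_fit):
        table = fs.standardized_effects_table({"mu_max": mu_fit})
        assert len(table) == 7 * 2 + 21 + 2
        assert table.index[-2] == "df_residual"
        assert table.index[-1] == "r2_adj"

    def test_eliminated_terms_show_dash(self, mu_fit):
        table = fs.standardized_effects_table({"mu_max": mu_fit})
        for label in mu_fit.eliminated:
            assert table.loc[label, "mu_max"] == "-"

    def test_retained_terms_show_t_statistic(self, mu_fit):
        table = fs.standardized_effects_table({"mu_max": mu_fit})
        for tc in mu_fit.terms:
            cell = table.loc[tc.term.label(mu_fit.factors), "mu_max"]
            assert cell == pytest.approx(tc.standardized_effect, abs=5e-4)


class TestPredictSurface:
    def test_reproduces_fitted_values_at_design_points(self, design243, mu_fit):
        pred = mu_fit.predict(design243.codes)
        grid = fs.predict_surface(mu_fit, "temperature", "smoke", resolution=3)
        corner = grid[(grid["temperature_coded"] == -1.0) & (grid["smoke_coded"] == -1.0)]
        point = np.zeros(7)
        point[1], point[4] = -1, -1
        assert corner["predicted"].iloc[0] == pytest.approx(float(mu_fit.predict(point)[0]))
        assert len(pred) == 243

    def test_pure_quadratic_surface_symmetric_about_center(self, design243):
        truth = fs.GroundTruth(
            intercept=1.0,
            coefficients={Term("quadratic", 1): -0.5, Term("quadratic", 4): -0.25},
            noise_sd=0.0,
        )
        y = fs.make_synthetic_responses(design243, truth)
        mm = fs.build_model_matrix(design243)
        fit = fs.fit_quadratic(mm, y, codes=design243.codes)
        grid = fs.predict_surface(fit, "temperature", "smoke", resolution=5)
        pivot = grid.pivot(index="temperature_coded", columns="smoke_coded",
                           values="predicted").to_numpy()
        np.testing.assert_allclose(pivot, pivot[::-1, :], atol=1e-10)
        np.testing.assert_allclose(pivot, pivot[:, ::-1], atol=1e-10)

    def test_vertex_of_known_bowl_at_minus_b_over_2a(self, design243):
        b_lin, b_quad = 0.3, -0.6
        truth = fs.GroundTruth(
            intercept=0.0,
            coefficients={Term("linear", 1): b_lin, Term("quadratic", 1): b_quad},
            noise_sd=0.0,
        )
        y = fs.make_synthetic_responses(design243, truth)
        mm = fs.build_model_matrix(design243)
        fit = fs.fit_quadratic(mm, y, codes=design243.codes)
        grid = fs.predict_surface(fit, "temperature", "smoke", resolution=201)
        best = grid.loc[grid["predicted"].idxmax()]
        assert best["temperature_coded"] == pytest.approx(-b_lin / (2 * b_quad), abs=0.01)

    def test_negative_predictions_floored_in_overlay(self, design243):
        truth = fs.GroundTruth(intercept=-1.0, coefficients={}, noise_sd=0.0)
        y = fs.make_synthetic_responses(design243, truth)
        mm = fs.build_model_matrix(design243)
        fit = fs.fit_quadratic(mm, y, codes=design243.codes)
        grid = fs.predict_surface(fit, "temperature", "smoke", resolution=3)
        assert (grid["predicted"] < 0).all()
        assert (grid["predicted_nonneg"] == 0).all()

    def test_unknown_factor_rejected(self, mu_fit):
        with pytest.raises(KeyError):
            fs.predict_surface(mu_fit, "temperature", "pressure")
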