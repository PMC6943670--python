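"""PLS model/results behaviour: fitting, LOO selection, contours."""

import numpy as np
import pytest

from fieldqsar.datasets import run_recovery_experiment
from fieldqsar.model import FieldPLS


class TestFit:
    def test_exact_linear_single_component(self, rng):
        """With orthogonal columns the first latent direction is the active
        column itself, so one component fits an exactly linear y."""
        A = rng.normal(size=(10, 4))
        X, _ = np.linalg.qr(A - A.mean(axis=0))  # orthonormal, zero-mean columns
        y = 2.5 * X[:, 1] + 1.0
        res = FieldPLS(y, X).fit(n_components=1)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.see == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(res.fittedvalues, y, atol=1e-8)

    def test_constant_response_convention(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.full(8, 5.5)
        res = FieldPLS(y, X).fit(n_components=1)
        assert res.r2 == 0.0
        np.testing.assert_allclose(res.coefficients, 0.0, atol=1e-8)

    def test_full_rank_pls_equals_least_squares(self, rng):
        """With components = rank, PLS reproduces the OLS predictions."""
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        res = FieldPLS(y, X).fit(n_components=5)
        # brute-force least squares with intercept
        A = np.column_stack([np.ones(8), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(res.fittedvalues, A @ beta, atol=1e-8)

    def test_excess_components_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        with pytest.raises(ValueError, match="rank"):
            FieldPLS(y, X).fit(n_components=5)

    def test_statistics_formulas(self, rng):
        X = rng.normal(size=(20, 6))
        y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(scale=0.3, size=20)
        c = 2
        res = FieldPLS(y, X).fit(n_components=c)
        rss = float(np.sum((y - res.fittedvalues) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        n = 20
        assert res.r2 == pytest.approx(1 - rss / tss, rel=1e-12)
        assert res.see == pytest.approx(np.sqrt(rss / (n - c - 1)), rel=1e-12)
        assert res.f_value == pytest.approx(
            (res.r2 / c) / ((1 - res.r2) / (n - c - 1)), rel=1e-12
        )


class TestLoo:
    def test_noiseless_collinear_data_q2_near_one(self, rng):
        X = rng.normal(size=(12, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 3.0
        cv = FieldPLS(y, X).loo_cross_validate(max_components=3)
        assert cv.q2 > 0.999

    def test_pure_noise_q2_low(self, rng):
        """y independent of X: LOO q² hovers at or below zero (20 repeats)."""
        q2s = []
        for _ in range(20):
            X = rng.normal(size=(14, 5))
            y = rng.normal(size=14)
            q2s.append(FieldPLS(y, X).loo_cross_validate(max_components=3).q2)
        assert np.mean(q2s) < 0.1
        # best-of-three component selection lets a rare draw creep up, but
        # the bulk of the distribution must stay unconvincing
        assert np.mean(np.asarray(q2s) < 0.3) >= 0.75

    def test_loo_equals_explicit_refit_oracle(self, rng):
        """Each LOO prediction equals a from-scratch refit without compound i."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        ncomp = 2
        cv = FieldPLS(y, X).loo_cross_validate(max_components=ncomp)
        for i in range(6):
            keep = np.ones(6, dtype=bool)
            keep[i] = False
            oracle = PLSRegression(n_components=ncomp, scale=False).fit(X[keep], y[keep])
            expected = float(oracle.predict(X[i][None, :]).ravel()[0])
            assert cv.per_fold_predictions[i] == pytest.approx(expected, abs=1e-8)

    def test_onc_is_smallest_count_achieving_best_q2(self, rng):
        X = rng.normal(size=(10, 3))
        y = X[:, 0] + 0.5 * X[:, 1]
        cv = FieldPLS(y, X).loo_cross_validate(max_components=3)
        best = max(cv.q2_by_components.values())
        smallest_best = min(c for c, v in cv.q2_by_components.items() if v == best)
        assert cv.onc == smallest_best
        assert cv.q2 == best

    def test_max_components_truncated_with_warning(self, rng):
        X = rng.normal(size=(5, 8))
        y = rng.normal(size=5)
        with pytest.warns(UserWarning, match="truncated"):
            FieldPLS(y, X).loo_cross_validate(max_components=10)


class TestPredict:
    def test_training_set_reproduces_fitted(self, rng):
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        res = FieldPLS(y, X).fit(n_components=2)
        np.testing.assert_allclose(res.predict(X), res.fittedvalues, atol=1e-12)

    def test_row_order_invariance_and_duplication(self, rng):
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        res = FieldPLS(y, X).fit(n_components=2)
        Xn = rng.normal(size=(5, 4))
        p = res.predict(Xn)
        perm = rng.permutation(5)
        np.testing.assert_allclose(res.predict(Xn[perm]), p[perm], atol=1e-12)
        np.testing.assert_allclose(
            res.predict(np.vstack([Xn[0], Xn[0]])), [p[0], p[0]], atol=1e-12
        )

    def test_hand_computed_linear_model(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, 1.0]])
        y = 2 * X[:, 0] + 3 * X[:, 1] + 1
        res = FieldPLS(y, X).fit(n_components=2)
        x_new = np.array([[2.0, -1.0]])
        assert res.predict(x_new)[0] == pytest.approx(2 * 2 + 3 * (-1) + 1, abs=1e-8)

    def test_column_mismatch_rejected(self, rng):
        X = rng.normal(size=(8, 4))
        res = FieldPLS(rng.normal(size=8), X).fit(n_components=1)
        with pytest.raises(ValueError, match="column mismatch"):
            res.predict(rng.normal(size=(2, 5)))


class TestInvariances:
    def test_statistics_invariant_to_row_and_column_permutation(self, rng):
        X = rng.normal(size=(12, 6))
        y = X[:, 0] + rng.normal(scale=0.2, size=12)
        res = FieldPLS(y, X).fit(n_components=2)
        cv = FieldPLS(y, X).loo_cross_validate(max_components=2)
        rperm = rng.permutation(12)
        cperm = rng.permutation(6)
        res_p = FieldPLS(y[rperm], X[rperm][:, cperm]).fit(n_components=2)
        cv_p = FieldPLS(y[rperm], X[rperm][:, cperm]).loo_cross_validate(max_components=2)
        assert res_p.r2 == pytest.approx(res.r2, abs=1e-9)
        assert cv_p.q2 == pytest.approx(cv.q2, abs=1e-9)

    def test_duplicated_column_leaves_predictions_unchanged(self, rng):
        """At full rank a perfectly collinear extra column spans the same
        space, so the fitted predictions cannot move."""
        X = rng.normal(size=(10, 4))
        y = X[:, 0] - X[:, 2] + rng.normal(scale=0.1, size=10)
        res = FieldPLS(y, X).fit(n_components=4)
        X_dup = np.column_stack([X, X[:, 1]])
        res_dup = FieldPLS(y, X_dup).fit(n_components=4)
        np.testing.assert_allclose(res_dup.fittedvalues, res.fittedvalues, atol=1e-6)

    def test_q2_not_above_r2_on_synthetic_suite(self):
        """Cross-validated predictivity is pessimistic relative to the fit."""
        for seed in (3, 11):
            results, _, _, metrics = run_recovery_experiment(seed, n_compounds=20)
            assert metrics["q2"] <= metrics["r2"] + 1e-9


class TestContours:
    def test_toy_ranking_matches_sort_oracle(self, rng):
        """Favoured/disfavoured membership equals a brute-force ranking on
        the cumulative |StDev*Coeff| scale."""
        results, block, truth, _ = run_recovery_experiment(9, n_compounds=16, n_regions=2)
        contours = results.stdev_coeff_contours(0.8, 0.2)
        values = results.coefficients * results.model.exog.std(axis=0)
        labels = block.kind_labels()[block.column_mask]
        k = labels[0]
        v = values[labels == k]
        order = np.argsort(v, kind="stable")
        cum = np.cumsum(np.abs(v[order])) / np.abs(v).sum()
        fav_oracle = np.sort(np.where(labels == k)[0][order[(cum > 0.8) & (v[order] > 0)]])
        dis_oracle = np.sort(np.where(labels == k)[0][order[(cum <= 0.2) & (v[order] < 0)]])
        np.testing.assert_array_equal(contours.favored_points[k], fav_oracle)
        np.testing.assert_array_equal(contours.disfavored_points[k], dis_oracle)
        assert not set(contours.favored_points[k]) & set(contours.disfavored_points[k])

    def test_single_positive_outlier_always_favored(self, rng):
        results, block, truth, _ = run_recovery_experiment(9, n_compounds=16, n_regions=2)
        # overwrite the fitted coefficients with a single positive outlier
        coef = np.zeros_like(results.coefficients)
        coef[7] = 4.0
        coef[3] = -0.1
        results._pls.coef_ = coef[None, :]
        contours = results.stdev_coeff_contours(0.95, 0.05)
        k = results.model.block.kind_labels()[results.model.block.column_mask][0]
        assert 7 in contours.favored_points[k]

    def test_all_zero_coefficients_empty_sets(self, rng):
        results, block, truth, _ = run_recovery_experiment(9, n_compounds=16, n_regions=2)
        results._pls.coef_ = np.zeros_like(results._pls.coef_)
        with pytest.warns(UserWarning, match="all-zero"):
            contours = results.stdev_coeff_contours()
        for k in contours.favored_points:
            assert len(contours.favored_points[k]) == 0
            assert len(contours.disfavored_points[k]) == 0


def test_field_contributions_sum_to_one(rng):
    results, block, truth, _ = run_recovery_experiment(7, n_compounds=16, n_regions=2)
    contrib = results.field_contributions()
    assert sum(contrib.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(v >= 0 for v in contrib.values())


def test_summary_mentions_key_statistics(rng):
    results, *_ = run_recovery_experiment(7, n_compounds=16, n_regions=2)
    text = results.summary()
    for token in ("q2", "r2", "SEE", "field contributions"):
        assert token in text
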