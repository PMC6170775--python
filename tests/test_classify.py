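"""Classifier bench: Cohen's Kappa, leave-group-out CV, tuning and
fossil posteriors."""

import numpy as np
import pytest

from taloco.classify import (
    MODEL_FAMILIES,
    CvSpec,
    cohens_kappa,
    fit_final_model,
    lgocv_evaluate,
    predict_fossils,
    tune_rf,
    tune_svm_cost,
)


def blobs(rng, n_per=20, spread=0.3, sep=4.0):
    """Three well-separated Gaussian blobs in 4-D."""
    centers = np.array(
        [[0, 0, 0, 0], [sep, 0, 0, 0], [0, sep, 0, 0]], dtype=float
    )
    x = np.vstack(
        [c + rng.normal(0, spread, size=(n_per, 4)) for c in centers]
    )
    y = np.repeat(["alpha", "beta", "gamma"], n_per)
    return x, y


class TestCohensKappa:
    @pytest.mark.parametrize(
        "confusion, expected",
        [
            (np.diag([5, 5]), 1.0),
            (np.array([[2, 2], [2, 2]]), 0.0),
            (np.array([[0, 5], [5, 0]]), -1.0),
        ],
    )
    def test_worked_examples(self, confusion, expected):
        assert cohens_kappa(confusion) == pytest.approx(expected)

    def test_degenerate_marginals_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert cohens_kappa(np.array([[4, 0], [0, 0]])) == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(np.zeros((2, 2)))

    def test_matches_sklearn_on_random_confusions(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            y_true = rng.integers(0, 3, size=50)
            y_pred = rng.integers(0, 3, size=50)
            conf = np.zeros((3, 3))
            for t, p in zip(y_true, y_pred):
                conf[t, p] += 1
            assert cohens_kappa(conf) == pytest.approx(
                cohen_kappa_score(y_true, y_pred)
            )


class TestLgocv:
    def test_separable_blobs_high_accuracy_every_family(self, rng):
        x, y = blobs(rng)
        cv = CvSpec(repeats=30, seed=4)
        for name in MODEL_FAMILIES:
            rep = lgocv_evaluate(x, y, name, cv=cv)
            assert rep.accuracy_mean >= 0.95, name

    def test_permuted_labels_give_chance_kappa(self, rng):
        x, y = blobs(rng)
        y_perm = rng.permutation(y)
        rep = lgocv_evaluate(x, y_perm, "LDA", cv=CvSpec(repeats=200, seed=1))
        assert abs(rep.kappa_mean) <= 0.1

    def test_deterministic_given_seed(self, rng):
        x, y = blobs(rng, n_per=10)
        cv = CvSpec(repeats=15, seed=9)
        a = lgocv_evaluate(x, y, "RF", cv=cv)
        b = lgocv_evaluate(x, y, "RF", cv=cv)
        assert np.array_equal(a.per_repeat_metrics, b.per_repeat_metrics)
        assert a.best_params == b.best_params

    def test_singleton_class_rejected(self, rng):
        x = rng.normal(size=(5, 2))
        y = np.array(["a", "a", "b", "b", "c"])
        with pytest.raises(ValueError):
            lgocv_evaluate(x, y, "LDA", cv=CvSpec(repeats=3, seed=0))

    def test_ci_bounds_ordered_and_metrics_in_range(self, rng):
        x, y = blobs(rng, n_per=10, spread=2.0)
        rep = lgocv_evaluate(x, y, "KNN", cv=CvSpec(repeats=25, seed=2))
        assert rep.accuracy_ci95[0] <= rep.accuracy_mean <= rep.accuracy_ci95[1]
        assert 0.0 <= rep.accuracy_mean <= 1.0
        assert -1.0 <= rep.kappa_mean <= 1.0


class TestTuning:
    def test_svm_cost_ladder_report_and_determinism(self, rng):
        x, y = blobs(rng, n_per=10)
        cv = CvSpec(repeats=10, seed=3)
        best1, rep1 = tune_svm_cost(x, y, cv=cv)
        best2, rep2 = tune_svm_cost(x, y, cv=cv)
        assert len(rep1.grid_results) == 7
        assert best1 == best2
        accs = [r["accuracy_mean"] for r in rep1.grid_results]
        assert max(accs) - min(accs) < 0.05  # separable data: flat in cost

    def test_svm_rejects_nonpositive_costs(self, rng):
        x, y = blobs(rng, n_per=5)
        with pytest.raises(ValueError):
            tune_svm_cost(x, y, costs=(0.0, 1.0), cv=CvSpec(repeats=2, seed=0))

    def test_rf_grid_size_and_mtry_bound(self, rng):
        x, y = blobs(rng, n_per=8)
        cv = CvSpec(repeats=3, seed=0)
        best, rep = tune_rf(x, y, n_trees=(50, 100), m_try=(2, 3), cv=cv)
        assert len(rep.grid_results) == 4
        with pytest.raises(ValueError):
            tune_rf(x, y, n_trees=(50,), m_try=(2, 99), cv=cv)


class TestFossilPrediction:
    def test_centroid_fossil_recovers_its_class(self, rng):
        x, y = blobs(rng)
        centroid = x[y == "beta"].mean(axis=0, keepdims=True)
        for family in ("RF", "LDA", "NB"):
            model = fit_final_model(x, y, family, {} if family != "RF" else {"n_estimators": 100}, seed=0)
            pred = predict_fossils(model, centroid, ["f1"])[0]
            assert pred.predicted_class == "beta"
            assert pred.posterior["beta"] > 0.9, family
        # sigmoid-calibrated SVM posteriors saturate below the native
        # families on small samples but must still be decisive
        svm = fit_final_model(x, y, "SVM_linear", {"C": 2.0}, seed=0)
        pred = predict_fossils(svm, centroid, ["f1"])[0]
        assert pred.predicted_class == "beta"
        assert pred.posterior["beta"] > 0.6

    def test_posteriors_sum_to_one(self, rng):
        x, y = blobs(rng)
        model = fit_final_model(x, y, "NB", {}, seed=0)
        preds = predict_fossils(model, rng.normal(size=(5, 4)) * 3, None)
        for p in preds:
            assert sum(p.posterior.values()) == pytest.approx(1.0, abs=1e-9)

    def test_equidistant_point_near_uniform_posterior(self, rng):
        # symmetric equilateral class layout; query at the barycentre
        angles = np.array([0, 2 * np.pi / 3, 4 * np.pi / 3])
        centers = np.column_stack([np.cos(angles), np.sin(angles)]) * 5
        x = np.vstack([c + rng.normal(0, 3.0, size=(200, 2)) for c in centers])
        y = np.repeat(["a", "b", "c"], 200)
        model = fit_final_model(x, y, "LDA", {}, seed=0)
        post = predict_fossils(model, centers.mean(axis=0, keepdims=True))[0].posterior
        assert max(post.values()) - min(post.values()) < 0.15

    def test_feature_count_mismatch_rejected(self, rng):
        x, y = blobs(rng, n_per=5)
        model = fit_final_model(x, y, "LDA", {}, seed=0)
        with pytest.raises(ValueError):
            predict_fossils(model, rng.normal(size=(2, 3)))
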