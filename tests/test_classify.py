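"""LOOCV protocol, metrics, kappa, permutation test, feature weights."""

import numpy as np
import pytest
from scipy import stats as sps

from neurodc.classify import (
    ModelSpec,
    cohen_kappa,
    compute_metrics,
    feature_weights,
    fit_full_model,
    loocv_predict,
    permutation_test,
    pooled_auc,
    run_all_models,
)


def separated_clouds(n1=10, n2=10, gap=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.standard_normal((n1, 3)) + gap / 2, rng.standard_normal((n2, 3)) - gap / 2]
    )
    y = np.r_[np.ones(n1, int), np.zeros(n2, int)]
    return X, y


def mannwhitney_auc_oracle(y, scores):
    """AUC from the rank-sum construction, ties counted one half."""
    ranks = sps.rankdata(scores)
    n_pos = int(np.sum(y == 1))
    n_neg = len(y) - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestLOOCV:
    @pytest.mark.parametrize("model", ["svm_linear", "random_forest", "logistic_regression"])
    def test_separable_clouds_classified_perfectly(self, model):
        X, y = separated_clouds(6, 6)
        grid = (
            {"n_estimators": [100], "max_depth": [None, 3]}
            if model == "random_forest"
            else {}
        )
        spec = ModelSpec(model=model, hyperparameter_grid=grid, seed=0)
        hard, score = loocv_predict(spec, X, y)
        assert np.array_equal(hard, y)
        assert len(score) == len(y)

    def test_every_subject_predicted_out_of_fold(self):
        # a 1-NN-like memorising check: duplicate rows with opposite labels
        # can only be classified at chance if the held-out row is unseen
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 2))
        y = np.r_[np.ones(6, int), np.zeros(6, int)]
        spec = ModelSpec(model="svm_linear", hyperparameter_grid={"C": [1.0]}, seed=0)
        hard, score = loocv_predict(spec, X, y)
        assert hard.shape == (12,)
        assert np.all(np.isfinite(score))

    def test_null_accuracy_compatible_with_chance(self):
        accs = []
        for seed in range(50):
            rng = np.random.default_rng(2000 + seed)
            X = rng.standard_normal((30, 8))
            y = np.r_[np.ones(15, int), np.zeros(15, int)]
            spec = ModelSpec(model="svm_linear", hyperparameter_grid={"C": [1.0]}, seed=seed)
            hard, _ = loocv_predict(spec, X, y)
            accs.append(float(np.mean(hard == y)))
        accs = np.array(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) <= 3 * se

    def test_too_few_subjects_rejected(self):
        X, y = separated_clouds(2, 1)
        with pytest.raises(ValueError, match="at least 4"):
            loocv_predict(ModelSpec(model="svm_linear"), X, y)


class TestMetrics:
    def test_reconstructed_confusion_ratios(self):
        # confusion reconstructed from a published 51/48 cohort:
        # sens 42/51, spec 29/48, acc 71/99
        y = np.r_[np.ones(51, int), np.zeros(48, int)]
        hard = np.r_[np.ones(42, int), np.zeros(9, int), np.ones(19, int), np.zeros(29, int)]
        scores = hard + np.linspace(0, 0.1, 99)
        rep = compute_metrics(y, hard, scores)
        assert rep.confusion == (42, 9, 19, 29)
        assert rep.sensitivity == pytest.approx(0.8235, abs=1e-4)
        assert rep.specificity == pytest.approx(0.6042, abs=1e-4)
        assert rep.accuracy == pytest.approx(0.7172, abs=1e-4)

    def test_perfect_ranking_gives_auc_one(self):
        y = np.array([1, 1, 0, 0])
        assert pooled_auc(y, np.array([4.0, 3.0, 2.0, 1.0])) == 1.0

    def test_all_tied_scores_give_auc_half(self):
        y = np.array([1, 1, 0, 0])
        assert pooled_auc(y, np.zeros(4)) == 0.5

    def test_auc_equals_mannwhitney_construction(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.standard_normal(n), 1)  # force ties
            assert pooled_auc(y, scores) == pytest.approx(
                mannwhitney_auc_oracle(y, scores), abs=1e-12
            )

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics(np.ones(4, int), np.ones(4, int), np.ones(4))


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa((10, 0, 0, 10)) == 1.0

    def test_constant_prediction_on_balanced_truth_is_zero(self):
        assert cohen_kappa((10, 0, 10, 0)) == 0.0

    def test_closed_form_on_reconstructed_confusion(self):
        assert cohen_kappa((43, 8, 20, 28)) == pytest.approx(0.429, abs=1e-3)

    def test_agrees_with_sklearn_on_label_vectors(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(23)
        for _ in range(20):
            y = (rng.random(30) < 0.5).astype(int)
            pred = (rng.random(30) < 0.5).astype(int)
            tp = int(np.sum((y == 1) & (pred == 1)))
            fn = int(np.sum((y == 1) & (pred == 0)))
            fp = int(np.sum((y == 0) & (pred == 1)))
            tn = int(np.sum((y == 0) & (pred == 0)))
            if (tp + fn) in (0, 30) or (tp + fp) in (0, 30):
                continue
            assert cohen_kappa((tp, fn, fp, tn)) == pytest.approx(
                cohen_kappa_score(y, pred), abs=1e-12
            )


class TestPermutationTest:
    def test_add_one_rule_floor_on_separable_data(self):
        X, y = separated_clouds(6, 6, gap=12.0)
        spec = ModelSpec(model="svm_linear", hyperparameter_grid={"C": [1.0]}, seed=0)
        p, summary = permutation_test(spec, X, y, n_permutations=19, seed=3)
        assert p == pytest.approx(1 / 20)
        assert summary["observed"] == 1.0

    def test_same_seed_reproduces_p(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 3))
        y = np.r_[np.ones(6, int), np.zeros(6, int)]
        spec = ModelSpec(model="logistic_regression", hyperparameter_grid={"C": [1.0]}, seed=0)
        p1, _ = permutation_test(spec, X, y, n_permutations=29, seed=11)
        p2, _ = permutation_test(spec, X, y, n_permutations=29, seed=11)
        assert p1 == p2

    def test_null_p_values_are_valid(self):
        # P(p <= alpha) must not exceed alpha by more than sampling noise
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(31000 + seed)
            X = rng.standard_normal((10, 3))
            y = np.r_[np.ones(5, int), np.zeros(5, int)]
            spec = ModelSpec(
                model="svm_linear", hyperparameter_grid={"C": [1.0]}, seed=seed
            )
            p, _ = permutation_test(spec, X, y, n_permutations=99, seed=seed)
            pvals.append(p)
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1):
            assert np.mean(pvals <= alpha) <= alpha + 0.03


class TestFeatureWeights:
    def test_separating_feature_dominates(self):
        rng = np.random.default_rng(6)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        X = rng.standard_normal((40, 4))
        X[:, 2] += 4.0 * y
        spec = ModelSpec(model="svm_linear", hyperparameter_grid={"C": [1.0]}, seed=0)
        fitted, _ = fit_full_model(spec, X, y)
        w = feature_weights(spec, fitted, list("abcd"))
        assert max(w, key=lambda k: abs(w[k])) == "c"

    def test_rf_importances_normalized_nonnegative(self):
        X, y = separated_clouds(8, 8, gap=2.0, seed=9)
        spec = ModelSpec(
            model="random_forest",
            hyperparameter_grid={"n_estimators": [100], "max_depth": [None]},
            seed=0,
        )
        fitted, _ = fit_full_model(spec, X, y)
        w = np.array(list(feature_weights(spec, fitted, list("abc")).values()))
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_shares_logistic_weight(self):
        rng = np.random.default_rng(15)
        y = np.r_[np.ones(40, int), np.zeros(40, int)]
        x = rng.standard_normal(80) + 1.2 * y
        noise = rng.standard_normal(80)
        spec = ModelSpec(model="logistic_regression", hyperparameter_grid={"C": [1.0]}, seed=0)
        single, _ = fit_full_model(spec, np.column_stack([x, noise]), y)
        w_single = feature_weights(spec, single, ["x", "n"])["x"]
        dup, _ = fit_full_model(spec, np.column_stack([x, x, noise]), y)
        w_dup = feature_weights(spec, dup, ["x1", "x2", "n"])
        assert abs(w_dup["x1"]) + abs(w_dup["x2"]) == pytest.approx(abs(w_single), rel=0.15)


class TestRunAllModels:
    def test_comparison_table_shape_and_determinism(self):
        X, y = separated_clouds(8, 8, gap=3.0, seed=12)
        grids = {"random_forest": {"n_estimators": [100], "max_depth": [None]}}
        _, c1 = run_all_models(X, y, list("abc"), seed=5, grids=grids)
        _, c2 = run_all_models(X, y, list("abc"), seed=5, grids=grids)
        assert list(c1.index) == ["SVM", "RF", "LR"]
        assert list(c1.columns) == ["AUC", "Accuracy", "Sensitivity", "Specificity", "Kappa"]
        assert c1.equals(c2)

    def test_strong_separation_yields_high_auc_everywhere(self):
        X, y = separated_clouds(10, 10, gap=6.0, seed=2)
        grids = {"random_forest": {"n_estimators": [100], "max_depth": [None]}}
        reports, comparison = run_all_models(X, y, list("abc"), seed=1, grids=grids)
        assert (comparison["AUC"] >= 0.95).all()

    def test_accuracy_identity_holds_in_reports(self):
        rng = np.random.default_rng(44)
        X = rng.standard_normal((20, 3))
        y = np.r_[np.ones(11, int), np.zeros(9, int)]
        grids = {
            "svm_linear": {"C": [1.0]},
            "logistic_regression": {"C": [1.0]},
            "random_forest": {"n_estimators": [100], "max_depth": [None]},
        }
        reports, _ = run_all_models(X, y, list("abc"), seed=3, grids=grids)
        for rep in reports.values():
            tp, fn, fp, tn = rep.confusion
            n_pos, n_neg = tp + fn, fp + tn
            assert rep.accuracy == pytest.approx(
                (rep.sensitivity * n_pos + rep.specificity * n_neg) / (n_pos + n_neg)
            )


class TestSelectionLeakage:
    def test_preselected_features_inflate_null_auc(self):
        """Selecting features on the full cohort before LOOCV (the
        single-shot protocol) is optimistically biased on null data
        relative to selection nested inside each fold."""
        from neurodc.select import lasso_select

        alphas = np.logspace(-3, 1, 8)

        def top_columns(X, y, seed):
            res = lasso_select(
                X, y, [str(i) for i in range(X.shape[1])],
                alpha_grid=alphas, n_folds=4, seed=seed,
            )
            cols = [int(k) for k in res.nonzero_features]
            return cols or list(range(X.shape[1]))

        spec_grid = {"C": [1.0]}
        biased, nested = [], []
        for rep in range(30):
            rng = np.random.default_rng(7000 + rep)
            X = rng.standard_normal((24, 12))
            y = np.r_[np.ones(12, int), np.zeros(12, int)]
            spec = ModelSpec(model="logistic_regression", hyperparameter_grid=spec_grid, seed=rep)

            cols = top_columns(X, y, rep)
            _, s_biased = loocv_predict(spec, X[:, cols], y)
            biased.append(pooled_auc(y, s_biased))

            scores = np.empty(len(y))
            for i in range(len(y)):
                train = np.delete(np.arange(len(y)), i)
                cols_i = top_columns(X[train], y[train], rep)
                fitted, _ = fit_full_model(spec, X[np.ix_(train, cols_i)], y[train])
                from neurodc.classify import _score

                scores[i] = _score(spec, fitted, X[i : i + 1, cols_i])[0]
            nested.append(pooled_auc(y, scores))
        assert np.mean(biased) - np.mean(nested) > 0
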