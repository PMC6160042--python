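import numpy as np
import pytest

from faimspipe.metrics import auc, bootstrap_ci
from faimspipe.models import (
    MODEL_KINDS,
    CVSpec,
    ModelSpec,
    PredictionSet,
    _make_estimator,
    cross_validate,
    draw_folds,
    fit_predict,
    probability_ensemble,
)
from faimspipe.selection import SelectionSpec
from .conftest import table_from


def separable_problem(n=30, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
    X = rng.normal(size=(n, 3)) * 0.1
    X[:, 0] += (y == "case").astype(float)  # feature tracks the label
    return X, y


class TestFitPredict:
    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_perfectly_separable_toy(self, kind):
        X, y = separable_problem(seed=1)
        Xt, yt = separable_problem(seed=2)
        probs = fit_predict(ModelSpec(kind), X, y, Xt, seed=0)
        assert auc(list(yt), probs) == 1.0

    def test_random_forest_has_500_trees(self):
        est = _make_estimator(ModelSpec("random_forest"), seed=0)
        assert est.n_estimators == 500

    def test_svm_kernel_parameters(self):
        est = _make_estimator(ModelSpec("svm_rbf"), seed=0)
        assert est.gamma == 0.05 and est.C == 5.0 and est.probability

    def test_gp_kernel_matches_sigma(self):
        est = _make_estimator(ModelSpec("gaussian_process"), seed=0)
        assert est.kernel.length_scale == pytest.approx(1 / np.sqrt(2 * 0.05))
        assert est.optimizer is None

    def test_neural_net_single_hidden_unit(self):
        est = _make_estimator(ModelSpec("neural_net"), seed=0)
        assert est.hidden_layer_sizes == (1,) and est.activation == "logistic"

    def test_single_class_training_rejected(self):
        X, _ = separable_problem()
        with pytest.raises(ValueError):
            fit_predict(ModelSpec("random_forest"), X, ["case"] * X.shape[0], X)

    def test_non_finite_features_rejected(self):
        X, y = separable_problem()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_predict(ModelSpec("svm_rbf"), X, y, X)


class TestFolds:
    def test_115_samples_max_training_104(self):
        labels = ["case"] * 72 + ["control"] * 43
        assignment = draw_folds(labels, CVSpec(k=10, seed=0))
        train_sizes = {int((assignment != f).sum()) for f in range(10)}
        assert train_sizes == {103, 104}

    def test_partition_property(self):
        labels = ["case"] * 20 + ["control"] * 20
        assignment = draw_folds(labels, CVSpec(k=10, seed=1))
        assert assignment.size == 40
        assert set(assignment) == set(range(10))

    def test_stratified_within_one_sample(self):
        labels = ["case"] * 24 + ["control"] * 36
        assignment = draw_folds(labels, CVSpec(k=10, seed=2))
        mask = np.array([l == "case" for l in labels])
        global_frac = mask.mean()
        for f in range(10):
            fold_mask = assignment == f
            n_fold = fold_mask.sum()
            expected = global_frac * n_fold
            assert abs(mask[fold_mask].sum() - expected) <= 1.0

    def test_deterministic_under_seed(self):
        labels = ["case"] * 15 + ["control"] * 15
        a = draw_folds(labels, CVSpec(k=5, seed=7))
        b = draw_folds(labels, CVSpec(k=5, seed=7))
        np.testing.assert_array_equal(a, b)


class TestCrossValidate:
    def _problem(self, n=40, m=30, seed=3):
        rng = np.random.default_rng(seed)
        labels = ["case"] * (n // 2) + ["control"] * (n // 2)
        X = rng.normal(size=(n, m))
        X[:, 4] += np.where(np.array(labels) == "case", 3.0, 0.0)
        return table_from(X), labels

    def test_every_sample_predicted_once(self):
        table, labels = self._problem()
        res = cross_validate(
            table, labels, [ModelSpec("sparse_logistic")], SelectionSpec(), CVSpec(k=5, seed=0)
        )
        probs = res.predictions["sparse_logistic"].probabilities
        assert probs.shape == (40,) and np.isfinite(probs).all()

    def test_identical_seed_identical_predictions(self):
        table, labels = self._problem()
        kw = dict(selection=SelectionSpec(), cv=CVSpec(k=5, seed=11))
        r1 = cross_validate(table, labels, [ModelSpec("sparse_logistic")], **kw)
        r2 = cross_validate(table, labels, [ModelSpec("sparse_logistic")], **kw)
        np.testing.assert_array_equal(
            r1.predictions["sparse_logistic"].probabilities,
            r2.predictions["sparse_logistic"].probabilities,
        )
        np.testing.assert_array_equal(r1.fold_assignment, r2.fold_assignment)

    def test_informative_feature_selected_and_auc_high(self):
        table, labels = self._problem()
        res = cross_validate(
            table, labels, [ModelSpec("sparse_logistic")], SelectionSpec(), CVSpec(k=5, seed=1)
        )
        hits = sum("f4" in feats for feats in res.selected_features)
        assert hits >= 4
        assert auc(labels, res.predictions["sparse_logistic"].probabilities) > 0.85

    def test_no_leakage_on_permuted_labels(self):
        # with permuted labels the bootstrap CI should usually cover 0.5
        rng = np.random.default_rng(4)
        table, labels = self._problem(seed=5)
        covered = 0
        reps = 6
        for _ in range(reps):
            perm = list(rng.permutation(labels))
            res = cross_validate(
                table, perm, [ModelSpec("sparse_logistic")], SelectionSpec(), CVSpec(k=5, seed=2)
            )
            lo, hi = bootstrap_ci(
                perm, res.predictions["sparse_logistic"].probabilities, n_boot=500, seed=6
            )
            covered += lo <= 0.5 <= hi
        assert covered >= reps - 1

    def test_pca_mode_runs(self):
        table, labels = self._problem()
        res = cross_validate(
            table,
            labels,
            [ModelSpec("sparse_logistic")],
            SelectionSpec(use_pca=True),
            CVSpec(k=5, seed=3),
        )
        assert np.isfinite(res.predictions["sparse_logistic"].probabilities).all()

    def test_wrapper_mode_runs(self):
        table, labels = self._problem(m=12)
        res = cross_validate(
            table,
            labels,
            [ModelSpec("sparse_logistic")],
            SelectionSpec(method="wrapper", nkeep=6),
            CVSpec(k=4, seed=4),
        )
        assert np.isfinite(res.predictions["sparse_logistic"].probabilities).all()


class TestProbabilityEnsemble:
    def _pset(self, probs, model="svm_rbf"):
        n = len(probs)
        return PredictionSet([f"s{i}" for i in range(n)], np.array(probs), model, np.zeros(n))

    def test_identical_sets_unchanged(self):
        p = self._pset([0.2, 0.7, 0.4])
        out = probability_ensemble([p, p, p])
        np.testing.assert_allclose(out.probabilities, p.probabilities)

    def test_mean_of_three(self):
        out = probability_ensemble(
            [self._pset([0.2]), self._pset([0.4]), self._pset([0.6])]
        )
        assert out.probabilities[0] == pytest.approx(0.4)

    def test_sample_order_preserved(self):
        p = self._pset([0.1, 0.9])
        assert probability_ensemble([p, p]).sample_ids == ["s0", "s1"]

    def test_mismatched_models_rejected(self):
        with pytest.raises(ValueError, match="model"):
            probability_ensemble([self._pset([0.5]), self._pset([0.5], model="neural_net")])

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            PredictionSet(["a"], np.array([1.2]), "svm_rbf", np.zeros(1))
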