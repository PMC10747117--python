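"""Classifier suite, metric arithmetic and model selection."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from eegreduce.modeling import (
    CLASSIFIER_IDS,
    evaluate,
    report_from_confusion,
    select_best,
    train_suite,
)

from .conftest import blob_matrix

SMALL_GRID = {
    "decision_tree": {"max_depth": [3]},
    "knn": {"n_neighbors": [3]},
    "random_forest": {"n_estimators": [30], "max_depth": [5]},
    "xgboost": {"n_estimators": [30], "max_depth": [3]},
}


class TestMetrics:
    def test_report_matches_sklearn_oracle(self):
        # realise an arbitrary confusion matrix as label vectors and compare
        cm = np.array([[37, 8], [5, 50]])
        y_true = np.repeat([0, 0, 1, 1], cm.ravel())
        y_pred = np.concatenate([np.zeros(37), np.ones(8), np.zeros(5), np.ones(50)])
        rep = report_from_confusion(cm)
        p, r, f, s = precision_recall_fscore_support(y_true, y_pred, labels=[0, 1])
        for i, cls in enumerate(("interictal", "ictal")):
            assert rep.precision[cls] == pytest.approx(100 * p[i], abs=1e-9)
            assert rep.recall[cls] == pytest.approx(100 * r[i], abs=1e-9)
            assert rep.f1[cls] == pytest.approx(100 * f[i], abs=1e-9)
        assert rep.accuracy == pytest.approx(100 * (y_true == y_pred).mean())

    def test_f1_consistency(self):
        rep = report_from_confusion([[399, 17], [11, 352]])
        for cls in ("interictal", "ictal"):
            p, r = rep.precision[cls] / 100, rep.recall[cls] / 100
            assert rep.f1[cls] == pytest.approx(100 * 2 * p * r / (p + r), abs=1e-9)

    def test_perfect_predictions(self):
        rep = report_from_confusion([[10, 0], [0, 12]])
        assert rep.accuracy == 100.0
        assert all(v == 100.0 for v in rep.precision.values())
        assert all(v == 100.0 for v in rep.f1.values())


class TestTrainSuite:
    def test_separable_blobs_all_classifiers_exceed_95(self):
        fm = blob_matrix(n=200, sep=5.0, seed=1)
        models = train_suite(fm, grid=SMALL_GRID, seed=1)
        assert [m.classifier_id for m in models] == list(CLASSIFIER_IDS)
        for m in models:
            assert m.train_cv_accuracy_mean > 0.95, m.classifier_id

    def test_label_shuffle_gives_chance_level(self):
        fm = blob_matrix(n=300, sep=0.0, seed=2)  # labels independent of X
        models = train_suite(
            fm,
            grid=SMALL_GRID,
            seed=2,
            classifiers=["logistic_regression", "naive_bayes"],
        )
        for m in models:
            assert m.train_cv_accuracy_mean == pytest.approx(0.5, abs=0.05)

    def test_single_point_grid_is_adopted(self):
        fm = blob_matrix(n=120, seed=3)
        models = train_suite(
            fm,
            grid={"xgboost": {"n_estimators": [5], "max_depth": [3]}},
            seed=3,
            classifiers=["xgboost"],
        )
        assert models[0].hyperparameters == {"n_estimators": 5, "max_depth": 3}

    def test_single_class_input_rejected(self):
        fm = blob_matrix(n=50, seed=4)
        fm.labels[:] = 1
        with pytest.raises(ValueError, match="single class"):
            train_suite(fm, seed=4)

    def test_reproducible_under_fixed_seed(self):
        fm = blob_matrix(n=150, sep=1.0, seed=5)
        test = blob_matrix(n=80, sep=1.0, seed=6)
        runs = []
        for _ in range(2):
            models = train_suite(
                fm, grid=SMALL_GRID, seed=42,
                classifiers=["random_forest", "xgboost"],
            )
            runs.append(
                [(m.hyperparameters, m.predict(test).tolist()) for m in models]
            )
        assert runs[0] == runs[1]


class TestSelectBest:
    def test_perfect_model_wins(self):
        train = blob_matrix(n=150, sep=5.0, seed=7)
        test = blob_matrix(n=80, sep=5.0, seed=8)
        models = train_suite(
            train, grid=SMALL_GRID, seed=7,
            classifiers=["naive_bayes", "xgboost"],
        )
        best = select_best(models, test)
        accs = {m.classifier_id: evaluate(m, test).accuracy for m in models}
        assert accs[best.classifier_id] == max(accs.values())

    def test_tie_breaks_by_fixed_order(self):
        train = blob_matrix(n=100, sep=8.0, seed=9)
        test = blob_matrix(n=60, sep=8.0, seed=10)
        # two runs of the same family: identical accuracy and cv score
        models = train_suite(
            train, grid=SMALL_GRID, seed=9, classifiers=["decision_tree"]
        ) + train_suite(train, grid=SMALL_GRID, seed=9, classifiers=["decision_tree"])
        best = select_best(models, test)
        assert best is models[0]

    def test_matches_brute_force_argmax(self):
        train = blob_matrix(n=200, sep=1.5, seed=11)
        test = blob_matrix(n=120, sep=1.5, seed=12)
        models = train_suite(train, grid=SMALL_GRID, seed=11)
        best = select_best(models, test)
        brute = max(
            models,
            key=lambda m: (
                evaluate(m, test).accuracy,
                m.train_cv_accuracy_mean,
                -CLASSIFIER_IDS.index(m.classifier_id),
            ),
        )
        assert best.classifier_id == brute.classifier_id

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best([], blob_matrix(n=10, seed=13))


def test_column_mismatch_names_offenders():
    train = blob_matrix(n=80, seed=14)
    other = blob_matrix(n=80, p=6, seed=14)
    models = train_suite(
        train, grid=SMALL_GRID, seed=14, classifiers=["decision_tree"]
    )
    with pytest.raises(ValueError, match="Energy_ch7"):
        models[0].predict(other)
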