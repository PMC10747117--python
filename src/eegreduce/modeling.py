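"""Classifier suite, hyperparameter search and evaluation metrics.

Seven supervised classifiers are trained on the attribute matrix: decision
tree, k-nearest neighbours, logistic regression, Gaussian naive Bayes,
random forest, gradient-boosted trees (XGBoost) and an RBF support vector
machine.  Tree ensembles are grid-searched over the number of estimators
{5, 100, 300, 500} and maximum depth {1, 3, 5, 10, 50}; the other families
carry small documented grids.  The model with the highest test accuracy is
carried forward to the explanation stage.

Class 1 (ictal) is the positive class; reports list per-class metrics in the
order (interictal, ictal).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .types import FeatureMatrix

log = logging.getLogger(__name__)

#: Fixed classifier order; also the tie-break order in model selection.
CLASSIFIER_IDS: tuple[str, ...] = (
    "decision_tree", "knn", "logistic_regression", "naive_bayes",
    "random_forest", "xgboost", "svm",
)

ESTIMATOR_GRID = [5, 100, 300, 500]
DEPTH_GRID = [1, 3, 5, 10, 50]


def default_grids() -> dict[str, dict[str, list]]:
    """Per-classifier hyperparameter grids.

    Tree ensembles use the estimators x depth grid; non-tree families use
    minimal grids (neighbour count for kNN, fixed RBF kernel for the SVM,
    default-regularised logistic regression, Gaussian naive Bayes).
    """
    return {
        "decision_tree": {"max_depth": list(DEPTH_GRID)},
        "knn": {"n_neighbors": [1, 3, 5, 7]},
        "logistic_regression": {"C": [1.0]},
        "naive_bayes": {},
        "random_forest": {
            "n_estimators": list(ESTIMATOR_GRID),
            "max_depth": list(DEPTH_GRID),
        },
        "xgboost": {
            "n_estimators": list(ESTIMATOR_GRID),
            "max_depth": list(DEPTH_GRID),
        },
        "svm": {"C": [1.0]},
    }


def make_estimator(classifier_id: str, seed: int) -> BaseEstimator:
    """A fresh unfitted estimator of the given family, seeded where random."""
    if classifier_id == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if classifier_id == "knn":
        return KNeighborsClassifier()
    if classifier_id == "logistic_regression":
        return LogisticRegression(max_iter=5000)
    if classifier_id == "naive_bayes":
        return GaussianNB()
    if classifier_id == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if classifier_id == "xgboost":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        )
    if classifier_id == "svm":
        return SVC(kernel="rbf", random_state=seed)
    raise KeyError(f"unknown classifier id {classifier_id!r}")


@dataclass
class TrainedModel:
    classifier_id: str
    hyperparameters: dict
    estimator: BaseEstimator
    train_cv_accuracy_mean: float
    feature_names: tuple[str, ...]
    seed: int = 0
    test_accuracy: float | None = None  # filled by select_best / evaluate

    def predict(self, fm: FeatureMatrix) -> np.ndarray:
        self._check_columns(fm)
        return self.estimator.predict(fm.values)

    def _check_columns(self, fm: FeatureMatrix) -> None:
        if tuple(fm.attribute_names) != tuple(self.feature_names):
            missing = [c for c in self.feature_names if c not in fm.attribute_names]
            extra = [c for c in fm.attribute_names if c not in self.feature_names]
            raise ValueError(
                f"feature columns do not match the model: missing {missing}, "
                f"extra {extra}"
            )


@dataclass
class EvalReport:
    """Confusion matrix and the derived percentage metrics.

    ``confusion`` rows are true classes, columns predicted, in the order
    (interictal, ictal).  All metrics are percentages.
    """

    confusion: np.ndarray
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int] = field(default_factory=dict)

    def to_dict(self, ndigits: int = 2) -> dict:
        r = lambda v: round(float(v), ndigits)
        return {
            "confusion": np.asarray(self.confusion).astype(int).tolist(),
            "accuracy": r(self.accuracy),
            "precision": {k: r(v) for k, v in self.precision.items()},
            "recall": {k: r(v) for k, v in self.recall.items()},
            "f1": {k: r(v) for k, v in self.f1.items()},
            "support": dict(self.support),
        }


CLASS_NAMES = ("interictal", "ictal")


def report_from_confusion(cm: np.ndarray) -> EvalReport:
    """Derive accuracy and per-class precision/recall/F1 (in %) from a 2x2
    confusion matrix with rows = true (interictal, ictal)."""
    cm = np.asarray(cm, dtype=np.int64)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion matrix must be 2x2 with non-negative counts")
    total = cm.sum()
    accuracy = 100.0 * np.trace(cm) / total if total else float("nan")
    precision, recall, f1, support = {}, {}, {}, {}
    for i, name in enumerate(CLASS_NAMES):
        tp = cm[i, i]
        pred = cm[:, i].sum()
        true = cm[i, :].sum()
        p = tp / pred if pred else float("nan")
        r = tp / true if true else float("nan")
        precision[name] = 100.0 * p
        recall[name] = 100.0 * r
        f1[name] = 100.0 * (2 * p * r / (p + r)) if (p + r) else float("nan")
        support[name] = int(true)
    return EvalReport(cm, float(accuracy), precision, recall, f1, support)


def evaluate(model: TrainedModel, test: FeatureMatrix) -> EvalReport:
    """Predict on the test matrix and compute all metrics from the confusion
    matrix.  Test columns must match the model's feature names exactly."""
    y_pred = model.predict(test)
    cm = confusion_matrix(test.labels, y_pred, labels=[0, 1])
    report = report_from_confusion(cm)
    model.test_accuracy = report.accuracy / 100.0
    return report


def train_suite(
    train: FeatureMatrix,
    grid: Mapping[str, Mapping[str, list]] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    classifiers: Sequence[str] = CLASSIFIER_IDS,
) -> list[TrainedModel]:
    """Grid-search every classifier family on the training matrix.

    Returns one best-grid model per family with its cross-validated mean
    training accuracy.  ``grid`` entries override the defaults per family.
    """
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data holds a single class")
    grids = default_grids()
    if grid:
        for cid, g in grid.items():
            if cid not in grids:
                raise KeyError(f"unknown classifier id {cid!r}")
            grids[cid] = {k: list(v) for k, v in g.items()}

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    models: list[TrainedModel] = []
    for cid in classifiers:
        est = make_estimator(cid, seed)
        param_grid = grids[cid]
        if param_grid:
            search = GridSearchCV(
                est, param_grid, scoring="accuracy", cv=cv, n_jobs=1, refit=True
            )
            search.fit(train.values, y)
            best = search.best_estimator_
            hp = dict(search.best_params_)
            cv_acc = float(search.best_score_)
        else:
            from sklearn.model_selection import cross_val_score

            cv_acc = float(
                np.mean(cross_val_score(clone(est), train.values, y, cv=cv, n_jobs=1))
            )
            best = clone(est).fit(train.values, y)
            hp = {}
        log.info("%s: cv accuracy %.4f with %s", cid, cv_acc, hp)
        models.append(
            TrainedModel(
                classifier_id=cid,
                hyperparameters=hp,
                estimator=best,
                train_cv_accuracy_mean=cv_acc,
                feature_names=tuple(train.attribute_names),
                seed=seed,
            )
        )
    return models


def select_best(models: Sequence[TrainedModel], test: FeatureMatrix) -> TrainedModel:
    """Pick the model with the highest test accuracy.

    Ties break by higher cross-validated training accuracy, then by the fixed
    classifier order.
    """
    if not models:
        raise ValueError("no models to select from")
    scored = []
    for m in models:
        report = evaluate(m, test)
        order = (
            CLASSIFIER_IDS.index(m.classifier_id)
            if m.classifier_id in CLASSIFIER_IDS
            else len(CLASSIFIER_IDS)
        )
        scored.append((-report.accuracy, -m.train_cv_accuracy_mean, order, m))
        log.info("%s: test accuracy %.2f%%", m.classifier_id, report.accuracy)
    scored.sort(key=lambda t: t[:3])
    return scored[0][3]


def refit(model: TrainedModel, train: FeatureMatrix) -> TrainedModel:
    """Fresh clone of the model's estimator fitted on (a subset of) columns."""
    est = clone(model.estimator)
    est.fit(train.values, train.labels)
    return TrainedModel(
        classifier_id=model.classifier_id,
        hyperparameters=dict(model.hyperparameters),
        estimator=est,
        train_cv_accuracy_mean=float("nan"),
        feature_names=tuple(train.attribute_names),
        seed=model.seed,
    )


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist the fitted estimator plus a JSON sidecar of its metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.estimator, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "classifier_id": model.classifier_id,
                "hyperparameters": model.hyperparameters,
                "seed": model.seed,
                "train_cv_accuracy_mean": model.train_cv_accuracy_mean,
                "feature_names": list(model.feature_names),
            },
            fh,
            indent=2,
        )
    return path
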