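"""Shapley additive attributions for the trained classifiers.

Three routes, picked automatically from the model family:

* **tree ensembles** (XGBoost boosters, scikit-learn decision trees and
  random forests) — a path-dependent tree-Shapley implementation operating
  on the fitted tree arrays in float64.  Conditional expectations under a
  feature coalition follow the training cover stored at each split, and the
  polynomial-time path algorithm distributes each leaf's value over the
  features on its path.  XGBoost attributions are on the log-odds margin
  scale; scikit-learn trees on the class-1 probability scale.
* **XGBoost fast path** (``algorithm="tree32"``) — the booster's built-in
  ``pred_contribs``, identical up to its float32 accumulation (~1e-5).
* **any other model** — a seeded permutation-sampling estimator against a
  background sample (default 100 rows).  One background row is drawn per
  permutation and shared across evaluated samples, so the telescoping sum
  keeps additivity exact: ``base + sum(phi) == f(x)`` for every sample.

All routes satisfy local accuracy: per-sample attributions plus the base
value reproduce the model output on its native margin scale (for boosters,
the float64 evaluation of the fitted trees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = ["AttributionResult", "shap_values", "model_margin"]


@dataclass
class AttributionResult:
    """Per-sample attribution matrix, its base value and the output scale."""

    phi: np.ndarray  # (n_eval, p)
    base_value: float
    output_scale: str  # "log-odds" | "probability"
    algorithm: str


# ---------------------------------------------------------------------------
# path-dependent tree Shapley (scikit-learn trees)


class _PathElement:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self, d: int, z: float, o: float, w: float):
        self.d, self.z, self.o, self.w = d, z, o, w

    def copy(self) -> "_PathElement":
        return _PathElement(self.d, self.z, self.o, self.w)


def _extend(m: list[_PathElement], pz: float, po: float, pi: int) -> list[_PathElement]:
    l = len(m)
    m = [e.copy() for e in m]
    m.append(_PathElement(pi, pz, po, 1.0 if l == 0 else 0.0))
    for i in range(l - 1, -1, -1):
        m[i + 1].w += po * m[i].w * (i + 1) / (l + 1)
        m[i].w = pz * m[i].w * (l - i) / (l + 1)
    return m


def _unwind(m: list[_PathElement], i: int) -> list[_PathElement]:
    l = len(m)
    m = [e.copy() for e in m]
    n = m[-1].w
    o, z = m[i].o, m[i].z
    for j in range(l - 2, -1, -1):
        if o != 0:
            t = m[j].w
            m[j].w = n * l / ((j + 1) * o)
            n = t - m[j].w * z * (l - j - 1) / l
        else:
            m[j].w = m[j].w * l / (z * (l - j - 1))
    for j in range(i, l - 1):
        m[j].d, m[j].z, m[j].o = m[j + 1].d, m[j + 1].z, m[j + 1].o
    return m[:-1]


def _tree_shap_sample(
    x: np.ndarray,
    phi: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    feature: np.ndarray,
    threshold: np.ndarray,
    leaf_value: np.ndarray,
    cover: np.ndarray,
    strict: bool = False,
) -> None:
    """Accumulate one tree's attributions for one sample into ``phi``.

    ``strict=True`` sends ``x < threshold`` left (the xgboost split rule);
    the default ``x <= threshold`` is scikit-learn's.
    """

    def recurse(j: int, m: list[_PathElement], pz: float, po: float, pi: int) -> None:
        m = _extend(m, pz, po, pi)
        if left[j] < 0:  # leaf
            for i in range(1, len(m)):
                w = sum(e.w for e in _unwind(m, i))
                phi[m[i].d] += w * (m[i].o - m[i].z) * leaf_value[j]
            return
        d = int(feature[j])
        goes_left = x[d] < threshold[j] if strict else x[d] <= threshold[j]
        if goes_left:
            hot, cold = left[j], right[j]
        else:
            hot, cold = right[j], left[j]
        iz = io = 1.0
        k = next((idx for idx in range(1, len(m)) if m[idx].d == d), None)
        if k is not None:
            iz, io = m[k].z, m[k].o
            m = _unwind(m, k)
        recurse(int(hot), m, iz * cover[hot] / cover[j], io, d)
        recurse(int(cold), m, iz * cover[cold] / cover[j], 0.0, d)

    recurse(0, [], 1.0, 1.0, -1)


def _sk_tree_arrays(tree) -> tuple[np.ndarray, ...]:
    t = tree.tree_
    counts = t.value[:, 0, :]
    with np.errstate(invalid="ignore"):
        proba1 = counts[:, 1] / counts.sum(axis=1)
    return (
        t.children_left,
        t.children_right,
        t.feature,
        t.threshold,
        np.nan_to_num(proba1),
        t.weighted_n_node_samples,
    )


def _tree_expected_value(left, right, leaf_value, cover) -> float:
    """Cover-weighted mean leaf value (the empty-coalition expectation)."""
    leaves = left < 0
    return float(np.sum(leaf_value[leaves] * cover[leaves]) / cover[0])


def _sklearn_tree_shap(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    trees = model.estimators_ if isinstance(model, RandomForestClassifier) else [model]
    n, p = X.shape
    phi = np.zeros((n, p))
    base = 0.0
    for tree in trees:
        left, right, feat, thr, val, cov = _sk_tree_arrays(tree)
        base += _tree_expected_value(left, right, val, cov)
        for i in range(n):
            _tree_shap_sample(X[i], phi[i], left, right, feat, thr, val, cov)
    k = len(trees)
    return phi / k, base / k


# ---------------------------------------------------------------------------
# xgboost boosters, evaluated in float64


class BoosterTrees:
    """Float64 view of a fitted xgboost booster's trees.

    Parses the tree structure once and provides margin evaluation, the
    cover-weighted expected margin and path-dependent Shapley attributions,
    all in float64 so local accuracy holds to machine precision.
    """

    def __init__(self, booster):
        df = booster.trees_to_dataframe()
        self.trees: list[tuple[np.ndarray, ...]] = []
        for _, g in df.groupby("Tree"):
            g = g.sort_values("Node")
            n = len(g)
            node_of = dict(zip(g["ID"], g["Node"]))
            left = np.full(n, -1, dtype=np.int64)
            right = np.full(n, -1, dtype=np.int64)
            feat = np.full(n, -1, dtype=np.int64)
            thr = np.zeros(n)
            val = np.zeros(n)
            cov = np.zeros(n)
            for row in g.itertuples():
                j = row.Node
                cov[j] = row.Cover
                if row.Feature == "Leaf":
                    val[j] = row.Gain
                else:
                    left[j] = node_of[row.Yes]
                    right[j] = node_of[row.No]
                    feat[j] = int(row.Feature[1:])
                    thr[j] = row.Split
            self.trees.append((left, right, feat, thr, val, cov))
        self.intercept = self._intercept(booster)

    @staticmethod
    def _intercept(booster) -> float:
        """Margin offset: logit of the stored base_score (binary objectives)."""
        import json

        cfg = json.loads(booster.save_config())
        params = cfg["learner"]["learner_model_param"]
        base_score = float(params["base_score"])
        objective = cfg["learner"]["objective"].get("name", "")
        if objective.startswith(("binary:", "reg:logistic")):
            base_score = min(max(base_score, 1e-12), 1 - 1e-12)
            return float(np.log(base_score / (1.0 - base_score)))
        return base_score

    def margin(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        out = np.full(X.shape[0], self.intercept)
        for left, right, feat, thr, val, _ in self.trees:
            for i in range(X.shape[0]):
                j = 0
                while left[j] >= 0:
                    j = left[j] if X[i, feat[j]] < thr[j] else right[j]
                out[i] += val[j]
        return out

    @property
    def expected_value(self) -> float:
        base = self.intercept
        for left, right, _, _, val, cov in self.trees:
            base += _tree_expected_value(left, right, val, cov)
        return base

    def shap(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        X = np.asarray(X, dtype=np.float64)
        n, p = X.shape
        phi = np.zeros((n, p))
        for left, right, feat, thr, val, cov in self.trees:
            for i in range(n):
                _tree_shap_sample(
                    X[i], phi[i], left, right, feat, thr, val, cov, strict=True
                )
        return phi, self.expected_value


# ---------------------------------------------------------------------------
# model output on its native margin scale


def model_margin(estimator, X: np.ndarray) -> tuple[np.ndarray, str]:
    """Model output on the scale the attributions explain.

    XGBoost: raw log-odds margin, evaluated from the fitted trees in
    float64.  Probabilistic models: P(class 1).  Margin-only models (e.g.
    an uncalibrated SVM): the decision function.
    """
    if _is_xgb(estimator):
        return BoosterTrees(estimator.get_booster()).margin(X), "log-odds"
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1], "probability"
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(X)), "decision"
    return estimator.predict(X).astype(float), "prediction"


def _is_xgb(estimator) -> bool:
    return estimator.__class__.__name__ == "XGBClassifier" or hasattr(
        estimator, "get_booster"
    )


# ---------------------------------------------------------------------------
# permutation-sampling fallback


def _sampling_shap(
    estimator,
    X: np.ndarray,
    background: np.ndarray,
    seed: int,
    n_permutations: int,
) -> tuple[np.ndarray, float, str]:
    rng = np.random.default_rng(seed)
    n, p = X.shape
    nb = background.shape[0]
    phi = np.zeros((n, p))
    base_vals = []
    for _ in range(n_permutations):
        order = rng.permutation(p)
        b = background[rng.integers(nb)]
        # one shared background row per permutation keeps additivity exact
        stack = np.empty((n, p + 1, p))
        stack[:, 0, :] = b
        for step, f in enumerate(order, start=1):
            stack[:, step, :] = stack[:, step - 1, :]
            stack[:, step, f] = X[:, f]
        out, scale = model_margin(estimator, stack.reshape(n * (p + 1), p))
        out = out.reshape(n, p + 1)
        base_vals.append(out[:, 0])
        for step, f in enumerate(order, start=1):
            phi[:, f] += out[:, step] - out[:, step - 1]
    phi /= n_permutations
    base = float(np.mean(base_vals))
    return phi, base, scale


# ---------------------------------------------------------------------------
# public entry point


def shap_values(
    estimator,
    X: np.ndarray,
    *,
    algorithm: str = "auto",
    background: np.ndarray | None = None,
    n_background: int = 100,
    n_permutations: int = 20,
    seed: int = 0,
) -> AttributionResult:
    """Per-sample Shapley attributions for ``estimator`` evaluated on ``X``.

    ``algorithm`` is ``"tree"`` (exact tree-path, tree models only),
    ``"sampling"`` (model-agnostic permutation estimate) or ``"auto"``.
    """
    X = np.asarray(X, dtype=np.float64)
    if algorithm == "auto":
        if _is_xgb(estimator) or isinstance(
            estimator, (DecisionTreeClassifier, RandomForestClassifier)
        ):
            algorithm = "tree"
        else:
            algorithm = "sampling"

    if algorithm == "tree32":
        if not _is_xgb(estimator):
            raise ValueError("tree32 (pred_contribs) applies to XGBoost models only")
        import xgboost as xgb

        dm = xgb.DMatrix(X)
        contribs = estimator.get_booster().predict(dm, pred_contribs=True)
        return AttributionResult(
            phi=np.asarray(contribs[:, :-1], dtype=np.float64),
            base_value=float(contribs[0, -1]),
            output_scale="log-odds",
            algorithm="tree-path (xgboost float32)",
        )
    if algorithm == "tree":
        if _is_xgb(estimator):
            phi, base = BoosterTrees(estimator.get_booster()).shap(X)
            return AttributionResult(phi, base, "log-odds", "tree-path")
        if isinstance(estimator, (DecisionTreeClassifier, RandomForestClassifier)):
            phi, base = _sklearn_tree_shap(estimator, X)
            return AttributionResult(phi, base, "probability", "tree-path")
        raise ValueError(
            f"tree attribution requested for non-tree model "
            f"{type(estimator).__name__}; pass algorithm='sampling'"
        )
    if algorithm == "sampling":
        if background is None:
            background = X
        rng = np.random.default_rng(seed)
        if background.shape[0] > n_background:
            idx = rng.choice(background.shape[0], n_background, replace=False)
            background = background[idx]
        phi, base, scale = _sampling_shap(
            estimator, X, np.asarray(background, dtype=np.float64), seed, n_permutations
        )
        return AttributionResult(phi, base, scale, "permutation-sampling")
    raise ValueError(f"unknown attribution algorithm {algorithm!r}")
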