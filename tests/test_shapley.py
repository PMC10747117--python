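"""Attribution engine: exactness against enumeration, additivity, ranking."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from eegreduce.modeling import TrainedModel, train_suite
from eegreduce.reduction import shap_rank
from eegreduce.shapley import BoosterTrees, model_margin, shap_values
from eegreduce.types import FeatureMatrix

from .conftest import blob_matrix
from .oracles import brute_force_tree_shap


def _xy(n=120, p=5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = (X[:, 0] + 0.6 * X[:, 1] * X[:, 2] + 0.3 * rng.normal(size=n) > 0).astype(int)
    return X, y, rng


class TestExactnessAgainstEnumeration:
    """The polynomial-time path algorithm must equal exhaustive Shapley
    enumeration under the cover-weighted conditional expectation."""

    @pytest.mark.parametrize("depth", [2, 4])
    def test_decision_tree(self, depth):
        X, y, rng = _xy(seed=1)
        model = DecisionTreeClassifier(max_depth=depth, random_state=0).fit(X, y)
        Xe = rng.normal(size=(5, 5))
        res = shap_values(model, Xe, algorithm="tree")
        from eegreduce.shapley import _sk_tree_arrays

        arrays = _sk_tree_arrays(model)
        for i in range(5):
            expected = brute_force_tree_shap(arrays, Xe[i], p=5)
            np.testing.assert_allclose(res.phi[i], expected, atol=1e-10)

    def test_random_forest_is_mean_over_trees(self):
        X, y, rng = _xy(seed=2)
        model = RandomForestClassifier(n_estimators=8, max_depth=3, random_state=0)
        model.fit(X, y)
        Xe = rng.normal(size=(3, 5))
        res = shap_values(model, Xe, algorithm="tree")
        from eegreduce.shapley import _sk_tree_arrays

        for i in range(3):
            expected = np.mean(
                [
                    brute_force_tree_shap(_sk_tree_arrays(t), Xe[i], p=5)
                    for t in model.estimators_
                ],
                axis=0,
            )
            np.testing.assert_allclose(res.phi[i], expected, atol=1e-10)

    def test_xgboost_parsed_trees(self):
        X, y, rng = _xy(seed=3)
        model = XGBClassifier(
            n_estimators=10, max_depth=3, random_state=0, tree_method="hist"
        ).fit(X, y)
        Xe = rng.normal(size=(3, 5))
        res = shap_values(model, Xe, algorithm="tree")
        trees = BoosterTrees(model.get_booster())
        for i in range(3):
            expected = sum(
                brute_force_tree_shap(arr, Xe[i], p=5, strict=True)
                for arr in trees.trees
            )
            np.testing.assert_allclose(res.phi[i], expected, atol=1e-9)

    def test_agrees_with_xgboost_builtin(self):
        X, y, rng = _xy(n=300, p=8, seed=4)
        model = XGBClassifier(
            n_estimators=80, max_depth=4, random_state=0, tree_method="hist"
        ).fit(X, y)
        Xe = rng.normal(size=(40, 8))
        mine = shap_values(model, Xe, algorithm="tree")
        builtin = shap_values(model, Xe, algorithm="tree32")
        np.testing.assert_allclose(mine.phi, builtin.phi, atol=1e-4)
        assert mine.base_value == pytest.approx(builtin.base_value, abs=1e-4)


class TestAdditivity:
    def test_tree_routes_exact(self):
        X, y, rng = _xy(n=250, p=8, seed=5)
        Xe = rng.normal(size=(60, 8))
        models = [
            DecisionTreeClassifier(max_depth=6, random_state=0).fit(X, y),
            RandomForestClassifier(n_estimators=25, max_depth=6, random_state=0).fit(X, y),
            XGBClassifier(n_estimators=150, max_depth=5, random_state=0,
                          tree_method="hist").fit(X, y),
        ]
        for model in models:
            res = shap_values(model, Xe, algorithm="tree")
            margin, _ = model_margin(model, Xe)
            err = np.abs(res.phi.sum(axis=1) + res.base_value - margin)
            assert err.max() < 1e-6, type(model).__name__

    def test_sampling_route_exact_by_telescoping(self):
        X, y, rng = _xy(n=200, p=6, seed=6)
        model = LogisticRegression(max_iter=2000).fit(X, y)
        Xe = rng.normal(size=(30, 6))
        res = shap_values(model, Xe, algorithm="sampling", n_permutations=8, seed=0)
        margin, _ = model_margin(model, Xe)
        err = np.abs(res.phi.sum(axis=1) + res.base_value - margin)
        assert err.max() < 1e-10

    def test_tree_route_refuses_non_tree_models(self):
        X, y, _ = _xy(seed=7)
        model = LogisticRegression().fit(X, y)
        with pytest.raises(ValueError, match="sampling"):
            shap_values(model, X[:5], algorithm="tree")


class TestRanking:
    def _fit_model(self, fm: FeatureMatrix, seed=0) -> TrainedModel:
        models = train_suite(
            fm,
            grid={"xgboost": {"n_estimators": [50], "max_depth": [3]}},
            seed=seed,
            classifiers=["xgboost"],
        )
        return models[0]

    def test_planted_feature_ranked_first(self):
        fm = blob_matrix(n=300, p=8, sep=4.0, seed=8)
        model = self._fit_model(fm)
        ranking = shap_rank(model, fm)
        assert ranking.attributes[0] == "Energy_ch0"
        assert np.all(np.diff(ranking.importance) <= 1e-12)  # non-increasing

    def test_noise_column_ranked_below_informative(self):
        # appended pure-noise column ends up below the informative ones in
        # expectation over seeded runs
        wins = 0
        for seed in range(10):
            fm = blob_matrix(n=200, p=4, sep=3.0, seed=seed, informative=2)
            model = self._fit_model(fm, seed=seed)
            ranking = shap_rank(model, fm)
            informative_ranks = [
                ranking.attributes.index(f"Energy_ch{j}") for j in (0, 1)
            ]
            noise_ranks = [
                ranking.attributes.index(f"Energy_ch{j}") for j in (2, 3)
            ]
            if max(informative_ranks) < min(noise_ranks):
                wins += 1
        assert wins >= 8

    def test_single_feature_importance_is_mean_margin_deviation(self):
        fm = blob_matrix(n=200, p=1, sep=4.0, seed=9)
        model = self._fit_model(fm)
        ranking = shap_rank(model, fm)
        margin, _ = model_margin(model.estimator, fm.values)
        expected = np.abs(margin - ranking.base_value).mean()
        assert ranking.importance[0] == pytest.approx(expected, rel=1e-9)

    def test_label_shuffle_collapses_importance_gap(self):
        # with labels shuffled, planted columns lose their advantage: the
        # max/median importance ratio stays small across seeds
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            fm = blob_matrix(n=200, p=10, sep=4.0, seed=seed)
            labels = fm.labels.copy()
            rng.shuffle(labels)
            shuffled = FeatureMatrix(fm.attribute_names, fm.values, labels)
            model = self._fit_model(shuffled, seed=seed)
            ranking = shap_rank(model, shuffled)
            ratios.append(ranking.importance[0] / np.median(ranking.importance))
        assert np.median(ratios) < 2.0

    def test_column_mismatch_rejected(self):
        fm = blob_matrix(n=100, p=4, seed=10)
        other = blob_matrix(n=100, p=3, seed=10)
        model = self._fit_model(fm)
        with pytest.raises(ValueError):
            shap_rank(model, other)
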