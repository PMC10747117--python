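"""Attribute ranking and the two-phase channel/feature reduction.

Phase 1: rank all attributes of the winning classifier by mean absolute
Shapley attribution, then train a series of nested models on the top-1,
top-2, ..., top-K attributes.

Phase 2: among the top-20 ranked attributes, count how often each feature
and each channel recurs; take the 4 most recurrent features and the 5 most
recurrent channels, cross them into 20 combined attributes, re-search
hyperparameters for the winning classifier family on that reduced matrix,
re-rank with Shapley attributions, and trace a second 20-point incremental
curve.  The outcome is a small interpretable model (a handful of attributes
on a handful of electrodes).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import parse_attribute
from .modeling import EvalReport, TrainedModel, evaluate, refit, train_suite
from .shapley import AttributionResult, shap_values
from .types import FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class AttributeRanking:
    """Attributes ordered by non-increasing mean absolute attribution."""

    attributes: tuple[str, ...]
    importance: np.ndarray  # aligned with `attributes`
    phi: np.ndarray  # n_eval x p, columns in *original* matrix order
    phi_columns: tuple[str, ...]
    base_value: float
    output_scale: str

    def top(self, k: int) -> tuple[str, ...]:
        if k > len(self.attributes):
            raise ValueError(f"top-{k} requested but only {len(self.attributes)} attributes")
        return self.attributes[:k]

    def importance_of(self, attribute: str) -> float:
        return float(self.importance[self.attributes.index(attribute)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.attributes) + 1),
                "attribute": list(self.attributes),
                "importance": self.importance,
            }
        )


@dataclass
class IncrementalPoint:
    k: int
    attributes: tuple[str, ...]
    report: EvalReport


@dataclass
class IncrementalCurve:
    """Per-k metrics for the nested top-k attribute models."""

    points: list[IncrementalPoint] = field(default_factory=list)

    def accuracies(self) -> list[float]:
        return [p.report.accuracy for p in self.points]

    def best(self, max_k: int | None = None) -> IncrementalPoint:
        pts = [p for p in self.points if max_k is None or p.k <= max_k]
        return max(pts, key=lambda p: (p.report.accuracy, -p.k))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row = {"k": p.k, "accuracy": round(p.report.accuracy, 2)}
            for cls in ("interictal", "ictal"):
                row[f"precision_{cls}"] = round(p.report.precision[cls], 2)
                row[f"recall_{cls}"] = round(p.report.recall[cls], 2)
                row[f"f1_{cls}"] = round(p.report.f1[cls], 2)
            row["attributes"] = "|".join(p.attributes)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class RecurrenceSelection:
    """Most recurrent features/channels among the top-ranked attributes."""

    top_features: list[tuple[str, int]]
    top_channels: list[tuple[str, int]]
    combined_attributes: tuple[str, ...]

    def feature_names(self) -> list[str]:
        return [f for f, _ in self.top_features]

    def channel_names(self) -> list[str]:
        return [c for c, _ in self.top_channels]

    def to_dict(self) -> dict:
        return {
            "top_features": [list(t) for t in self.top_features],
            "top_channels": [list(t) for t in self.top_channels],
            "combined_attributes": list(self.combined_attributes),
        }


def shap_rank(
    model: TrainedModel,
    eval_set: FeatureMatrix,
    top_k: int | None = None,
    *,
    algorithm: str = "auto",
    seed: int = 0,
) -> AttributeRanking:
    """Rank the model's attributes by mean absolute Shapley attribution.

    Attributions are computed on ``eval_set`` (by default the test split).
    ``top_k`` truncates the returned ordering; the per-sample matrix keeps
    all columns in the original order.
    """
    model._check_columns(eval_set)
    result: AttributionResult = shap_values(
        model.estimator, eval_set.values, algorithm=algorithm, seed=seed
    )
    importance = np.abs(result.phi).mean(axis=0)
    order = np.argsort(-importance, kind="stable")
    if top_k is not None:
        order = order[:top_k]
    return AttributeRanking(
        attributes=tuple(eval_set.attribute_names[i] for i in order),
        importance=importance[order],
        phi=result.phi,
        phi_columns=tuple(eval_set.attribute_names),
        base_value=result.base_value,
        output_scale=result.output_scale,
    )


def incremental_models(
    ranking: AttributeRanking,
    train: FeatureMatrix,
    test: FeatureMatrix,
    K: int,
    hp_model: TrainedModel,
) -> IncrementalCurve:
    """Train nested models on the top-1..top-K ranked attributes.

    Model k reuses ``hp_model``'s classifier family and hyperparameters
    (fresh fit on exactly the top-k columns) and is evaluated on the test
    split with the full metric set.
    """
    if K > len(ranking.attributes):
        raise ValueError(f"K={K} exceeds the {len(ranking.attributes)} ranked attributes")
    curve = IncrementalCurve()
    for k in range(1, K + 1):
        subset = list(ranking.top(k))
        model_k = refit(hp_model, train.select(subset))
        report = evaluate(model_k, test.select(subset))
        curve.points.append(IncrementalPoint(k, tuple(subset), report))
        log.debug("k=%d accuracy %.2f%%", k, report.accuracy)
    return curve


def _top_by_recurrence(
    counts: Counter,
    n: int,
    tie_importance: dict[str, float],
) -> list[tuple[str, int]]:
    # order: count desc, then summed mean-|attribution| of the item's
    # attributes desc, then lexicographic
    items = sorted(
        counts.items(),
        key=lambda kv: (-kv[1], -tie_importance.get(kv[0], 0.0), kv[0]),
    )
    dropped = items[n:]
    if dropped and dropped[0][1] == items[n - 1][1]:
        log.info(
            "recurrence tie at count %d broken by summed attribution: kept %s, dropped %s",
            items[n - 1][1],
            items[n - 1][0],
            [d[0] for d in dropped if d[1] == items[n - 1][1]],
        )
    return items[:n]


def recurrence_combine(
    ranking: AttributeRanking,
    n_features: int = 4,
    n_channels: int = 5,
    n_top: int = 20,
) -> RecurrenceSelection:
    """Select the most recurrent features and channels in the top attributes.

    Counts feature and channel occurrences among the ``n_top`` highest-ranked
    attributes, keeps the ``n_features`` / ``n_channels`` most frequent of
    each (ties broken by the summed importance of the tied item's attributes,
    then lexicographically) and returns their full cross product as the
    combined attribute set, ordered feature-major.
    """
    top = ranking.top(n_top)
    feat_counts: Counter = Counter()
    chan_counts: Counter = Counter()
    feat_imp: dict[str, float] = {}
    chan_imp: dict[str, float] = {}
    for name in top:
        feat, chan = parse_attribute(name)
        imp = ranking.importance_of(name)
        feat_counts[feat] += 1
        chan_counts[chan] += 1
        feat_imp[feat] = feat_imp.get(feat, 0.0) + imp
        chan_imp[chan] = chan_imp.get(chan, 0.0) + imp
    top_feats = _top_by_recurrence(feat_counts, n_features, feat_imp)
    top_chans = _top_by_recurrence(chan_counts, n_channels, chan_imp)
    from .features import attribute_name

    combined = tuple(
        attribute_name(f, c) for f, _ in top_feats for c, _ in top_chans
    )
    return RecurrenceSelection(top_feats, top_chans, combined)


def run_phase2(
    selection: RecurrenceSelection,
    train: FeatureMatrix,
    test: FeatureMatrix,
    grid: dict | None,
    seed: int,
    classifier_id: str,
    *,
    cv_folds: int = 5,
    rank_algorithm: str = "auto",
) -> tuple[TrainedModel, AttributeRanking, IncrementalCurve]:
    """Grid-search the winning family on the combined attributes, re-rank and
    trace the second incremental curve over all combined attributes."""
    sub_train = train.select(list(selection.combined_attributes))
    sub_test = test.select(list(selection.combined_attributes))
    models = train_suite(
        sub_train,
        grid=grid,
        cv_folds=cv_folds,
        seed=seed,
        classifiers=[classifier_id],
    )
    model = models[0]
    evaluate(model, sub_test)
    ranking = shap_rank(model, sub_test, algorithm=rank_algorithm, seed=seed)
    curve = incremental_models(
        ranking, sub_train, sub_test, K=len(selection.combined_attributes), hp_model=model
    )
    return model, ranking, curve


def summary_plot(ranking: AttributeRanking, top_k: int = 20, path=None):
    """Beeswarm-style summary of per-sample attributions for the top
    attributes; returns the matplotlib figure (written to ``path`` if given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(ranking.top(min(top_k, len(ranking.attributes))))
    idx = [ranking.phi_columns.index(n) for n in names]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(names) + 1.5))
    rng = np.random.default_rng(0)
    for row, (name, j) in enumerate(zip(names, idx)):
        vals = ranking.phi[:, j]
        jitter = rng.uniform(-0.3, 0.3, vals.shape)
        ax.scatter(vals, row + jitter, s=4, alpha=0.5)
    ax.set_yticks(range(len(names)), names)
    ax.invert_yaxis()
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel(f"attribution ({ranking.output_scale} scale)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
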