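"""End-to-end orchestration of the two-phase reduction experiment.

Phase 1: load (or generate) the recordings, z-score per channel, cut 1-s
windows, extract the 13 x n_channels attribute matrix, grid-search the
seven-classifier suite, pick the winner by test accuracy, rank attributes by
Shapley attribution and trace the top-k incremental curve.

Phase 2: combine the most recurrent features and channels of the top-20
ranking into a reduced attribute set, re-search hyperparameters for the
winning family on that set, re-rank, and trace the second incremental curve.

All tables are persisted as CSV/JSON under the configured output directory,
together with a manifest (config hash, seed, library versions) that makes a
run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .features import FEATURE_NAMES, extract_features
from .modeling import (
    CLASSIFIER_IDS,
    EvalReport,
    TrainedModel,
    evaluate,
    select_best,
    train_suite,
)
from .preprocess import binarize_labels
from .reduction import (
    AttributeRanking,
    IncrementalCurve,
    RecurrenceSelection,
    incremental_models,
    recurrence_combine,
    run_phase2 as _reduction_phase2,
    shap_rank,
)
from .synth import SynthConfig, generate
from .types import DatasetSplit, FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full two-phase run."""

    source: str = "synth"  # synth | ubmc | delimited
    ubmc_path: str | None = None
    delimited: dict | None = None  # {train: [...], test: [...], fs, channels_as}
    synth: SynthConfig = field(default_factory=SynthConfig)
    window_seconds: float = 1.0
    feature_set: tuple[str, ...] | None = None
    zc_mode: str = "conventional"
    classifiers: tuple[str, ...] = CLASSIFIER_IDS
    grid: dict | None = None  # per-classifier overrides
    cv_folds: int = 5
    seed: int = 0
    n_top: int = 20
    n_features: int = 4
    n_channels: int = 5
    incremental_K: int = 20
    rank_split: str = "test"  # test | train
    rank_algorithm: str = "auto"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.source not in ("synth", "ubmc", "delimited"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.rank_split not in ("test", "train"):
            raise ValueError("rank_split must be 'test' or 'train'")
        if isinstance(self.synth, dict):
            self.synth = SynthConfig(**self.synth)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update(overrides)
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Phase1Result:
    train_fm: FeatureMatrix
    test_fm: FeatureMatrix
    models: list[TrainedModel]
    best: TrainedModel
    best_report: EvalReport
    ranking: AttributeRanking
    curve: IncrementalCurve


@dataclass
class Phase2Result:
    selection: RecurrenceSelection
    model: TrainedModel
    report: EvalReport
    ranking: AttributeRanking
    curve: IncrementalCurve


def load_split(config: RunConfig) -> DatasetSplit:
    if config.source == "synth":
        return generate(config.synth)
    if config.source == "ubmc":
        if not config.ubmc_path:
            raise ValueError("ubmc source requires ubmc_path")
        return eio.load_ubmc_dataset(config.ubmc_path)
    spec = config.delimited or {}
    split = DatasetSplit()
    for name in ("train", "test"):
        for entry in spec.get(name, []):
            rec = eio.load_delimited(
                entry["path"],
                fs=spec.get("fs", 500.0),
                channel_names=entry.get("channel_names"),
                label=entry.get("label", "interictal"),
                channels_as=spec.get("channels_as", "columns"),
            )
            getattr(split, name).append(rec)
    return split


def build_features(config: RunConfig) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Load -> z-score -> window -> extract, for both splits."""
    split = load_split(config)
    train_ws, test_ws = binarize_labels(split, config.window_seconds)
    fms = []
    for ws in (train_ws, test_ws):
        fm = extract_features(ws, config.feature_set, zc_mode=config.zc_mode)
        fm, dropped = fm.dropna()
        if dropped:
            log.warning("dropped %d windows with undefined attributes", dropped)
        fms.append(fm)
    log.info(
        "feature matrices: train %dx%d, test %dx%d",
        fms[0].n_rows, fms[0].n_attributes, fms[1].n_rows, fms[1].n_attributes,
    )
    return fms[0], fms[1]


def run_phase1(config: RunConfig) -> Phase1Result:
    """Execute the first phase end to end and persist its artefacts."""
    train_fm, test_fm = build_features(config)
    models = train_suite(
        train_fm,
        grid=config.grid,
        cv_folds=config.cv_folds,
        seed=config.seed,
        classifiers=config.classifiers,
    )
    best = select_best(models, test_fm)
    best_report = evaluate(best, test_fm)
    log.info(
        "phase-1 winner: %s (test accuracy %.2f%%)",
        best.classifier_id, best_report.accuracy,
    )
    rank_fm = test_fm if config.rank_split == "test" else train_fm
    ranking = shap_rank(
        best, rank_fm, algorithm=config.rank_algorithm, seed=config.seed
    )
    K = min(config.incremental_K, len(ranking.attributes))
    curve = incremental_models(ranking, train_fm, test_fm, K=K, hp_model=best)
    result = Phase1Result(train_fm, test_fm, models, best, best_report, ranking, curve)
    _persist_phase1(config, result)
    return result


def run_phase2(config: RunConfig, phase1: Phase1Result) -> Phase2Result:
    """Execute the second phase from phase-1 outputs and persist artefacts."""
    selection = recurrence_combine(
        phase1.ranking,
        n_features=config.n_features,
        n_channels=config.n_channels,
        n_top=config.n_top,
    )
    model, ranking, curve = _reduction_phase2(
        selection,
        phase1.train_fm,
        phase1.test_fm,
        grid=config.grid,
        seed=config.seed,
        classifier_id=phase1.best.classifier_id,
        cv_folds=config.cv_folds,
        rank_algorithm=config.rank_algorithm,
    )
    report = evaluate(
        model, phase1.test_fm.select(list(selection.combined_attributes))
    )
    result = Phase2Result(selection, model, report, ranking, curve)
    _persist_phase2(config, phase1, result)
    return result


def run_all(config: RunConfig) -> tuple[Phase1Result, Phase2Result]:
    p1 = run_phase1(config)
    p2 = run_phase2(config, p1)
    return p1, p2


# ---------------------------------------------------------------------------
# persistence


def _out(config: RunConfig) -> Path | None:
    if config.out_dir is None:
        return None
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _manifest(config: RunConfig) -> dict:
    import sklearn
    import xgboost

    return {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        },
    }


def _persist_phase1(config: RunConfig, r: Phase1Result) -> None:
    out = _out(config)
    if out is None:
        return
    eio.write_table(_manifest(config), out / "manifest.json")
    eio.write_table(r.train_fm, out / "features_train.csv")
    eio.write_table(r.test_fm, out / "features_test.csv")
    suite_rows = []
    for m in r.models:
        suite_rows.append(
            {
                "classifier": m.classifier_id,
                "hyperparameters": json.dumps(m.hyperparameters),
                "train_cv_accuracy_mean": round(100 * m.train_cv_accuracy_mean, 2),
                "test_accuracy": round(100 * (m.test_accuracy or float("nan")), 2),
            }
        )
    eio.write_table(suite_rows, out / "classifier_suite.csv", format="csv")
    eio.write_table(r.ranking.to_frame(), out / "phase1_ranking.csv")
    eio.write_table(r.curve.to_frame(), out / "phase1_curve.csv")
    eio.write_table(
        {"winner": r.best.classifier_id, **r.best_report.to_dict()},
        out / "phase1_eval.json",
    )


def _persist_phase2(config: RunConfig, p1: Phase1Result, r: Phase2Result) -> None:
    out = _out(config)
    if out is None:
        return
    eio.write_table(r.ranking.to_frame(), out / "phase2_ranking.csv")
    eio.write_table(r.curve.to_frame(), out / "phase2_curve.csv")
    report = {
        "selection": r.selection.to_dict(),
        "winner": r.model.classifier_id,
        "hyperparameters": r.model.hyperparameters,
        "phase2_eval": r.report.to_dict(),
        "phase1_accuracy_curve": [round(a, 2) for a in p1.curve.accuracies()],
        "phase2_accuracy_curve": [round(a, 2) for a in r.curve.accuracies()],
    }
    eio.write_table(report, out / "reduction_report.json")
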