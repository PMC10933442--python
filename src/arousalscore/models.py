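"""Per-sleep-stage intensity classifiers.

:class:`ArousalIntensityModel` is built from a feature table (one row per
scored event: metadata plus the 136 normalized features) and ``fit()``
returns an :class:`ArousalIntensityResults` carrying, for each of the four
sleep stages REM/N1/N2/N3, the chosen classifier family, the RFECV-selected
feature subset, the tuned hyperparameters, the fitted estimator, and the
held-out stage report.

The training protocol: one global stratified 80/20 split; the training side
is partitioned by stage at onset; per stage, minority levels are SMOTE-
oversampled to parity, recursive feature elimination with 5-fold CV is run
for both classifier families (random forest and LightGBM gradient boosting),
the family/subset pair with the highest mean CV accuracy wins, and its
hyperparameters are tuned by TPE with successive-halving pruning. Nothing
from the test side ever enters oversampling, selection, or tuning.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from . import tuning
from .evaluation import StagePrediction, StageReport, aggregate_report
from .features import FEATURE_NAMES
from .io import read_feature_table

logger = logging.getLogger(__name__)

MODEL_STAGES = ("REM", "N1", "N2", "N3")
CLASSIFIER_KINDS = ("random_forest", "gradient_boosting")

SEARCH_SPACES: dict[str, dict] = {
    "random_forest": {
        "n_estimators": {"type": "int", "low": 100, "high": 400},
        "max_depth": {"type": "int", "low": 3, "high": 20},
        "min_samples_leaf": {"type": "int", "low": 1, "high": 8},
        "max_features": {"type": "float", "low": 0.1, "high": 1.0},
    },
    "gradient_boosting": {
        "n_estimators": {"type": "int", "low": 100, "high": 400},
        "learning_rate": {"type": "float", "low": 0.01, "high": 0.3, "log": True},
        "num_leaves": {"type": "int", "low": 8, "high": 64},
        "min_child_samples": {"type": "int", "low": 2, "high": 20},
        "colsample_bytree": {"type": "float", "low": 0.3, "high": 1.0},
    },
}


@dataclass
class TrainConfig:
    test_frac: float = 0.2
    cv_folds: int = 5
    smote_k: int = 5
    rfe_step: float = 0.15          # fraction of features removed per RFE iteration
    min_features: int = 5
    n_trials: int = 30
    objective: str = "mean_cv_accuracy"  # or "level0_sensitivity"
    seed: int = 0
    min_stage_events: int = 10      # stages with fewer training events are skipped


@dataclass
class SplitDataset:
    """A stratified train/test partition of a feature table."""

    train: pd.DataFrame
    test: pd.DataFrame
    seed: int


@dataclass
class StageModelSpec:
    """What was chosen for one sleep stage (mirrors a per-stage config row)."""

    stage: str
    classifier_kind: str
    selected_features: list[str]
    hyperparameters: dict = field(default_factory=dict)
    cv_folds: int = 5
    cv_accuracy: float | None = None

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "classifier_kind": self.classifier_kind,
            "n_selected_features": len(self.selected_features),
            "selected_features": list(self.selected_features),
            "hyperparameters": dict(self.hyperparameters),
            "cv_folds": self.cv_folds,
            "cv_accuracy": self.cv_accuracy,
        }


@dataclass
class StageModel:
    """A fitted per-stage classifier bundle."""

    spec: StageModelSpec
    estimator: object
    classes: tuple[int, ...]


def split_dataset(matrix: pd.DataFrame, test_frac: float = 0.2, seed: int = 0) -> SplitDataset:
    """Global stratified split; test size is the ceiling of ``test_frac * N``."""
    if len(matrix) < 10:
        raise ValueError(f"need at least 10 events to split, got {len(matrix)}")
    counts = matrix["level"].value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"cannot stratify: level(s) {sorted(thin.index)} have fewer than 2 events"
        )
    train, test = train_test_split(
        matrix,
        test_size=test_frac,
        random_state=seed,
        shuffle=True,
        stratify=matrix["level"],
    )
    return SplitDataset(train=train, test=test, seed=seed)


def oversample_minority(
    train: pd.DataFrame,
    k_neighbors: int = 5,
    seed: int = 0,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """SMOTE: raise every minority level to the majority count.

    Each synthetic row is a convex combination ``x + u * (x_nn - x)`` of a
    minority point and one of its k nearest minority neighbours (u uniform
    on [0, 1]). Classes smaller than ``k_neighbors + 1`` fall back to fewer
    neighbours with a warning; singleton classes are duplicated. Synthetic
    rows get ``event_id`` values prefixed ``synthetic:`` so leakage audits
    can tell them from real events. Already-balanced input returns unchanged.
    """
    feats = list(feature_cols) if feature_cols is not None else list(FEATURE_NAMES)
    counts = train["level"].value_counts()
    majority = counts.max()
    if (counts == majority).all():
        return train.copy()
    rng = np.random.default_rng(seed)
    parts = [train]
    for lvl in sorted(counts.index):
        need = int(majority - counts[lvl])
        if need == 0:
            continue
        group = train[train["level"] == lvl]
        X = group[feats].to_numpy(dtype=float)
        c = len(X)
        if c == 1:
            synth = np.repeat(X, need, axis=0)
        else:
            k_eff = min(k_neighbors, c - 1)
            if k_eff < k_neighbors:
                warnings.warn(
                    f"level {lvl} has only {c} members; reducing SMOTE k to {k_eff}"
                )
            nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
            neigh = nn.kneighbors(X, return_distance=False)[:, 1:]
            base = rng.integers(0, c, size=need)
            partner = neigh[base, rng.integers(0, k_eff, size=need)]
            u = rng.random((need, 1))
            synth = X[base] + u * (X[partner] - X[base])
        sdf = pd.DataFrame(synth, columns=feats)
        sdf["level"] = lvl
        sdf["stage"] = group["stage"].iloc[0] if "stage" in group else None
        sdf["event_id"] = [f"synthetic:{lvl}:{i}" for i in range(need)]
        parts.append(sdf)
    out = pd.concat(parts, ignore_index=True)
    return out


def _base_estimator(kind: str, seed: int):
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if kind == "gradient_boosting":
        return LGBMClassifier(
            n_estimators=100,
            min_child_samples=5,
            random_state=seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


def make_estimator(kind: str, params: dict, seed: int):
    """Instantiate a classifier of the given family with tuned parameters."""
    est = _base_estimator(kind, seed)
    est.set_params(**params)
    return est


def rfecv_select(
    train: pd.DataFrame,
    classifier_kind: str,
    cv_folds: int = 5,
    seed: int = 0,
    step: float = 0.15,
    min_features: int = 5,
    feature_cols: list[str] | None = None,
) -> tuple[list[str], float]:
    """Recursive feature elimination with cross-validation.

    Returns the feature subset with the highest mean CV accuracy along the
    elimination path (ties resolve to the smaller subset) and that accuracy.
    """
    feats = list(feature_cols) if feature_cols is not None else list(FEATURE_NAMES)
    y = train["level"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs at least two intensity levels")
    X = train[feats].to_numpy(dtype=float)
    folds = min(cv_folds, int(np.min(np.bincount(pd.factorize(y)[0]))))
    folds = max(folds, 2)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    if len(feats) == 1:
        return feats, float("nan")
    selector = RFECV(
        _base_estimator(classifier_kind, seed),
        step=step,
        cv=cv,
        scoring="accuracy",
        min_features_to_select=min(min_features, len(feats)),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        selector.fit(X, y)
    selected = [feats[i] for i in np.flatnonzero(selector.support_)]
    score = float(np.max(selector.cv_results_["mean_test_score"]))
    return selected, score


def choose_stage_config(
    train: pd.DataFrame, stage: str, config: TrainConfig
) -> StageModelSpec:
    """Evaluate both classifier families with RFECV; keep the best.

    Ties go to the random forest, then to the smaller feature subset.
    """
    results = {}
    for kind in CLASSIFIER_KINDS:
        selected, score = rfecv_select(
            train,
            kind,
            cv_folds=config.cv_folds,
            seed=config.seed,
            step=config.rfe_step,
            min_features=config.min_features,
        )
        results[kind] = (selected, score)
        logger.info(
            "stage %s / %s: %d features, mean CV accuracy %.4f",
            stage, kind, len(selected), score,
        )
    best_kind = max(
        CLASSIFIER_KINDS,
        key=lambda k: (
            results[k][1],
            k == "random_forest",
            -len(results[k][0]),
        ),
    )
    selected, score = results[best_kind]
    return StageModelSpec(
        stage=stage,
        classifier_kind=best_kind,
        selected_features=selected,
        cv_folds=config.cv_folds,
        cv_accuracy=score,
    )


def _fold_objective(objective: str):
    def score(y_true, y_pred):
        if objective == "level0_sensitivity" and 0 in y_true:
            mask = y_true == 0
            return float(np.mean(y_pred[mask] == 0))
        return float(np.mean(y_pred == y_true))

    return score


def tune_and_fit(
    train: pd.DataFrame, spec: StageModelSpec, config: TrainConfig
) -> StageModel:
    """TPE + successive-halving search, then refit on the full training set."""
    X = train[spec.selected_features].to_numpy(dtype=float)
    y = train["level"].to_numpy()
    folds_n = max(2, min(config.cv_folds, int(np.min(np.bincount(pd.factorize(y)[0])))))
    cv = StratifiedKFold(n_splits=folds_n, shuffle=True, random_state=config.seed)
    folds = list(cv.split(X, y))
    score_fn = _fold_objective(config.objective)

    def evaluate_fold(params: dict, f: int) -> float:
        tr, va = folds[f]
        est = make_estimator(spec.classifier_kind, params, config.seed)
        est.fit(X[tr], y[tr])
        return score_fn(y[va], est.predict(X[va]))

    space = SEARCH_SPACES[spec.classifier_kind]
    best_params, best_value, _ = tuning.tune(
        evaluate_fold, len(folds), space, config.n_trials, config.seed
    )
    est = make_estimator(spec.classifier_kind, best_params, config.seed)
    est.fit(X, y)
    fitted_spec = replace(spec, hyperparameters=best_params)
    return StageModel(
        spec=fitted_spec,
        estimator=est,
        classes=tuple(int(c) for c in est.classes_),
    )


def predict_levels(model: StageModel, features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predict intensity levels and per-class probability scores.

    Score rows sum to 1; the column order is ``model.classes``.
    """
    missing = [f for f in model.spec.selected_features if f not in features.columns]
    if missing:
        raise KeyError(f"feature table is missing selected column(s): {missing}")
    X = features[model.spec.selected_features].to_numpy(dtype=float)
    levels = model.estimator.predict(X).astype(int)
    scores = model.estimator.predict_proba(X)
    return levels, scores


class ArousalIntensityModel:
    """Per-sleep-stage arousal-intensity classification model.

    Parameters
    ----------
    feature_table
        One row per scored event: the metadata columns (``event_id``,
        ``recording``, ``stage``, ``level``, ``onset_s``, ``duration_s``)
        followed by the 136 feature columns.
    config
        Training protocol settings; defaults follow the standard protocol
        (80/20 split, 5-fold CV, SMOTE k=5).
    """

    def __init__(self, feature_table: pd.DataFrame, config: TrainConfig | None = None):
        required = {"event_id", "stage", "level", *FEATURE_NAMES}
        missing = required - set(feature_table.columns)
        if missing:
            raise ValueError(f"feature table lacks column(s): {sorted(missing)[:5]} ...")
        self.table = feature_table.reset_index(drop=True)
        self.config = config or TrainConfig()

    @classmethod
    def from_feature_table(cls, path, config: TrainConfig | None = None) -> "ArousalIntensityModel":
        return cls(read_feature_table(path), config)

    def fit(self) -> "ArousalIntensityResults":
        cfg = self.config
        split = split_dataset(self.table, cfg.test_frac, cfg.seed)
        stage_models: dict[str, StageModel] = {}
        stage_predictions: dict[str, StagePrediction] = {}
        skipped: dict[str, str] = {}
        for stage in MODEL_STAGES:
            tr = split.train[split.train["stage"] == stage]
            te = split.test[split.test["stage"] == stage]
            if len(tr) < cfg.min_stage_events or tr["level"].nunique() < 2:
                skipped[stage] = (
                    f"{len(tr)} training events / {tr['level'].nunique()} levels"
                )
                logger.warning("skipping stage %s: %s", stage, skipped[stage])
                continue
            balanced = oversample_minority(tr, cfg.smote_k, cfg.seed)
            spec = choose_stage_config(balanced, stage, cfg)
            model = tune_and_fit(balanced, spec, cfg)
            stage_models[stage] = model
            if len(te):
                y_pred, scores = predict_levels(model, te)
                stage_predictions[stage] = StagePrediction(
                    y_true=te["level"].to_numpy(dtype=int),
                    y_pred=y_pred,
                    scores=scores,
                    classes=model.classes,
                )
        report = aggregate_report(stage_predictions) if stage_predictions else StageReport()
        return ArousalIntensityResults(
            models=stage_models,
            report=report,
            split=split,
            skipped_stages=skipped,
            config=cfg,
        )


@dataclass
class ArousalIntensityResults:
    """Fit results: per-stage model bundles, held-out report, split audit."""

    models: dict[str, StageModel]
    report: StageReport
    split: SplitDataset
    skipped_stages: dict[str, str]
    config: TrainConfig

    @property
    def train_event_ids(self) -> set:
        return set(self.split.train["event_id"])

    @property
    def test_event_ids(self) -> set:
        return set(self.split.test["event_id"])

    def summary(self) -> str:
        lines = [
            "Arousal intensity classification — per-sleep-stage models",
            f"events: {len(self.split.train)} train / {len(self.split.test)} test "
            f"(seed {self.split.seed})",
            "",
            "Stage  Classifier          #Features  CV acc",
        ]
        for stage, m in self.models.items():
            acc = m.spec.cv_accuracy
            acc_s = f"{acc:.4f}" if acc is not None else "-"
            lines.append(
                f"{stage:<6} {m.spec.classifier_kind:<18} "
                f"{len(m.spec.selected_features):<10} {acc_s}"
            )
        for stage, why in self.skipped_stages.items():
            lines.append(f"{stage:<6} (skipped: {why})")
        lines.append("")
        lines.append(self.report.summary())
        return "\n".join(lines)

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Route rows to their stage's model; returns predicted levels."""
        out = []
        for stage, model in self.models.items():
            sub = features[features["stage"] == stage]
            if not len(sub):
                continue
            levels, _ = predict_levels(model, sub)
            out.append(pd.DataFrame({"event_id": sub["event_id"], "level_pred": levels}))
        if not out:
            return pd.DataFrame(columns=["event_id", "level_pred"])
        return pd.concat(out, ignore_index=True)

    def save(self, out_dir) -> None:
        """Persist estimator bundles (joblib) and specs (JSON) for provenance."""
        import joblib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        specs = {stage: m.spec.to_dict() for stage, m in self.models.items()}
        with open(out / "stage_specs.json", "w") as f:
            json.dump(specs, f, indent=2, sort_keys=True)
        joblib.dump(
            {stage: m for stage, m in self.models.items()}, out / "stage_models.joblib"
        )
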