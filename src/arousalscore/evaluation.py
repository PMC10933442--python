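"""Per-class metrics, confusion matrices, and cross-stage aggregation.

Metrics are one-vs-rest per intensity level: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN), and AUROC from the
rank statistic (ties get half credit). Undefined ratios (0/0) are reported
as absent, never as 0.

Aggregation across sleep stages follows two rules: the per-level "average"
row is the unweighted mean over the stages whose test set contains the
level; the "total" row pools every prediction and support-weights the
pooled per-level metrics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score

ALL_LEVELS = (0, 1, 2, 3, 4)
METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "auroc")


@dataclass
class ClassMetrics:
    """One-vs-rest metrics for a single intensity level (fractions in [0,1])."""

    level: int
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    auroc: float | None = None
    support: int = 0

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "support": self.support,
            **{m: getattr(self, m) for m in METRIC_NAMES},
        }


@dataclass
class StagePrediction:
    """Held-out predictions of one stage model."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray          # (n, len(classes)); rows sum to 1
    classes: tuple[int, ...]    # column order of ``scores``


@dataclass
class StageReport:
    """Per-stage metrics plus the average and total aggregation rows."""

    stages: dict = field(default_factory=dict)   # stage -> {confusion, levels, metrics}
    average: dict = field(default_factory=dict)  # level -> ClassMetrics
    total: dict = field(default_factory=dict)    # metric -> value; plus per-level

    def to_dict(self) -> dict:
        return {
            "stages": {
                s: {
                    "levels": list(v["levels"]),
                    "confusion": np.asarray(v["confusion"]).tolist(),
                    "metrics": {str(m.level): m.to_dict() for m in v["metrics"]},
                }
                for s, v in self.stages.items()
            },
            "average": {str(lvl): m.to_dict() for lvl, m in self.average.items()},
            "total": self.total,
        }

    def summary(self) -> str:
        lines = ["Stage  Level  Sens%   Spec%   PPV%    NPV%    AUROC%  n"]

        def fmt(v):
            return f"{100 * v:6.2f}" if v is not None else "   -  "

        for stage, v in self.stages.items():
            for m in v["metrics"]:
                lines.append(
                    f"{stage:<6} {m.level:<6} {fmt(m.sensitivity)} {fmt(m.specificity)} "
                    f"{fmt(m.ppv)} {fmt(m.npv)} {fmt(m.auroc)} {m.support}"
                )
        for lvl, m in self.average.items():
            lines.append(
                f"Avg    {lvl:<6} {fmt(m.sensitivity)} {fmt(m.specificity)} "
                f"{fmt(m.ppv)} {fmt(m.npv)} {fmt(m.auroc)} {m.support}"
            )
        t = self.total
        if t:
            lines.append(
                f"Total         {fmt(t.get('sensitivity'))} {fmt(t.get('specificity'))} "
                f"{fmt(t.get('ppv'))} {fmt(t.get('npv'))} {fmt(t.get('auroc'))} "
                f"{t.get('support')}"
            )
        return "\n".join(lines)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def per_class_metrics(y_true, y_pred, levels=None) -> tuple[np.ndarray, list[ClassMetrics]]:
    """Confusion matrix and one-vs-rest metrics (without AUROC) per level."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if levels is None:
        levels = sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=levels)
    total = cm.sum()
    out = []
    for i, lvl in enumerate(levels):
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = int(total - tp - fn - fp)
        out.append(
            ClassMetrics(
                level=int(lvl),
                sensitivity=_ratio(tp, tp + fn),
                specificity=_ratio(tn, tn + fp),
                ppv=_ratio(tp, tp + fp),
                npv=_ratio(tn, tn + fn),
                support=tp + fn,
            )
        )
    return cm, out


def ovr_auroc(y_true, scores, classes) -> dict[int, float | None]:
    """One-vs-rest AUROC per class; absent classes get ``None``."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    if scores.shape != (len(y_true), len(classes)):
        raise ValueError(
            f"scores shape {scores.shape} does not match "
            f"{len(y_true)} rows x {len(classes)} classes"
        )
    out: dict[int, float | None] = {}
    for i, c in enumerate(classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            out[int(c)] = None
        else:
            out[int(c)] = float(roc_auc_score(pos, scores[:, i]))
    return out


def _full_score_matrix(pred: StagePrediction, levels) -> np.ndarray:
    """Expand a stage's score matrix to the full level set (missing -> 0)."""
    full = np.zeros((len(pred.y_true), len(levels)))
    for j, c in enumerate(pred.classes):
        full[:, levels.index(int(c))] = pred.scores[:, j]
    return full


def aggregate_report(stage_predictions: dict[str, StagePrediction]) -> StageReport:
    """Build the full report from per-stage held-out predictions."""
    if not stage_predictions:
        raise ValueError("need at least one stage")
    report = StageReport()
    levels = list(ALL_LEVELS)

    for stage, pred in stage_predictions.items():
        stage_levels = sorted(set(int(v) for v in pred.y_true) | set(int(v) for v in pred.y_pred))
        cm, metrics = per_class_metrics(pred.y_true, pred.y_pred, stage_levels)
        auc = ovr_auroc(pred.y_true, pred.scores, pred.classes)
        for m in metrics:
            m.auroc = auc.get(m.level)
        report.stages[stage] = {"levels": stage_levels, "confusion": cm, "metrics": metrics}

    # Average row: unweighted mean over stages where the level occurs in the test set
    for lvl in levels:
        per_stage = [
            next(m for m in v["metrics"] if m.level == lvl)
            for v in report.stages.values()
            if any(m.level == lvl and m.support > 0 for m in v["metrics"])
        ]
        if not per_stage:
            continue
        avg = ClassMetrics(level=lvl, support=sum(m.support for m in per_stage))
        for name in METRIC_NAMES:
            vals = [getattr(m, name) for m in per_stage if getattr(m, name) is not None]
            if vals:
                setattr(avg, name, float(np.mean(vals)))
        report.average[lvl] = avg

    # Total row: pool all predictions, support-weight the pooled per-level metrics
    y_true = np.concatenate([p.y_true for p in stage_predictions.values()])
    y_pred = np.concatenate([p.y_pred for p in stage_predictions.values()])
    scores = np.vstack(
        [_full_score_matrix(p, levels) for p in stage_predictions.values()]
    )
    _, pooled = per_class_metrics(y_true, y_pred, levels)
    pooled_auc = ovr_auroc(y_true, scores, levels)
    for m in pooled:
        m.auroc = pooled_auc.get(m.level)
    total: dict = {"support": int(len(y_true))}
    for name in METRIC_NAMES:
        pairs = [
            (getattr(m, name), m.support)
            for m in pooled
            if getattr(m, name) is not None and m.support > 0
        ]
        if pairs:
            w = np.array([s for _, s in pairs], dtype=float)
            v = np.array([v for v, _ in pairs], dtype=float)
            total[name] = float(np.sum(v * w) / np.sum(w))
    total["per_level"] = {str(m.level): m.to_dict() for m in pooled}
    report.total = total
    return report
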