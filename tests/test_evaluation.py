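"""Metric definitions and the cross-stage aggregation rules."""
import numpy as np
import pytest

from arousalscore.evaluation import (
    StagePrediction,
    aggregate_report,
    ovr_auroc,
    per_class_metrics,
)


def test_binary_confusion_ratios():
    y_true = [1] * 10 + [0] * 100
    y_pred = [1] * 8 + [0] * 2 + [1] * 10 + [0] * 90
    _, metrics = per_class_metrics(y_true, y_pred)
    m1 = next(m for m in metrics if m.level == 1)
    assert m1.sensitivity == pytest.approx(0.800)
    assert m1.specificity == pytest.approx(0.900)
    assert m1.ppv == pytest.approx(0.4444, abs=1e-4)
    assert m1.npv == pytest.approx(0.9783, abs=1e-4)
    assert m1.support == 10


def test_prior_study_hit_rate():
    """168 of 244 control windows recovered: level-0 sensitivity 68.85%."""
    y_true = np.zeros(244, dtype=int)
    y_pred = np.array([0] * 168 + [1] * 76)
    _, metrics = per_class_metrics(y_true, y_pred, levels=[0, 1])
    hit_rate = 100 * metrics[0].sensitivity
    assert round(hit_rate, 2) == 68.85


def test_perfect_predictions():
    y = np.array([0, 1, 2, 3, 4] * 4)
    _, metrics = per_class_metrics(y, y)
    for m in metrics:
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.ppv == 1.0 and m.npv == 1.0


def test_undefined_ratios_are_absent_not_zero():
    # level 2 never occurs and is never predicted: sensitivity and PPV undefined
    _, metrics = per_class_metrics([0, 0, 1], [0, 0, 1], levels=[0, 1, 2])
    m2 = next(m for m in metrics if m.level == 2)
    assert m2.sensitivity is None and m2.ppv is None
    assert m2.specificity == 1.0


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        per_class_metrics([0, 1], [0])


def test_auroc_perfect_and_ties():
    y = np.array([0, 0, 1, 1])
    perfect = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
    assert ovr_auroc(y, perfect, [0, 1])[1] == 1.0
    flat = np.full((4, 2), 0.5)
    assert ovr_auroc(y, flat, [0, 1])[1] == 0.5


def test_auroc_matches_exhaustive_pair_oracle(rng):
    y = rng.integers(0, 2, size=20)
    y[0], y[1] = 0, 1  # both classes present
    s = np.round(rng.random(20), 1)  # coarse scores force ties
    scores = np.column_stack([1 - s, s])
    auc = ovr_auroc(y, scores, [0, 1])[1]
    pos = s[y == 1]
    neg = s[y == 0]
    pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
    assert auc == pytest.approx(np.mean(pairs))


def test_auroc_invariant_to_monotone_transform(rng):
    y = rng.integers(0, 2, size=30)
    y[:2] = [0, 1]
    s = rng.random(30)
    a1 = ovr_auroc(y, np.column_stack([1 - s, s]), [0, 1])[1]
    a2 = ovr_auroc(y, np.column_stack([np.exp(-s), np.exp(s)]), [0, 1])[1]
    assert a1 == pytest.approx(a2)


def _stage_prediction_with_level0_sensitivity(hits, total, seed=0):
    """Level-0 support `total` with `hits` recovered, plus some level-1 rows."""
    y_true = np.array([0] * total + [1] * 10)
    y_pred = np.array([0] * hits + [1] * (total - hits) + [1] * 10)
    scores = np.zeros((len(y_true), 2))
    scores[np.arange(len(y_true)), (y_pred != 0).astype(int)] = 1.0
    return StagePrediction(y_true=y_true, y_pred=y_pred, scores=scores, classes=(0, 1))


def test_average_row_is_unweighted_mean_over_stages_with_level():
    """Stage level-0 sensitivities 82.22/80.56/86.42 (level 0 absent in the
    fourth stage) average to 83.07 under the unweighted cross-stage rule."""
    preds = {
        "REM": _stage_prediction_with_level0_sensitivity(37, 45),   # 82.22%
        "N1": _stage_prediction_with_level0_sensitivity(58, 72),    # 80.56%
        "N2": _stage_prediction_with_level0_sensitivity(70, 81),    # 86.42%
        "N3": StagePrediction(                                      # no level 0
            y_true=np.array([3, 3, 4, 4]),
            y_pred=np.array([3, 3, 4, 4]),
            scores=np.eye(2)[[0, 0, 1, 1]],
            classes=(3, 4),
        ),
    }
    report = aggregate_report(preds)
    assert round(100 * report.average[0].sensitivity, 2) == 83.07
    assert report.average[0].support == 45 + 72 + 81


def test_single_stage_average_equals_stage_metrics():
    pred = _stage_prediction_with_level0_sensitivity(8, 10)
    report = aggregate_report({"N2": pred})
    m0 = next(m for m in report.stages["N2"]["metrics"] if m.level == 0)
    assert report.average[0].sensitivity == m0.sensitivity


def test_total_row_matches_pooled_confusion_oracle(rng):
    preds = {}
    all_true, all_pred = [], []
    for stage in ("REM", "N1", "N2"):
        y_true = rng.integers(0, 5, size=60)
        y_pred = rng.integers(0, 5, size=60)
        scores = rng.random((60, 5))
        scores /= scores.sum(axis=1, keepdims=True)
        preds[stage] = StagePrediction(
            y_true=y_true, y_pred=y_pred, scores=scores, classes=(0, 1, 2, 3, 4)
        )
        all_true.append(y_true)
        all_pred.append(y_pred)
    report = aggregate_report(preds)
    # oracle: pool every prediction, recompute, support-weight
    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    _, pooled = per_class_metrics(y_true, y_pred, [0, 1, 2, 3, 4])
    expected = sum(m.sensitivity * m.support for m in pooled) / sum(
        m.support for m in pooled
    )
    assert report.total["sensitivity"] == pytest.approx(expected)
    assert report.total["support"] == 180


def test_confusion_matrix_sums(rng):
    y_true = rng.integers(0, 5, size=100)
    y_pred = rng.integers(0, 5, size=100)
    cm, metrics = per_class_metrics(y_true, y_pred, [0, 1, 2, 3, 4])
    assert cm.sum() == 100
    for i, m in enumerate(metrics):
        assert cm[i].sum() == m.support
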