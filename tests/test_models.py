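"""Splitting, SMOTE, feature selection, tuning glue, and the Model/Results API."""
import numpy as np
import pandas as pd
import pytest

import arousalscore.models as models
from arousalscore.models import (
    ArousalIntensityModel,
    StageModelSpec,
    TrainConfig,
    choose_stage_config,
    make_estimator,
    oversample_minority,
    predict_levels,
    rfecv_select,
    split_dataset,
    tune_and_fit,
)
from conftest import make_feature_frame


def _level_frame(counts: dict, rng, n_features=4):
    """Minimal frame with a level column and a few feature columns."""
    rows = []
    for lvl, c in counts.items():
        rows += [lvl] * c
    levels = np.array(rows)
    X = rng.standard_normal((len(levels), n_features))
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    df["level"] = levels
    df["stage"] = "N2"
    df["event_id"] = [f"e{i}" for i in range(len(df))]
    return df


def test_split_reproduces_published_sizes(rng):
    """14,512 events at 80/20 with ceiling test size: 2,903 / 11,609."""
    counts = {0: 980, 1: 3107, 2: 3384, 3: 3472, 4: 3569}
    df = _level_frame(counts, rng)
    split = split_dataset(df, 0.2, seed=0)
    assert len(split.test) == 2903
    assert len(split.train) == 11609


def test_split_is_disjoint_partition_and_deterministic(rng):
    df = _level_frame({0: 20, 1: 30, 2: 30}, rng)
    s1 = split_dataset(df, 0.2, seed=3)
    s2 = split_dataset(df, 0.2, seed=3)
    ids_train = set(s1.train["event_id"])
    ids_test = set(s1.test["event_id"])
    assert ids_train.isdisjoint(ids_test)
    assert ids_train | ids_test == set(df["event_id"])
    assert list(s1.train["event_id"]) == list(s2.train["event_id"])


def test_split_rejects_singleton_level(rng):
    df = _level_frame({0: 1, 1: 30, 2: 30}, rng)
    with pytest.raises(ValueError, match="fewer than 2"):
        split_dataset(df, 0.2, seed=0)


def test_smote_reaches_parity(rng):
    df = _level_frame({0: 10, 1: 100, 2: 100, 3: 100, 4: 100}, rng)
    out = oversample_minority(df, k_neighbors=5, seed=0, feature_cols=["f0", "f1", "f2", "f3"])
    assert (out["level"].value_counts() == 100).all()


def test_smote_synthetic_points_are_convex_combinations(rng):
    feats = ["f0", "f1"]
    df = _level_frame({0: 10, 1: 40}, rng, n_features=2)
    out = oversample_minority(df, k_neighbors=3, seed=1, feature_cols=feats)
    originals = df[df["level"] == 0][feats].to_numpy()
    synth = out[out["event_id"].str.startswith("synthetic:")][feats].to_numpy()
    assert len(synth) == 30
    for x in synth:
        found = False
        for i in range(len(originals)):
            for j in range(len(originals)):
                if i == j:
                    continue
                d = originals[j] - originals[i]
                r = x - originals[i]
                # x = p_i + u (p_j - p_i) with one consistent u in [0, 1]
                with np.errstate(divide="ignore", invalid="ignore"):
                    u = np.where(d != 0, r / d, np.nan)
                u_vals = u[~np.isnan(u)]
                if len(u_vals) and np.allclose(u_vals, u_vals[0], atol=1e-9):
                    if -1e-12 <= u_vals[0] <= 1 + 1e-12:
                        found = True
                        break
            if found:
                break
        assert found, f"synthetic point {x} is not on a segment between two parents"


def test_smote_balanced_input_unchanged(rng):
    df = _level_frame({0: 50, 1: 50}, rng)
    out = oversample_minority(df, feature_cols=["f0", "f1", "f2", "f3"])
    pd.testing.assert_frame_equal(out, df)


def test_smote_small_class_reduces_k(rng):
    df = _level_frame({0: 3, 1: 50}, rng)
    with pytest.warns(UserWarning, match="reducing SMOTE k"):
        out = oversample_minority(df, k_neighbors=5, seed=0, feature_cols=["f0", "f1", "f2", "f3"])
    assert (out["level"].value_counts() == 50).all()


def _informative_frame(rng, n=160, n_levels=4):
    """Two jointly necessary informative features among eight noise features.

    Levels 0..3 are encoded as (level // 2, level %% 2) across features f2 and
    f7, so neither feature alone separates more than two level pairs.
    """
    levels = np.tile(np.arange(n_levels), n // n_levels)
    X = rng.standard_normal((n, 10))
    X[:, 2] = (levels // 2) * 4.0 + 0.2 * rng.standard_normal(n)
    X[:, 7] = (levels % 2) * 4.0 + 0.2 * rng.standard_normal(n)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)])
    df["level"] = levels
    return df


def test_rfecv_keeps_informative_features(rng):
    df = _informative_frame(rng)
    selected, score = rfecv_select(
        df, "random_forest", cv_folds=5, seed=0, step=1, min_features=1,
        feature_cols=[f"f{i}" for i in range(10)],
    )
    assert {"f2", "f7"} <= set(selected)
    assert score > 0.95


def test_rfecv_single_feature_passthrough(rng):
    df = _informative_frame(rng)
    selected, _ = rfecv_select(df, "random_forest", feature_cols=["f2"])
    assert selected == ["f2"]


def test_rfecv_rejects_single_class(rng):
    df = _informative_frame(rng)
    df["level"] = 1
    with pytest.raises(ValueError, match="two intensity levels"):
        rfecv_select(df, "random_forest", feature_cols=["f0", "f1"])


def test_choose_stage_config_tie_prefers_random_forest(rng, monkeypatch):
    def fake_rfecv(train, kind, **kw):
        return (["f0", "f1"] if kind == "gradient_boosting" else ["f0"]), 0.9

    monkeypatch.setattr(models, "rfecv_select", fake_rfecv)
    spec = choose_stage_config(_informative_frame(rng), "N2", TrainConfig())
    assert spec.classifier_kind == "random_forest"
    assert spec.selected_features == ["f0"]


def test_choose_stage_config_argmax(rng, monkeypatch):
    def fake_rfecv(train, kind, **kw):
        return ["f0"], (0.95 if kind == "gradient_boosting" else 0.7)

    monkeypatch.setattr(models, "rfecv_select", fake_rfecv)
    spec = choose_stage_config(_informative_frame(rng), "REM", TrainConfig())
    assert spec.classifier_kind == "gradient_boosting"


def test_tune_and_fit_deterministic(rng):
    df = _informative_frame(rng, n=60)
    spec = StageModelSpec(
        stage="N2", classifier_kind="random_forest", selected_features=["f2", "f7"]
    )
    cfg = TrainConfig(n_trials=4, seed=2)
    m1 = tune_and_fit(df, spec, cfg)
    m2 = tune_and_fit(df, spec, cfg)
    assert m1.spec.hyperparameters == m2.spec.hyperparameters


def test_predict_levels_memorizes_training_data(rng):
    df = _informative_frame(rng)
    spec = StageModelSpec(
        stage="N2", classifier_kind="random_forest",
        selected_features=[f"f{i}" for i in range(10)],
    )
    est = make_estimator("random_forest", {"n_estimators": 200}, seed=0)
    est.fit(df[spec.selected_features].to_numpy(), df["level"].to_numpy())
    model = models.StageModel(spec=spec, estimator=est, classes=(0, 1, 2, 3))
    levels, scores = predict_levels(model, df)
    assert np.mean(levels == df["level"].to_numpy()) >= 0.99
    assert set(levels) <= {0, 1, 2, 3, 4}
    np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)


def test_predict_levels_names_missing_columns(rng):
    df = _informative_frame(rng)
    spec = StageModelSpec(
        stage="N2", classifier_kind="random_forest", selected_features=["f2", "nope"]
    )
    model = models.StageModel(spec=spec, estimator=None, classes=(0, 1))
    with pytest.raises(KeyError, match="nope"):
        predict_levels(model, df)


def test_model_fit_no_leakage_and_recovery(rng):
    """End-to-end on a constructed feature table: disjoint split, no test id
    in training, and near-perfect recovery of a strongly separable signal."""
    table = make_feature_frame(150, rng, stage="N2", level_effect=5.0)
    cfg = TrainConfig(n_trials=2, rfe_step=0.3, seed=0)
    results = ArousalIntensityModel(table, cfg).fit()
    assert results.train_event_ids.isdisjoint(results.test_event_ids)
    assert results.train_event_ids | results.test_event_ids == set(table["event_id"])
    assert not any(
        eid.startswith("synthetic:") for eid in results.test_event_ids
    )
    assert "N2" in results.models
    report = results.report
    sens = [m.sensitivity for m in report.stages["N2"]["metrics"] if m.sensitivity is not None]
    assert np.mean(sens) > 0.9
    text = results.summary()
    assert "N2" in text and "Total" in text
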