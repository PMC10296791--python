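"""Feature selection, classifier contracts, metrics and attribution."""

import numpy as np
import pandas as pd
import pytest

from cardioresp.models import (
    evaluate,
    explain,
    load_model,
    save_model,
    select_features,
    split_table,
    train_segment_classifier,
    train_subtype_classifier,
    youden_cutoff,
)
from cardioresp.types import SplitSpec


def _feature_table(rng, n_per_class=120):
    """Three classes; 'informative' shifts by 3 SD per class, 'noise' doesn't."""
    rows = []
    for ci, label in enumerate(["N", "H", "A"]):
        for _ in range(n_per_class):
            rows.append({
                "subject": f"S{rng.integers(0, 6)}",
                "start_s": 0.0, "label": label, "kind": label,
                "informative": rng.normal(3.0 * ci, 1.0),
                "noise": rng.normal(0.0, 1.0),
            })
    return pd.DataFrame(rows)


def test_select_features_keeps_signal_drops_null(rng):
    tbl = _feature_table(rng)
    sel = select_features(tbl, feature_cols=["informative", "noise"])
    assert "informative" in sel.retained
    assert sel.ranking.iloc[0]["feature"] == "informative"


def test_select_features_constant_feature_removed(rng):
    tbl = _feature_table(rng)
    tbl["flat"] = 1.0
    sel = select_features(tbl, feature_cols=["informative", "flat"])
    assert "flat" not in sel.retained
    row = sel.ranking.set_index("feature").loc["flat"]
    assert row["pvalue"] == 1.0


def test_train_eval_on_encoded_differences(rng):
    tbl = _feature_table(rng)
    model, report = train_segment_classifier(
        tbl, split=SplitSpec(seed=0), feature_cols=["informative", "noise"])
    assert report.macro_f1 > 0.8
    assert sorted(model.classes) == ["A", "H", "N"]


def test_train_missing_class_raises(rng):
    tbl = _feature_table(rng)
    tbl = tbl[tbl.label != "H"]
    tbl.loc[tbl.index[:1], "label"] = "H"  # present overall, absent from train side
    with pytest.raises(ValueError):
        train_segment_classifier(tbl, split=SplitSpec(seed=0, test_frac=0.5),
                                 feature_cols=["informative"])


def test_by_subject_split_never_leaks(rng):
    tbl = _feature_table(rng)
    train, test = split_table(tbl, SplitSpec(mode="by_subject", seed=1))
    assert set(train.subject).isdisjoint(set(test.subject))


def test_model_bundle_round_trip(tmp_path, rng):
    tbl = _feature_table(rng)
    model, _ = train_segment_classifier(
        tbl, split=SplitSpec(seed=0), feature_cols=["informative", "noise"])
    save_model(model, tmp_path / "bundle", meta={"config_hash": "abc"})
    clone, meta = load_model(tmp_path / "bundle")
    assert meta["config_hash"] == "abc"
    np.testing.assert_array_equal(clone.predict(tbl), model.predict(tbl))


def test_evaluate_perfect_predictions():
    rep = evaluate(["N", "H", "A"], ["N", "H", "A"])
    assert rep.accuracy == 1.0
    assert rep.macro_f1 == 1.0
    assert np.trace(rep.confusion) == 3


def test_evaluate_known_confusion_matrix():
    y_true = [1] * 10 + [0] * 10
    y_pred = [1] * 8 + [0] * 2 + [1] * 3 + [0] * 7
    rep = evaluate(y_true, y_pred, classes=[0, 1])
    assert rep.per_class["1"]["sensitivity"] == pytest.approx(0.8)
    assert rep.per_class["1"]["precision"] == pytest.approx(8 / 11)
    np.testing.assert_array_equal(rep.confusion, [[7, 3], [2, 8]])


def test_single_threshold_roc_auc_is_balanced_accuracy(rng):
    """Binary scores for a hard classifier give AUC = (sens + spec) / 2."""
    y = rng.integers(0, 2, size=200)
    pred = np.where(rng.random(200) < 0.8, y, 1 - y)  # noisy copy
    rep = evaluate(y, pred, classes=[0, 1], scores=pred.astype(float))
    sens = rep.per_class["1"]["sensitivity"]
    spec = rep.per_class["0"]["sensitivity"]
    assert rep.roc["auc"] == pytest.approx((sens + spec) / 2)


def test_youden_cutoff_on_separated_scores():
    y = np.array([1, 1, 0, 0])
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    cut = youden_cutoff(y, scores)
    assert 0.2 < cut <= 0.8


def test_subtype_classifier_perfectly_separable(rng):
    n, t = 60, 30
    y = rng.integers(0, 2, size=n)
    X = rng.normal(0, 0.3, size=(n, t)) + y[:, None] * 2.0
    model, report, cutoff = train_subtype_classifier(
        X, y, split=SplitSpec(seed=0, test_frac=0.3), hidden=8, epochs=120)
    assert report.roc["auc"] == 1.0
    assert 0.0 < cutoff <= 1.0


def test_explain_ranks_informative_feature_first(rng):
    tbl = _feature_table(rng)
    for k in range(9):
        tbl[f"noise{k}"] = rng.normal(size=len(tbl))
    cols = ["informative"] + [f"noise{k}" for k in range(9)]
    model, _ = train_segment_classifier(tbl, split=SplitSpec(seed=0), feature_cols=cols)
    attribution = explain(model, tbl)
    assert attribution.iloc[0]["feature"] == "informative"
    assert attribution.attrs["method"] == "treeshap"


def test_explain_efficiency_property(rng):
    """Per-row attributions (plus bias) sum to the margin prediction."""
    import xgboost as xgb

    tbl = _feature_table(rng)
    cols = ["informative", "noise"]
    model, _ = train_segment_classifier(tbl, split=SplitSpec(seed=0), feature_cols=cols)
    attribution = explain(model, tbl)
    contribs = attribution.attrs["attributions"]
    X = model._matrix(tbl)
    margins = model.estimator.get_booster().predict(
        xgb.DMatrix(X, feature_names=cols), output_margin=True)
    np.testing.assert_allclose(contribs.sum(axis=-1), margins, rtol=1e-4, atol=1e-4)


def test_explain_permutation_fallback_for_plain_tree(rng):
    tbl = _feature_table(rng)
    model, _ = train_segment_classifier(
        tbl, model="decision_tree", split=SplitSpec(seed=0),
        feature_cols=["informative", "noise"])
    with pytest.warns(UserWarning, match="permutation"):
        attribution = explain(model, tbl)
    assert attribution.attrs["method"] == "permutation"
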