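"""Rule labeler, feature matrix hygiene, and the cross-validated SVM."""

import numpy as np
import pandas as pd
import pytest

from orgwave.calcium import analyze_trace
from orgwave.classify import (
    FEATURE_COLUMNS,
    MorphologyLabel,
    abnormality_by_region,
    build_feature_matrix,
    rule_label,
    train_evaluate_svm,
)
from orgwave.synthetic import generate_trace


@pytest.mark.parametrize("kind,rule", [
    ("bifid", "bifid_multispike"),
    ("plateau_uptake", "plateau_uptake"),
    ("early_second_upstroke", "rising_uptake_early_upstroke"),
    ("spontaneous_release", "spontaneous_release"),
])
@pytest.mark.parametrize("group", ["control", "dox"])
def test_each_morphology_triggers_its_rule(kind, rule, group, control_ca, dox_ca):
    base = control_ca if group == "control" else dox_ca
    params = base if kind == "spontaneous_release" else base.scaled(1.3)
    tr, _ = generate_trace(params, n_beats=6, noise_sd=0.0, drift="none",
                           abnormality=kind, seed=3)
    det, _, feats, _ = analyze_trace(tr.values, tr.dt_ms)
    lab = rule_label(det, tr.dt_ms, feats)
    assert lab.label == "abnormal"
    assert rule in lab.triggered_rules


@pytest.mark.parametrize("group", ["control", "dox"])
def test_clean_normal_trace_triggers_nothing(group, control_ca, dox_ca):
    params = control_ca if group == "control" else dox_ca
    tr, _ = generate_trace(params, n_beats=6, noise_sd=0.0, drift="none", seed=4)
    det, _, feats, _ = analyze_trace(tr.values, tr.dt_ms)
    lab = rule_label(det, tr.dt_ms, feats)
    assert lab.label == "normal"
    assert lab.triggered_rules == ()


def test_labeler_agrees_with_ground_truth_on_clean_scenes():
    """>= 99% agreement with generator labels on noise-free scenes."""
    from orgwave.presets import CONTROL, DOX
    from orgwave.synthetic import generate_scene

    hits = total = 0
    for preset, seed in [(CONTROL, 51), (DOX, 52)]:
        scene = generate_scene(preset, n_cells=60, seed=seed, noise=False, drift="none")
        gt = scene.ground_truth.set_index("cell_id")
        for tr in scene.traces.traces("calcium"):
            det, _, feats, summary = analyze_trace(tr.values, tr.dt_ms)
            if not summary.quantifiable:
                continue
            lab = rule_label(det, tr.dt_ms, feats, cell_id=tr.cell_id)
            total += 1
            hits += (lab.label == "abnormal") == (gt.loc[tr.cell_id, "abnormality"] != "normal")
    assert total > 80
    assert hits / total >= 0.99


def test_label_consistency_is_enforced():
    with pytest.raises(ValueError):
        MorphologyLabel(cell_id="c", label="abnormal", triggered_rules=())


def _toy_summaries(n=60, seed=0, separation=4.0):
    rng = np.random.default_rng(seed)
    half = n // 2
    rows = []
    for i in range(n):
        abnormal = i >= half
        base = separation if abnormal else 0.0
        row = {c: base + rng.normal() for c in FEATURE_COLUMNS}
        row["label"] = "abnormal" if abnormal else "normal"
        row["cell_id"] = f"c{i}"
        rows.append(row)
    return pd.DataFrame(rows)


def test_identical_summaries_give_identical_feature_rows():
    df = _toy_summaries(n=24, separation=0.0)
    df.loc[1, FEATURE_COLUMNS] = df.loc[0, FEATURE_COLUMNS]
    X, _ = build_feature_matrix(df)
    np.testing.assert_allclose(X.iloc[0].to_numpy(dtype=float),
                               X.iloc[1].to_numpy(dtype=float))


def test_single_class_input_is_rejected():
    df = _toy_summaries(n=30)
    df["label"] = "normal"
    with pytest.raises(ValueError, match="both classes"):
        build_feature_matrix(df)


def test_standardization_uses_training_folds_only():
    """Refit-per-fold oracle: scaler statistics come from the training
    split, so the training columns are standardized and the test columns
    reuse those statistics."""
    from sklearn.model_selection import StratifiedKFold
    from sklearn.preprocessing import StandardScaler

    df = _toy_summaries(n=40, separation=1.0)
    X, y = build_feature_matrix(df)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
    train_idx, test_idx = next(skf.split(X, y))
    scaler = StandardScaler().fit(X.to_numpy()[train_idx])
    z_train = scaler.transform(X.to_numpy()[train_idx])
    np.testing.assert_allclose(z_train.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(z_train.std(axis=0), 1.0, atol=1e-9)
    z_test = scaler.transform(X.to_numpy()[test_idx])
    manual = (X.to_numpy()[test_idx] - scaler.mean_) / scaler.scale_
    np.testing.assert_allclose(z_test, manual)


def test_separable_classes_reach_perfect_accuracy():
    df = _toy_summaries(n=80, separation=8.0)
    X, y = build_feature_matrix(df)
    rep = train_evaluate_svm(X.to_numpy(), y, seed=0)
    assert rep.accuracy == 1.0
    assert rep.roc_auc == 1.0
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0


def test_permuted_labels_fall_to_chance():
    """With labels shuffled, accuracy sits inside the binomial 99% band
    around the majority-class rate."""
    rng = np.random.default_rng(0)
    df = _toy_summaries(n=200, separation=6.0)
    X, y = build_feature_matrix(df)
    y_perm = rng.permutation(y)
    rep = train_evaluate_svm(X.to_numpy(), y_perm, seed=0)
    p0 = max(y_perm.mean(), 1 - y_perm.mean())
    band = 2.58 * np.sqrt(p0 * (1 - p0) / len(y_perm))
    assert rep.accuracy <= p0 + band + 0.02


def test_roc_auc_equals_mann_whitney_oracle():
    """Pooled out-of-fold AUC equals the brute-force pairwise statistic."""
    df = _toy_summaries(n=120, separation=1.5)
    X, y = build_feature_matrix(df)
    rep = train_evaluate_svm(X.to_numpy(), y, seed=1)
    scores = rep.oof_scores
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    mw = wins / (len(pos) * len(neg))
    assert rep.roc_auc == pytest.approx(mw, abs=1e-9)


def test_confusion_matrix_identities_hold():
    df = _toy_summaries(n=100, separation=1.0)
    X, y = build_feature_matrix(df)
    rep = train_evaluate_svm(X.to_numpy(), y, seed=2)
    assert rep.tp + rep.fp + rep.tn + rep.fn == len(y)
    assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
    assert rep.specificity == pytest.approx(rep.tn / (rep.tn + rep.fp))
    assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / len(y))


def test_fixed_seed_reproduces_the_report():
    df = _toy_summaries(n=80, separation=1.0)
    X, y = build_feature_matrix(df)
    a = train_evaluate_svm(X.to_numpy(), y, seed=3)
    b = train_evaluate_svm(X.to_numpy(), y, seed=3)
    assert a.selected_c == b.selected_c
    assert a.accuracy == b.accuracy
    np.testing.assert_array_equal(a.oof_predictions, b.oof_predictions)


def test_roc_curve_is_monotone():
    df = _toy_summaries(n=100, separation=1.0)
    X, y = build_feature_matrix(df)
    rep = train_evaluate_svm(X.to_numpy(), y, seed=4)
    assert np.all(np.diff(rep.roc_fpr) >= 0)
    assert np.all(np.diff(rep.roc_tpr) >= 0)


def test_abnormal_fractions_match_census_oracle():
    labels = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(8)],
        "region": ["Close"] * 4 + ["Mid"] * 3 + ["Far"],
        "label": ["abnormal", "normal", "abnormal", "normal",
                  "abnormal", "abnormal", "abnormal", "normal"],
    })
    out = abnormality_by_region(labels)
    by = out.set_index("region")
    assert by.loc["Close", "fraction_abnormal"] == pytest.approx(0.5)
    assert by.loc["Mid", "fraction_abnormal"] == pytest.approx(1.0)
    assert by.loc["Far", "fraction_abnormal"] == pytest.approx(0.0)
    assert by.loc["Center", "n_cells"] == 0


def test_all_normal_scene_has_zero_abnormal_fractions():
    labels = pd.DataFrame({
        "cell_id": ["a", "b"], "region": ["Close", "Far"],
        "label": ["normal", "normal"],
    })
    out = abnormality_by_region(labels)
    assert (out["fraction_abnormal"].dropna() == 0).all()
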