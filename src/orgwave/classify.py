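"""Abnormal calcium-transient classification.

A deterministic rule labeler transcribes the expert criteria for
arrhythmia-prone morphology — bifid/multi-spiked peaks, a plateau during
uptake, a second upstroke before complete decay, and spontaneous
inter-peak release — into explicit thresholds, and stands in for expert
consensus.  An RBF-kernel SVM is then trained on per-cell averaged
transient features under stratified 10-fold cross-validation with a grid
search over the regularization parameter C, and reported through a
pooled out-of-fold confusion matrix, sensitivity / specificity /
accuracy, and an ROC curve from decision scores (abnormal = positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter
from sklearn.metrics import roc_curve, auc as sk_auc
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from orgwave.calcium import TransientFeatures

DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
DEFAULT_FOLDS = 10

RULE_NAMES = (
    "bifid_multispike",
    "plateau_uptake",
    "rising_uptake_early_upstroke",
    "spontaneous_release",
)

FEATURE_COLUMNS = [
    "amplitude_au",
    "time_to_peak_ms",
    "interpeak_ms",
    "width20_ms",
    "left_width20_ms",
    "right_width20_ms",
    "max_slope_aupms",
    "auc_aums",
    "frequency_hz",
]


@dataclass(frozen=True)
class RuleThresholds:
    """Numeric thresholds behind the morphological rules."""

    secondary_max_frac: float = 0.2  # intra-transient maxima above this fraction
    plateau_slope_frac: float = 0.05  # |derivative| below this fraction of max rise
    plateau_rise_frac: float = 0.25  # sustained for this fraction of the rise
    early_decay_frac: float = 0.40  # next rise while still above this fraction
    spont_noise_mult: float = 3.0  # lower prominence bound, in noise SDs


@dataclass
class MorphologyLabel:
    cell_id: str
    label: str  # normal | abnormal
    triggered_rules: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.label == "abnormal") != bool(self.triggered_rules):
            raise ValueError("label must be abnormal iff any rule triggered")


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise SD from second differences (MAD-based).

    Second differences cancel locally linear signal content, so the
    estimate tracks frame noise rather than transient slopes even at
    high duty cycles; for white noise their SD is sqrt(6) times the
    per-sample SD.
    """
    d = np.diff(np.asarray(values, dtype=float), n=2)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(6.0))


def _smooth(values: np.ndarray) -> np.ndarray:
    if len(values) < 7:
        return values
    return savgol_filter(values, 7, 2)


def rule_label(values: np.ndarray, dt_ms: float,
               features: list[TransientFeatures], cell_id: str = "cell",
               thresholds: RuleThresholds = RuleThresholds(),
               noise_sd: float | None = None) -> MorphologyLabel:
    """Evaluate the four morphology rules on a detrended trace.

    Rules operate on a lightly smoothed copy of the trace so that single
    noise samples cannot mimic morphology; thresholds reference the raw
    noise SD estimated from first differences.
    """
    values = np.asarray(values, dtype=float)
    good = [f for f in features if not f.flagged]
    if not good:
        raise ValueError(f"cell {cell_id!r} has no quantifiable transient")
    # rules needing only apex/amplitude use every measured peak; rules that
    # need clean 20% crossings (support, rise) use the unflagged ones
    measured = [f for f in features if f.amplitude_au > 0]
    sd = estimate_noise_sd(values) if noise_sd is None else noise_sd
    smooth = _smooth(values)
    heavy = savgol_filter(values, 9, 2) if len(values) >= 9 else smooth
    light = savgol_filter(values, 5, 2) if len(values) >= 5 else values
    triggered: set[str] = set()
    floor = np.quantile(smooth, 0.05)
    quiet = smooth[smooth <= floor + 4.0 * sd + 1e-12]
    baseline0 = float(np.median(quiet)) if len(quiet) else float(smooth.min())
    global_span = float(smooth.max() - baseline0)
    spont_gaps = 0
    plateau_beats = 0

    for f in good:
        i0 = int(round(f.left_cross_ms / dt_ms))
        i1 = int(round(f.right_cross_ms / dt_ms))
        apex = int(round(f.peak_time_ms / dt_ms))

        # 1) bifid / multi-spiked: >= 2 intra-transient maxima above 20%
        seg = smooth[i0 : i1 + 1]
        if len(seg) >= 3:
            level = f.baseline_au + thresholds.secondary_max_frac * f.amplitude_au
            prom = max(3.0 * sd, 0.05 * f.amplitude_au)
            maxima, _ = find_peaks(seg, height=level, prominence=prom)
            if len(maxima) >= 2:
                triggered.add("bifid_multispike")

        # 2) plateau during uptake: some stretch of at least 25% of the
        #    rise over which the signal barely increases.  Window-total
        #    increases on a heavily smoothed copy are robust to frame
        #    noise, unlike pointwise derivatives; the bound is the tighter
        #    of 5% of the max rise slope sustained over the window and 2%
        #    of the amplitude.
        rise_n = apex - i0
        if rise_n >= 4 and f.max_slope_aupms > 0:
            m = max(2, int(np.ceil(thresholds.plateau_rise_frac * rise_n)))
            seg_rise = heavy[i0 : apex + 1]
            if len(seg_rise) > m:
                increase = np.abs(seg_rise[m:] - seg_rise[:-m])
                bound = min(
                    thresholds.plateau_slope_frac * f.max_slope_aupms * m * dt_ms,
                    0.02 * f.amplitude_au,
                )
                if np.min(increase) < bound:
                    plateau_beats += 1

        # 4) spontaneous release: an inter-transient bump.  A bump must
        #    both rise above the running minimum of the diastolic stretch
        #    and fall back by a comparable amount, which separates it
        #    from the sub-threshold foot of the next transient (rise
        #    without return) and keeps its full size even when it rides
        #    the decaying tail.  A single noisy gap can mimic a small
        #    bump, so the rule asks for corroboration in a second gap.
        nxt = next((g for g in good if g.peak_time_ms > f.peak_time_ms), None)
        if nxt is not None:
            j0 = int(round(f.right_cross_ms / dt_ms))
            j1 = int(round(nxt.left_cross_ms / dt_ms))
            if j1 - j0 >= 6:
                gap = light[j0 : j1 + 1]
                maxima, _ = find_peaks(gap)
                excursion = 0.0
                for p_ in maxima:
                    if p_ < 1:
                        continue
                    rise = float(gap[p_] - gap[:p_].min())
                    fall = float(gap[p_] - gap[p_:].min())
                    excursion = max(excursion, min(rise, fall))
                lo = max(thresholds.spont_noise_mult * sd, 0.05 * global_span)
                hi = 0.2 * global_span
                if lo < excursion < hi:
                    spont_gaps += 1

    # plateau and spontaneous release recur on every beat, so both ask
    # for corroboration on a second beat before labelling the cell
    if plateau_beats >= 2:
        triggered.add("plateau_uptake")
    if spont_gaps >= 2:
        triggered.add("spontaneous_release")

    # 3) early second upstroke: the signal never returns below 40% of a
    #    peak's amplitude before the next apex (evaluated on all measured
    #    peaks, since overlapping transients defeat width measurement)
    measured = sorted(measured, key=lambda f: f.peak_time_ms)
    for f, g in zip(measured, measured[1:]):
        a0 = int(round(f.peak_time_ms / dt_ms))
        a1 = int(round(g.peak_time_ms / dt_ms))
        gap = smooth[a0 : a1 + 1]
        floor = f.baseline_au + thresholds.early_decay_frac * f.amplitude_au
        if len(gap) >= 3 and gap.min() > floor:
            triggered.add("rising_uptake_early_upstroke")

    label = "abnormal" if triggered else "normal"
    return MorphologyLabel(cell_id=cell_id, label=label,
                           triggered_rules=tuple(sorted(triggered)))


def build_feature_matrix(summaries: pd.DataFrame,
                         labels: pd.Series | None = None,
                         min_cells: int = 20) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell feature table and binary label vector (abnormal = 1).

    Features are returned raw; standardization happens inside the
    cross-validation loop using training-fold statistics only, so no
    information leaks from the held-out folds.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in summaries.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    if labels is None:
        if "label" not in summaries.columns:
            raise ValueError("labels are required (column 'label' or explicit vector)")
        labels = summaries["label"]
    X = summaries[FEATURE_COLUMNS].copy()
    keep = X.notna().all(axis=1).to_numpy()
    X = X.loc[keep].reset_index(drop=True)
    y = (pd.Series(labels).loc[keep] == "abnormal").to_numpy().astype(int)
    if len(X) < min_cells:
        raise ValueError(f"at least {min_cells} quantifiable cells are required")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train")
    return X, y


@dataclass
class ClassifierReport:
    """Cross-validated SVM performance (abnormal = positive class)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_auc: float
    selected_c: float
    fold_accuracies: list[float]
    grid_accuracies: dict[float, float] = field(default_factory=dict)
    oof_scores: np.ndarray | None = None
    oof_predictions: np.ndarray | None = None


def train_evaluate_svm(X, y, c_grid=DEFAULT_C_GRID, seed: int = 0,
                       n_folds: int = DEFAULT_FOLDS) -> ClassifierReport:
    """Stratified k-fold CV with a C grid search for an RBF SVM.

    The best C maximizes the mean CV accuracy over the shared folds (ties
    break toward the smaller C); the report pools the out-of-fold
    predictions and decision scores of that C into one confusion matrix
    and ROC curve.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    def fit_predict(c: float):
        preds = np.empty(len(y), dtype=int)
        scores = np.empty(len(y), dtype=float)
        fold_acc = []
        for train_idx, test_idx in folds:
            if len(np.unique(y[train_idx])) < 2:
                raise ValueError("degenerate fold: a training fold lost a class")
            model = make_pipeline(StandardScaler(), SVC(C=c, kernel="rbf"))
            model.fit(X[train_idx], y[train_idx])
            p = model.predict(X[test_idx])
            preds[test_idx] = p
            scores[test_idx] = model.decision_function(X[test_idx])
            fold_acc.append(float(np.mean(p == y[test_idx])))
        return preds, scores, fold_acc

    grid_acc: dict[float, float] = {}
    cache: dict[float, tuple] = {}
    for c in c_grid:
        preds, scores, fold_acc = fit_predict(c)
        grid_acc[c] = float(np.mean(fold_acc))
        cache[c] = (preds, scores, fold_acc)
    best_c = max(grid_acc, key=lambda c: (grid_acc[c], -c))
    preds, scores, fold_acc = cache[best_c]

    tp = int(np.sum((preds == 1) & (y == 1)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    fpr, tpr, _ = roc_curve(y, scores)
    return ClassifierReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        accuracy=(tp + tn) / len(y),
        roc_fpr=fpr, roc_tpr=tpr, roc_auc=float(sk_auc(fpr, tpr)),
        selected_c=float(best_c),
        fold_accuracies=fold_acc,
        grid_accuracies=grid_acc,
        oof_scores=scores,
        oof_predictions=preds,
    )


def abnormality_by_region(labels: pd.DataFrame,
                          region_column: str = "region") -> pd.DataFrame:
    """Fraction of abnormal cells per region (n = 0 regions included)."""
    from orgwave.presets import REGIONS

    rows = []
    for region in REGIONS:
        sub = labels[labels[region_column] == region]
        n = len(sub)
        k = int((sub["label"] == "abnormal").sum()) if n else 0
        rows.append(
            {
                "region": region,
                "n_cells": n,
                "n_abnormal": k,
                "fraction_abnormal": k / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
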