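"""End-to-end orchestration: from a scene (or trace tables) to the full
report bundle — per-cell calcium and beat features, regional tables,
synchrony, morphology labels, SVM report and group statistics.

The bundle is deterministic for a fixed configuration and seed; every
output is a DataFrame (written as CSV) or a JSON-serializable dict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from orgwave import __version__
from orgwave.calcium import analyze_trace
from orgwave.classify import (
    ClassifierReport,
    abnormality_by_region,
    build_feature_matrix,
    rule_label,
    train_evaluate_svm,
)
from orgwave.contractility import (
    beating_census,
    compute_motion_signals,
    normalize_to_period,
    segment_beats,
    summarize_beats,
)
from orgwave.io import TraceSet, write_trace_table
from orgwave.spatial import (
    RegionMap,
    aggregate_by_region,
    assign_region,
    heatmap_table,
    region_map_from_rois,
    synchrony_table,
)
from orgwave.synthetic import Scene, generate_scene

CALCIUM_METRICS = [
    "amplitude_au", "time_to_peak_ms", "interpeak_ms", "width20_ms",
    "left_width20_ms", "right_width20_ms", "max_slope_aupms", "auc_aums",
    "frequency_hz",
]
BEAT_METRICS = ["systole_s", "diastole_s", "beat_duration_s", "period_s",
                "amplitude_au", "frequency_hz"]


@dataclass
class RunBundle:
    """All tables produced by one pipeline run."""

    calcium_cells: pd.DataFrame
    beat_cells: pd.DataFrame
    calcium_by_region: pd.DataFrame
    beats_by_region: pd.DataFrame
    beating: pd.DataFrame
    synchrony: pd.DataFrame
    labels: pd.DataFrame
    abnormal_by_region: pd.DataFrame
    heatmaps: dict[str, pd.DataFrame]
    classifier: ClassifierReport | None
    config: dict


def analyze_scene(scene: Scene, *, config: dict | None = None,
                  train_classifier: bool = True,
                  classifier_seed: int = 0) -> RunBundle:
    """Run the full analysis chain on a synthetic scene."""
    cfg = {
        "calcium": {"drift_window_ms": 4000.0, "prominence": 0.2,
                    "min_separation_ms": 200.0},
        "contract": {"threshold_frac": 0.1, "window_s": 3.0},
        "spatial": {"max_lag_s": 2.0},
        "ml": {"folds": 10, "seed": classifier_seed},
        "seed": scene.seed,
        "version": __version__,
    }
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and k in cfg:
                cfg[k].update(v)
            else:
                cfg[k] = v

    rmap = region_map_from_rois(scene.rois)
    positions = {r.cell_id: (r.x_um, r.y_um) for r in scene.rois}

    ca_rows, label_rows = [], []
    for tr in scene.traces.traces("calcium"):
        try:
            detrended, apexes, feats, summary = analyze_trace(
                tr.values, tr.dt_ms,
                cell_id=tr.cell_id,
                drift_window_ms=cfg["calcium"]["drift_window_ms"],
                min_prominence_frac=cfg["calcium"]["prominence"],
                min_separation_ms=cfg["calcium"]["min_separation_ms"],
            )
        except ValueError as exc:
            raise RuntimeError(f"calcium stage failed for cell {tr.cell_id!r}") from exc
        region = assign_region(tr.position_um, rmap)
        row = {"cell_id": tr.cell_id, "x_um": tr.position_um[0],
               "y_um": tr.position_um[1], "region": region,
               "n_peaks": summary.n_peaks, "quantifiable": summary.quantifiable}
        for m in CALCIUM_METRICS:
            row[m] = getattr(summary, m)
        ca_rows.append(row)
        if summary.quantifiable:
            lab = rule_label(detrended, tr.dt_ms, feats, cell_id=tr.cell_id)
            label_rows.append({"cell_id": tr.cell_id, "region": region,
                               "label": lab.label,
                               "triggered_rules": "|".join(lab.triggered_rules)})

    beat_summaries = []
    beat_rows = []
    ratio_rows = []
    for tr in scene.traces.traces("motion"):
        signals = compute_motion_signals(tr.values)
        beats = segment_beats(signals.amplitude, tr.dt_ms / 1000.0,
                              threshold_frac=cfg["contract"]["threshold_frac"],
                              window_s=cfg["contract"]["window_s"])
        region = assign_region(tr.position_um, rmap)
        summary = summarize_beats(beats, cell_id=tr.cell_id, region=region)
        beat_summaries.append(summary)
        row = {"cell_id": tr.cell_id, "region": region, "n_beats": summary.n_beats,
               "beating": summary.beating}
        for m in BEAT_METRICS:
            row[m] = getattr(summary, m)
        ratios = normalize_to_period(beats)
        if len(ratios):
            row["systole_ratio"] = float(ratios["systole_ratio"].mean())
            row["diastole_ratio"] = float(ratios["diastole_ratio"].mean())
            row["beat_ratio"] = float(ratios["beat_ratio"].mean())
        beat_rows.append(row)

    ca_cells = pd.DataFrame(ca_rows)
    beat_cells = pd.DataFrame(beat_rows)
    labels = pd.DataFrame(label_rows)

    surrounding_ca = ca_cells[ca_cells["cell_id"] != "organoid"]
    ca_by_region = aggregate_by_region(ca_cells, CALCIUM_METRICS)
    beats_by_region = aggregate_by_region(
        beat_cells[beat_cells["beating"]], BEAT_METRICS)
    census = beating_census([s for s in beat_summaries if s.cell_id != "organoid"]) \
        if len(beat_summaries) > 1 else beating_census(beat_summaries)
    try:
        synchrony = synchrony_table(scene.traces, "calcium",
                                    max_lag_s=cfg["spatial"]["max_lag_s"])
    except ValueError as exc:
        raise RuntimeError(f"synchrony stage failed: {exc}") from exc
    abn_region = abnormality_by_region(labels) if len(labels) else pd.DataFrame()

    heatmaps = {
        m: heatmap_table(ca_cells, m) for m in ("width20_ms", "max_slope_aupms")
    }

    classifier = None
    if train_classifier and len(labels) >= 20:
        merged = ca_cells.merge(labels[["cell_id", "label"]], on="cell_id")
        merged = merged[merged["quantifiable"]]
        try:
            X, y = build_feature_matrix(merged)
            classifier = train_evaluate_svm(
                X.to_numpy(), y, seed=cfg["ml"]["seed"], n_folds=cfg["ml"]["folds"])
        except ValueError:
            classifier = None

    return RunBundle(
        calcium_cells=ca_cells,
        beat_cells=beat_cells,
        calcium_by_region=ca_by_region,
        beats_by_region=beats_by_region,
        beating=census,
        synchrony=synchrony,
        labels=labels,
        abnormal_by_region=abn_region,
        heatmaps=heatmaps,
        classifier=classifier,
        config=cfg,
    )


def write_bundle(bundle: RunBundle, outdir: str | Path) -> None:
    """Write every bundle table as CSV plus a JSON report and run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "calcium_cells.csv": bundle.calcium_cells,
        "beat_cells.csv": bundle.beat_cells,
        "calcium_by_region.csv": bundle.calcium_by_region,
        "beats_by_region.csv": bundle.beats_by_region,
        "beating_census.csv": bundle.beating,
        "synchrony.csv": bundle.synchrony,
        "labels.csv": bundle.labels,
        "abnormal_by_region.csv": bundle.abnormal_by_region,
    }
    for name, frame in tables.items():
        frame.to_csv(outdir / name, index=False, float_format="%.10g")
    for metric, frame in bundle.heatmaps.items():
        frame.to_csv(outdir / f"heatmap_{metric}.csv", index=False,
                     float_format="%.10g")
    report = {"config": bundle.config}
    if bundle.classifier is not None:
        c = bundle.classifier
        report["classifier"] = {
            "confusion": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
            "sensitivity": c.sensitivity,
            "specificity": c.specificity,
            "accuracy": c.accuracy,
            "roc_auc": c.roc_auc,
            "selected_c": c.selected_c,
            "fold_accuracies": c.fold_accuracies,
            "grid_accuracies": {str(k): v for k, v in c.grid_accuracies.items()},
            "roc_points": [
                {"fpr": float(f), "tpr": float(t)}
                for f, t in zip(c.roc_fpr, c.roc_tpr)
            ],
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def labeled_benchmark(n_cells_per_group: int = 500, seed: int = 0,
                      presets: dict | None = None) -> pd.DataFrame:
    """Rule-labeled per-cell feature table across control and dox scenes.

    The default benchmark pools one scene per condition with the cell
    count overridden, analyzes every calcium trace, labels it with the
    morphology rules, and returns the merged feature/label table used to
    train and evaluate the SVM.
    """
    from orgwave.presets import PRESETS

    presets = presets or PRESETS
    frames = []
    for offset, (name, preset) in enumerate(sorted(presets.items())):
        scene = generate_scene(preset, n_cells=n_cells_per_group,
                               seed=seed + 1000 * offset)
        bundle = analyze_scene(scene, train_classifier=False)
        merged = bundle.calcium_cells.merge(
            bundle.labels[["cell_id", "label"]], on="cell_id")
        merged = merged[merged["quantifiable"] & (merged["cell_id"] != "organoid")]
        merged.insert(0, "group", name)
        merged["cell_id"] = name + "_" + merged["cell_id"]
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(scene: Scene, outdir: str | Path | None = None,
                 config: dict | None = None, classifier_seed: int = 0) -> RunBundle:
    """Analyze a scene and optionally write the bundle to ``outdir``."""
    bundle = analyze_scene(scene, config=config, classifier_seed=classifier_seed)
    if outdir is not None:
        write_bundle(bundle, outdir)
        write_trace_table(scene.traces, Path(outdir) / "traces.csv")
    return bundle
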