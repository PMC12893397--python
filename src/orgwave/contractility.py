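"""Contractility analysis from brightfield motion.

Two signals are derived from a recording: ``speed`` (mean absolute
difference between consecutive frames — how fast the tissue is moving)
and ``amplitude`` (mean absolute difference from an automatically chosen
resting reference frame — how far the tissue is deformed).  Beats are
segmented from the amplitude signal with a dynamic threshold that tracks
local baseline shifts; each beat yields systole (onset to apex),
diastole (apex to offset), beat duration (their sum) and the apex-to-apex
period, optionally normalized to the period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

DEFAULT_THRESHOLD_FRAC = 0.1
DEFAULT_WINDOW_S = 3.0
DEFAULT_MIN_SEPARATION_S = 0.2
_REFERENCE_NEIGHBORS = 10
_CROSSING_DEBOUNCE = 2
#: a recording is considered non-beating unless its amplitude range
#: clears this many noise SDs
_RESOLVABLE_SNR = 6.0


@dataclass
class MotionSignals:
    """Frame-differencing signals for one ROI."""

    speed: np.ndarray  # length n_frames - 1
    amplitude: np.ndarray  # length n_frames
    reference_index: int


@dataclass
class BeatFeatures:
    """One segmented beat (times in seconds)."""

    onset_s: float
    apex_s: float
    offset_s: float
    systole_s: float
    diastole_s: float
    beat_duration_s: float
    period_s: float | None
    amplitude_au: float


@dataclass
class CellBeatSummary:
    cell_id: str
    n_beats: int
    systole_s: float
    diastole_s: float
    beat_duration_s: float
    period_s: float
    amplitude_au: float
    frequency_hz: float
    beating: bool
    region: str | None = None


def _roi_series(stack: np.ndarray, roi_mask: np.ndarray | None) -> np.ndarray:
    if roi_mask is None:
        return stack.reshape(len(stack), -1)
    return stack.reshape(len(stack), -1)[:, roi_mask.ravel()]


def compute_motion_signals(data: np.ndarray, roi_mask: np.ndarray | None = None,
                           reference: str | int = "auto") -> MotionSignals:
    """Speed and amplitude signals from a stack or a 1D motion trace.

    The reference frame is chosen automatically as the frame minimizing
    the summed absolute difference to its 10 temporal neighbours among
    the lowest-quintile speed frames (the resting phase); pass an integer
    to pin it explicitly.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        frames = data[:, None]
    elif data.ndim == 3:
        frames = _roi_series(data, roi_mask)
    else:
        raise ValueError("data must be a 1D trace or a (frames, rows, cols) stack")
    n = len(frames)
    if n < 3:
        raise ValueError("at least 3 frames are required")
    speed = np.abs(np.diff(frames, axis=0)).mean(axis=1)

    if reference == "auto":
        order = np.argsort(speed, kind="stable")
        quintile = max(1, len(speed) // 5)
        candidates = np.unique(np.concatenate([order[:quintile], order[:quintile] + 1]))
        candidates = candidates[candidates < n]
        best, best_cost = int(candidates[0]), np.inf
        half = _REFERENCE_NEIGHBORS // 2
        for c in candidates:
            lo, hi = max(0, c - half), min(n, c + half + 1)
            cost = np.abs(frames[lo:hi] - frames[c]).mean(axis=1).sum()
            if cost < best_cost:
                best, best_cost = int(c), cost
        ref = best
    else:
        ref = int(reference)
    amplitude = np.abs(frames - frames[ref]).mean(axis=1)
    return MotionSignals(speed=speed, amplitude=amplitude, reference_index=ref)


def _rolling_threshold(amplitude: np.ndarray, dt_s: float, window_s: float,
                       threshold_frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Dynamic threshold curve: local baseline + frac * local span."""
    win = max(3, int(round(window_s / dt_s)))
    series = pd.Series(amplitude)
    base = series.rolling(win, center=True, min_periods=1).quantile(0.10).to_numpy()
    peak = series.rolling(win, center=True, min_periods=1).max().to_numpy()
    thr = base + threshold_frac * (peak - base)
    return thr, base


def segment_beats(amplitude: np.ndarray, dt_s: float,
                  threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
                  window_s: float = DEFAULT_WINDOW_S,
                  min_separation_s: float = DEFAULT_MIN_SEPARATION_S) -> list[BeatFeatures]:
    """Segment beats from an amplitude signal with dynamic thresholding.

    Apexes are local maxima above the rolling threshold; onsets/offsets
    are the threshold crossings bracketing each apex (linear
    interpolation, two-sample debounce).  Beats whose onset or offset
    falls outside the recording or collides with a neighbouring apex are
    dropped.  An empty list marks a non-beating cell.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    d = np.diff(amplitude)
    noise_sd = float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))
    global_span = float(np.quantile(amplitude, 0.99) - np.quantile(amplitude, 0.10))
    if global_span <= _RESOLVABLE_SNR * noise_sd or global_span <= 0:
        return []  # indistinguishable from noise: non-beating
    thr, base = _rolling_threshold(amplitude, dt_s, window_s, threshold_frac)
    distance = max(1, int(round(min_separation_s / dt_s)))
    span = amplitude - thr
    # the prominence floor keeps noise bumps in quiet stretches (where the
    # local threshold collapses) from registering as beats
    prom_floor = max(0.25 * global_span, 4.0 * noise_sd)
    apexes, _ = find_peaks(span, height=0.0, distance=distance,
                           prominence=prom_floor)
    beats: list[BeatFeatures] = []
    for idx, apex in enumerate(apexes):
        lo = apexes[idx - 1] if idx > 0 else 0
        hi = apexes[idx + 1] if idx + 1 < len(apexes) else len(amplitude) - 1
        onset = _cross(span, apex, lo, step=-1)
        offset = _cross(span, apex, hi, step=+1)
        if onset is None or offset is None:
            continue
        onset_s, apex_s, offset_s = onset * dt_s, apex * dt_s, offset * dt_s
        period = (apexes[idx + 1] - apex) * dt_s if idx + 1 < len(apexes) else None
        beats.append(
            BeatFeatures(
                onset_s=onset_s,
                apex_s=apex_s,
                offset_s=offset_s,
                systole_s=apex_s - onset_s,
                diastole_s=offset_s - apex_s,
                beat_duration_s=offset_s - onset_s,
                period_s=period,
                amplitude_au=float(amplitude[apex] - base[apex]),
            )
        )
    return beats


def _cross(span: np.ndarray, apex: int, limit: int, step: int) -> float | None:
    """Sub-sample zero crossing of (amplitude - threshold) away from the apex."""
    j = apex
    below = 0
    while (j > limit) if step < 0 else (j < limit):
        j += step
        below = below + 1 if span[j] < 0 else 0
        if below >= _CROSSING_DEBOUNCE:
            k = j - step * (_CROSSING_DEBOUNCE - 1)  # first below-zero sample of the run
            other = k - step  # adjacent sample on the apex side (>= 0)
            frac = span[other] / (span[other] - span[k])
            return other + step * frac
    return None


def summarize_beats(beats: list[BeatFeatures], cell_id: str = "cell",
                    region: str | None = None) -> CellBeatSummary:
    """Per-cell mean beat features; a cell with no beats is non-beating."""
    if not beats:
        return CellBeatSummary(
            cell_id=cell_id, n_beats=0, systole_s=np.nan, diastole_s=np.nan,
            beat_duration_s=np.nan, period_s=np.nan, amplitude_au=np.nan,
            frequency_hz=np.nan, beating=False, region=region,
        )
    periods = [b.period_s for b in beats if b.period_s is not None]
    if len(beats) >= 2:
        span = beats[-1].apex_s - beats[0].apex_s
        freq = (len(beats) - 1) / span
    else:
        freq = np.nan
    return CellBeatSummary(
        cell_id=cell_id,
        n_beats=len(beats),
        systole_s=float(np.mean([b.systole_s for b in beats])),
        diastole_s=float(np.mean([b.diastole_s for b in beats])),
        beat_duration_s=float(np.mean([b.beat_duration_s for b in beats])),
        period_s=float(np.mean(periods)) if periods else np.nan,
        amplitude_au=float(np.mean([b.amplitude_au for b in beats])),
        frequency_hz=freq,
        beating=True,
        region=region,
    )


def normalize_to_period(beats: list[BeatFeatures]) -> pd.DataFrame:
    """Per-beat durations divided by that beat's apex-to-apex period.

    Beats without a defined period (the last one, or a single-beat
    recording) are excluded; an empty frame is returned for fewer than
    two beats, flagging the ratios as undefined.
    """
    rows = []
    for b in beats:
        if b.period_s is None:
            continue
        rows.append(
            {
                "systole_ratio": b.systole_s / b.period_s,
                "diastole_ratio": b.diastole_s / b.period_s,
                "beat_ratio": b.beat_duration_s / b.period_s,
            }
        )
    return pd.DataFrame(rows, columns=["systole_ratio", "diastole_ratio", "beat_ratio"])


def beating_census(summaries: list[CellBeatSummary]) -> pd.DataFrame:
    """Fraction of beating cells, overall and per region.

    Regions with no cells are reported with n = 0 rather than omitted;
    a census over zero cells raises.
    """
    if not summaries:
        raise ValueError("beating census requires at least one cell")
    from orgwave.presets import REGIONS

    rows = [
        {
            "region": "All",
            "n_cells": len(summaries),
            "n_beating": sum(s.beating for s in summaries),
        }
    ]
    for region in REGIONS:
        cells = [s for s in summaries if s.region == region]
        rows.append(
            {
                "region": region,
                "n_cells": len(cells),
                "n_beating": sum(s.beating for s in cells),
            }
        )
    frame = pd.DataFrame(rows)
    frame["fraction_beating"] = np.where(
        frame["n_cells"] > 0, frame["n_beating"] / frame["n_cells"], np.nan
    )
    return frame
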