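"""Synthetic recordings of an organoid with radially dispersed 2D cells.

The generator draws a scene layout (Poisson cell count, exponentially
thinning radial placement, per-region kinetics and abnormality mixes),
synthesizes one calcium and one motion trace per cell phase-locked to the
organoid, and can rasterize a small grayscale image stack.  Every trace
carries a ground-truth record, which is what makes the analysis chain
testable end to end.

Abnormal calcium morphologies mirror the expert taxonomy:

* ``bifid`` — a secondary intra-transient maximum on the falling limb;
* ``plateau_uptake`` — the rise is held flat mid-way for half of the
  rise duration;
* ``early_second_upstroke`` — every second transient starts while the
  previous one is still above 50% of its amplitude;
* ``spontaneous_release`` — a sub-threshold bump between transients.

Cells carrying any abnormality also draw slower, shallower kinetics
(width x1.30, max slope x0.75 by default), reflecting the impaired
calcium handling that accompanies arrhythmic morphology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from orgwave.io import RoiSpec, Trace, TraceSet
from orgwave.presets import (
    REGIONS,
    BeatShapeParams,
    ScenePreset,
    TransientShapeParams,
)
from orgwave.waveform import (
    BeatPulse,
    CalibratedWaveform,
    calibrate_beat_pulse,
    calibrate_transient_shape,
)

DEFAULT_SAMPLING_MS = 20.0  # 50 frames/s
DEFAULT_DURATION_MS = 15_000.0
DEFAULT_START_MS = 400.0

# abnormality-injection constants (fractions of the transient amplitude
# or of characteristic durations)
# bifid apex geometry: after the main apex the signal dips and partially
# recovers before resuming the decay, giving two sub-peaks 180 ms apart —
# closer than the peak-detection separation, so the pair reads as one
# transient whatever the underlying kinetics
BIFID_DIP_LEVEL = 0.62
BIFID_SECOND_LEVEL = 0.88
BIFID_DIP_MS = 70.0
BIFID_RECOVER_MS = 90.0
PLATEAU_RISE_FRAC = 0.70  # hold duration as a fraction of the rise
EARLY_RESTART_LEVEL = 0.50  # next upstroke starts at this decay level
SPONT_BUMP_FRAC = 0.15
SPONT_BUMP_SIGMA_MS = 45.0
#: the bump lands between the settled tail and the next onset, at a
#: random phase per gap (spontaneous release is not phase-locked)
SPONT_BUMP_LEAD_SIGMAS = 3.5

_LN5 = math.log(5.0)


def _resolve_waveform(shape) -> tuple[CalibratedWaveform, TransientShapeParams | None]:
    if isinstance(shape, CalibratedWaveform):
        return shape, None
    if isinstance(shape, TransientShapeParams):
        return calibrate_transient_shape(shape), shape
    raise TypeError("shape must be TransientShapeParams or CalibratedWaveform")


def _default_drift(times_ms: np.ndarray, amplitude: float, phase: float) -> np.ndarray:
    """Slow linear + sinusoidal baseline wander used to exercise drift removal."""
    span = max(times_ms[-1], 1.0)
    return (
        0.10 * amplitude * times_ms / span
        + 0.03 * amplitude * np.sin(2 * np.pi * times_ms / 10_000.0 + phase)
    )


def _onsets(wf: CalibratedWaveform, period_ms: float, n_beats: int,
            start_ms: float, abnormality: str) -> np.ndarray:
    if abnormality != "early_second_upstroke":
        return start_ms + period_ms * np.arange(n_beats)
    # every third beat is premature, starting while the previous transient
    # has only decayed to EARLY_RESTART_LEVEL; the remaining beats keep the
    # underlying rhythm, so the cell stays quantifiable between episodes
    early_gap = wf.peak_time_ms + wf.decay_ms * math.log(1.0 / EARLY_RESTART_LEVEL)
    onsets = []
    for k in range(n_beats):
        if k % 3 == 2:
            onsets.append(start_ms + (k - 1) * period_ms + early_gap)
        else:
            onsets.append(start_ms + k * period_ms)
    return np.asarray(onsets)


def _bifid_beat(wf: CalibratedWaveform, tloc: np.ndarray) -> np.ndarray:
    """One transient whose apex splits into two sub-peaks."""
    A = wf.amplitude
    tp = wf.peak_time_ms
    u = tloc - tp  # time past the main apex
    dip_end = BIFID_DIP_MS
    rec_end = BIFID_DIP_MS + BIFID_RECOVER_MS
    y = wf(tloc)
    m = (u >= 0) & (u < dip_end)
    y[m] = A * (1.0 + (BIFID_DIP_LEVEL - 1.0) * u[m] / dip_end)
    m = (u >= dip_end) & (u < rec_end)
    y[m] = A * (BIFID_DIP_LEVEL
                + (BIFID_SECOND_LEVEL - BIFID_DIP_LEVEL) * (u[m] - dip_end) / BIFID_RECOVER_MS)
    m = u >= rec_end
    y[m] = BIFID_SECOND_LEVEL * A * np.exp(-(u[m] - rec_end) / wf.decay_ms)
    return y


def _plateau_beat(wf: CalibratedWaveform, tloc: np.ndarray) -> np.ndarray:
    """One transient with its rise held flat mid-shoulder."""
    hold_at = wf.upstroke_ms + 0.5 * wf.shoulder_ms
    hold_ms = PLATEAU_RISE_FRAC * wf.peak_time_ms
    level = float(wf(np.array([hold_at]))[0])
    y = np.where(
        tloc < hold_at,
        wf(tloc),
        np.where(tloc < hold_at + hold_ms, level, wf(tloc - hold_ms)),
    )
    return y


def _render_train(times_ms: np.ndarray, wf: CalibratedWaveform,
                  onsets: np.ndarray, abnormality: str,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    y = np.zeros_like(times_ms)
    A = wf.amplitude
    if rng is None:
        rng = np.random.default_rng(0)
    for k, o in enumerate(onsets):
        tloc = times_ms - o
        if abnormality == "plateau_uptake":
            y += _plateau_beat(wf, tloc)
        elif abnormality == "bifid":
            y += _bifid_beat(wf, tloc)
        else:
            y += wf(tloc)
        if abnormality == "spontaneous_release" and k + 1 < len(onsets):
            # diastolic bump on the settled tail, at a random phase per gap
            latest = onsets[k + 1] - SPONT_BUMP_LEAD_SIGMAS * SPONT_BUMP_SIGMA_MS
            earliest = min(o + wf.support_ms + 2.0 * SPONT_BUMP_SIGMA_MS, latest)
            center = rng.uniform(earliest, latest)
            y += SPONT_BUMP_FRAC * A * np.exp(
                -0.5 * ((times_ms - center) / SPONT_BUMP_SIGMA_MS) ** 2
            )
    return y


def generate_trace(
    shape,
    *,
    n_beats: int = 8,
    sampling_interval_ms: float = DEFAULT_SAMPLING_MS,
    noise_sd: float = 0.0,
    drift: str = "none",
    abnormality: str = "normal",
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    start_ms: float = DEFAULT_START_MS,
    phase_jitter: bool = False,
    duration_ms: float | None = None,
    period_ms: float | None = None,
    cell_id: str = "cell",
    position_um: tuple[float, float] = (0.0, 0.0),
    amplitude_factor: float = 1.0,
) -> tuple[Trace, TransientShapeParams]:
    """Synthesize one calcium trace and its ground-truth record.

    ``shape`` is a :class:`TransientShapeParams` target (calibrated here)
    or an already calibrated waveform (then ``period_ms`` is required).
    ``drift`` is ``"none"``, ``"default"`` or a callable of the time
    vector.  ``amplitude_factor`` scales the whole waveform (smaller
    transients at unchanged kinetics).  The sampling interval must
    resolve the release phase (at most one fifth of the left width).
    """
    wf, params = _resolve_waveform(shape)
    if amplitude_factor != 1.0:
        wf = replace(wf, amplitude=wf.amplitude * amplitude_factor)
    if period_ms is None:
        if params is None:
            raise ValueError("period_ms is required with a pre-calibrated waveform")
        period_ms = params.period_ms
    if n_beats < 1:
        raise ValueError("n_beats must be at least 1")
    left = params.left_width20_ms if params is not None else wf.peak_time_ms / 2
    if sampling_interval_ms > left / 5.0:
        raise ValueError(
            "sampling_interval_ms too coarse: must be at most left_width20_ms / 5"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    if phase_jitter:
        start_ms = start_ms + rng.uniform(0.0, period_ms)
    if duration_ms is None:
        duration_ms = start_ms + (n_beats - 1) * period_ms + wf.support_ms + sampling_interval_ms
        if abnormality == "early_second_upstroke":
            duration_ms += period_ms
    n_samples = int(round(duration_ms / sampling_interval_ms)) + 1
    times = np.arange(n_samples) * sampling_interval_ms

    onsets = _onsets(wf, period_ms, n_beats, start_ms, abnormality)
    clean = _render_train(times, wf, onsets, abnormality, rng=rng)

    values = clean.copy()
    if drift == "default":
        values = values + _default_drift(times, wf.amplitude, rng.uniform(0, 2 * np.pi))
    elif callable(drift):
        values = values + drift(times)
    elif drift != "none":
        raise ValueError("drift must be 'none', 'default' or a callable")
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    truth = (
        replace(params, amplitude_au=wf.amplitude, abnormality=abnormality,
                max_rise_aupms=params.max_rise_aupms * amplitude_factor,
                auc_aums=params.auc_aums * amplitude_factor)
        if params is not None
        else TransientShapeParams(
            peak_width20_ms=1.0, left_width20_ms=0.5, right_width20_ms=0.5,
            max_rise_aupms=1.0, auc_aums=1.0, period_ms=period_ms,
            amplitude_au=wf.amplitude, abnormality=abnormality,
        )
    )
    trace = Trace(
        cell_id=cell_id, modality="calcium", times_ms=times, values=values,
        position_um=position_um, source="synthetic",
    )
    return trace, truth


def generate_motion_trace(
    beat: BeatShapeParams,
    *,
    n_beats: int = 8,
    sampling_interval_ms: float = DEFAULT_SAMPLING_MS,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    start_ms: float = DEFAULT_START_MS,
    phase_jitter: bool = False,
    duration_ms: float | None = None,
    beating: bool = True,
    cell_id: str = "cell",
    position_um: tuple[float, float] = (0.0, 0.0),
) -> tuple[Trace, BeatShapeParams]:
    """Synthesize one motion (contractility amplitude) trace."""
    pulse = calibrate_beat_pulse(beat)
    period_ms = beat.period_s * 1000.0
    if rng is None:
        rng = np.random.default_rng(seed)
    if phase_jitter:
        start_ms = start_ms + rng.uniform(0.0, period_ms)
    if duration_ms is None:
        duration_ms = start_ms + (n_beats - 1) * period_ms + pulse.support_s * 1000.0 + sampling_interval_ms
    n_samples = int(round(duration_ms / sampling_interval_ms)) + 1
    times = np.arange(n_samples) * sampling_interval_ms

    values = np.zeros_like(times)
    if beating:
        for k in range(n_beats):
            values += pulse((times - start_ms - k * period_ms) / 1000.0)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    trace = Trace(
        cell_id=cell_id, modality="motion", times_ms=times, values=values,
        position_um=position_um, source="synthetic",
    )
    return trace, beat


def generate_population(
    params: TransientShapeParams,
    n_cells: int,
    seed: int = 0,
    *,
    jitter_cv: float = 0.08,
    noise_sd_frac: float = 0.02,
    drift: str = "default",
    sampling_interval_ms: float = DEFAULT_SAMPLING_MS,
    n_beats: int | None = None,
    abnormality: str = "normal",
) -> list[tuple[Trace, TransientShapeParams]]:
    """An ensemble of independent cells drawn around one kinetic target.

    Per-cell kinetics are the target scaled by a unit-mean lognormal time
    factor (CV ``jitter_cv``); sampling phase is randomized per cell so
    ensemble averages are free of common-mode sampling artifacts.
    """
    rng = np.random.default_rng(seed)
    if n_beats is None:
        n_beats = max(1, int((DEFAULT_DURATION_MS - DEFAULT_START_MS) / params.period_ms) - 1)
    out = []
    for i in range(n_cells):
        factor = _unit_lognormal(rng, jitter_cv)
        cell_params = params.scaled(factor, abnormality=abnormality)
        wf = calibrate_transient_shape(cell_params)
        trace, truth = generate_trace(
            cell_params,
            n_beats=n_beats,
            sampling_interval_ms=sampling_interval_ms,
            noise_sd=noise_sd_frac * wf.amplitude,
            drift=drift,
            abnormality=abnormality,
            rng=rng,
            phase_jitter=True,
            cell_id=f"cell{i:04d}",
        )
        out.append((trace, truth))
    return out


def generate_motion_population(
    beat: BeatShapeParams,
    n_cells: int,
    seed: int = 0,
    *,
    jitter_cv: float = 0.06,
    noise_sd_frac: float = 0.02,
    sampling_interval_ms: float = DEFAULT_SAMPLING_MS,
    n_beats: int | None = None,
) -> list[tuple[Trace, BeatShapeParams]]:
    """An ensemble of beating cells drawn around one beat target."""
    rng = np.random.default_rng(seed)
    if n_beats is None:
        n_beats = max(2, int((DEFAULT_DURATION_MS - DEFAULT_START_MS) / (beat.period_s * 1000.0)) - 1)
    out = []
    for i in range(n_cells):
        factor = _unit_lognormal(rng, jitter_cv)
        cell_beat = beat.scaled(factor)
        trace, truth = generate_motion_trace(
            cell_beat,
            n_beats=n_beats,
            sampling_interval_ms=sampling_interval_ms,
            noise_sd=noise_sd_frac * beat.amplitude_au,
            rng=rng,
            phase_jitter=True,
            cell_id=f"cell{i:04d}",
        )
        out.append((trace, truth))
    return out


def _max_time_factor(params: TransientShapeParams,
                     margin: float = 0.92) -> float:
    """Largest kinetic time factor whose transient settles within the cycle.

    The template's total footprint scales linearly with the time factor;
    cells are capped so the recovery reaches baseline with a margin
    before the next beat (a periodically driven cell cannot sustain a
    transient longer than its cycle).
    """
    wf = calibrate_transient_shape(params)
    return margin * params.period_ms / wf.support_ms


def _unit_lognormal(rng: np.random.Generator, cv: float) -> float:
    """Lognormal multiplier with mean exactly 1 and the given CV."""
    if cv <= 0:
        return 1.0
    s2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(-0.5 * s2, math.sqrt(s2)))


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------


@dataclass
class Scene:
    """A synthetic recording: traces, ground truth, ROI geometry."""

    preset: ScenePreset
    traces: TraceSet
    ground_truth: pd.DataFrame
    rois: list[RoiSpec]
    seed: int
    stack: np.ndarray | None = None
    stack_pixel_size_um: float | None = None


def scene_layout(preset: ScenePreset, n_cells: int | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Draw the geometric/categorical part of a scene (no traces).

    Cell count is Poisson around the preset mean; radial distance from the
    organoid boundary is exponential with the preset decay rate (steeper
    for dox, so occupancy falls monotonically outward); angles are
    uniform.  Beating flags and abnormality labels are drawn i.i.d. from
    the preset fractions; abnormal cells pick one of the four morphologies
    uniformly.
    """
    from orgwave.spatial import RegionMap, assign_region

    rng = np.random.default_rng(seed)
    n = int(rng.poisson(preset.mean_cell_count)) if n_cells is None else int(n_cells)
    rmap = RegionMap(
        center_um=(0.0, 0.0),
        organoid_radius_um=preset.organoid_radius_um,
        ring_spacing_um=preset.ring_spacing_um,
    )
    rows = [
        {
            "cell_id": "organoid",
            "x_um": 0.0,
            "y_um": 0.0,
            "region": "Center",
            "is_organoid": True,
            "is_beating": True,
            "abnormality": "normal",
        }
    ]
    radii = preset.organoid_radius_um + rng.exponential(
        1.0 / preset.radial_density_decay, size=n
    )
    angles = rng.uniform(0.0, 2 * np.pi, size=n)
    beating = rng.random(n) < preset.beating_fraction
    abn_draw = rng.random(n)
    abn_kind = rng.integers(0, 4, size=n)
    kinds = ("bifid", "plateau_uptake", "early_second_upstroke", "spontaneous_release")
    for i in range(n):
        x = radii[i] * math.cos(angles[i])
        y = radii[i] * math.sin(angles[i])
        region = assign_region((x, y), rmap)
        frac = preset.abnormal_fraction_by_region[REGIONS.index(region)]
        rows.append(
            {
                "cell_id": f"cell{i:04d}",
                "x_um": x,
                "y_um": y,
                "region": region,
                "is_organoid": False,
                "is_beating": bool(beating[i]),
                "abnormality": kinds[abn_kind[i]] if abn_draw[i] < frac else "normal",
            }
        )
    return pd.DataFrame(rows)


def generate_scene(
    preset: ScenePreset,
    n_cells: int | None = None,
    seed: int = 0,
    *,
    sampling_interval_ms: float = DEFAULT_SAMPLING_MS,
    duration_ms: float = DEFAULT_DURATION_MS,
    noise: bool = True,
    drift: str = "default",
    stack: bool = False,
    stack_shape: tuple[int, int] = (256, 256),
    stack_pixel_size_um: float = 4.0,
) -> Scene:
    """Generate a full synthetic recording for one condition.

    Every cell's calcium and motion traces are phase-locked to the
    organoid: after synthesis each noise-free cell trace is cross-
    correlated against the organoid's and shifted by the argmax lag, so
    the maximum cross-correlation sits at lag zero by construction.
    """
    from orgwave.spatial import cross_correlate

    layout = scene_layout(preset, n_cells=n_cells, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    n_samples = int(round(duration_ms / sampling_interval_ms)) + 1
    times = np.arange(n_samples) * sampling_interval_ms

    def n_beats_for(period_ms: float, support_ms: float) -> int:
        return max(1, int((duration_ms - DEFAULT_START_MS - support_ms) // period_ms) + 1)

    traces = TraceSet()
    truth_rows = []
    rois = []
    shipped_ca: dict[str, np.ndarray] = {}

    # organoid reference first (no kinetic jitter, always beating, normal)
    ca_center = preset.transient_params_by_region[0]
    beat_center = preset.beat_params_by_region[0]

    def synth_cell(row, ca_params, beat_params_, align_ref=None,
                   amplitude_factor=1.0):
        wf = calibrate_transient_shape(ca_params)
        nb = n_beats_for(ca_params.period_ms, wf.support_ms)
        mk = dict(
            n_beats=nb,
            sampling_interval_ms=sampling_interval_ms,
            duration_ms=duration_ms,
            abnormality=row["abnormality"],
            cell_id=row["cell_id"],
            position_um=(row["x_um"], row["y_um"]),
        )
        # per-cell drift and noise are drawn once so alignment iterations
        # below shift only the underlying waveform, not the realization
        amp = wf.amplitude
        disturbance = np.zeros_like(times)
        if drift == "default":
            disturbance += _default_drift(times, amp, rng.uniform(0, 2 * np.pi))
        if noise:
            disturbance = disturbance + rng.normal(
                0.0, preset.noise_sd_frac * amp, size=times.shape)

        cell_render_seed = int(rng.integers(2**31))

        def render(shift_samples: int):
            clean, truth = generate_trace(
                ca_params, noise_sd=0.0, drift="none",
                rng=np.random.default_rng(cell_render_seed),
                start_ms=DEFAULT_START_MS - shift_samples * sampling_interval_ms,
                amplitude_factor=amplitude_factor,
                **mk,
            )
            return clean, truth, clean.values + disturbance

        shift = 0.0
        clean, truth, values = render(shift)
        if align_ref is not None:
            # phase-lock to the organoid: shift (including sub-sample
            # phase) until the cross-correlation against the shipped
            # organoid trace peaks at lag zero with margin, so sampling
            # phase cannot tip the argmax onto a neighbouring lag
            max_lag = int(round(2000.0 / sampling_interval_ms))
            for _ in range(8):
                xc = cross_correlate(align_ref, values, max_lag)
                lag = xc.argmax_lag
                i0 = int(np.where(xc.lags == lag)[0][0])
                delta = 0.0
                if 0 < i0 < len(xc.lags) - 1:
                    a, b, c = xc.values[i0 - 1], xc.values[i0], xc.values[i0 + 1]
                    den = a - 2.0 * b + c
                    if den < 0:
                        delta = float(np.clip((a - c) / (2.0 * den), -0.5, 0.5))
                if lag == 0 and abs(delta) < 0.35:
                    break
                shift += lag + delta
                clean, truth, values = render(shift)
        ca_trace = Trace(cell_id=row["cell_id"], modality="calcium", times_ms=times,
                         values=values, position_um=(row["x_um"], row["y_um"]),
                         source="synthetic")
        # motion
        pulse = calibrate_beat_pulse(beat_params_)
        nbb = n_beats_for(beat_params_.period_s * 1000.0, pulse.support_s * 1000.0)
        mstart = DEFAULT_START_MS - shift * sampling_interval_ms
        mvals = np.zeros_like(times)
        if row["is_beating"]:
            for k in range(nbb):
                mvals += pulse((times - mstart - k * beat_params_.period_s * 1000.0) / 1000.0)
        if noise:
            mvals = mvals + rng.normal(0.0, 0.02 * beat_params_.amplitude_au, size=mvals.shape)
        mo_trace = Trace(cell_id=row["cell_id"], modality="motion", times_ms=times,
                         values=mvals, position_um=(row["x_um"], row["y_um"]),
                         source="synthetic")
        return clean.values, ca_trace, mo_trace, truth

    for _, row in layout.iterrows():
        region_idx = REGIONS.index(row["region"])
        if row["is_organoid"]:
            ca_params, bt_params = ca_center, beat_center
            align_ref = None
            amp_factor = 1.0
        else:
            region_params = preset.transient_params_by_region[region_idx]
            factor = _unit_lognormal(rng, preset.kinetic_jitter_cv)
            amp_factor = 1.0
            if row["abnormality"] == "spontaneous_release":
                amp_factor = preset.spont_amplitude_factor
            elif row["abnormality"] != "normal":
                factor *= preset.abnormal_width_factor
            factor = min(factor, _max_time_factor(region_params))
            ca_params = region_params.scaled(factor, abnormality=row["abnormality"])
            bfactor = _unit_lognormal(rng, preset.beat_jitter_cv)
            bt_params = preset.beat_params_by_region[region_idx].scaled(bfactor)
            align_ref = shipped_ca["organoid"]
        clean_vals, ca_tr, mo_tr, truth = synth_cell(
            row, ca_params, bt_params, align_ref,
            amplitude_factor=amp_factor if not row["is_organoid"] else 1.0)
        shipped_ca[row["cell_id"]] = ca_tr.values
        traces.add(ca_tr)
        traces.add(mo_tr)
        rois.append(
            RoiSpec(cell_id=row["cell_id"], x_um=row["x_um"], y_um=row["y_um"],
                    radius_um=preset.organoid_radius_um if row["is_organoid"] else 8.0,
                    is_organoid=bool(row["is_organoid"]))
        )
        truth_rows.append(
            {
                **{k: row[k] for k in ("cell_id", "x_um", "y_um", "region",
                                        "is_organoid", "is_beating", "abnormality")},
                "width20_ms": truth.peak_width20_ms,
                "left_width20_ms": truth.left_width20_ms,
                "right_width20_ms": truth.right_width20_ms,
                "max_slope_aupms": truth.max_rise_aupms,
                "auc_aums": truth.auc_aums,
                "ca_period_ms": truth.period_ms,
                "ca_amplitude_au": truth.amplitude_au,
                "systole_s": bt_params.systole_s,
                "diastole_s": bt_params.diastole_s,
                "beat_duration_s": bt_params.beat_duration_s,
                "beat_period_s": bt_params.period_s,
            }
        )

    scene = Scene(
        preset=preset,
        traces=traces,
        ground_truth=pd.DataFrame(truth_rows),
        rois=rois,
        seed=seed,
    )
    if stack:
        scene.stack = render_stack(scene, shape=stack_shape,
                                   pixel_size_um=stack_pixel_size_um)
        scene.stack_pixel_size_um = stack_pixel_size_um
    return scene


def render_stack(scene: Scene, *, shape: tuple[int, int] = (256, 256),
                 pixel_size_um: float = 4.0, background: float = 100.0,
                 gain: float = 1000.0, max_frames: int = 750) -> np.ndarray:
    """Rasterize the scene's calcium traces as a uint16 image stack.

    Disk-shaped cells light up with their trace values; cells outside the
    frame are skipped.  Intended for small validation stacks, not
    photorealism.
    """
    from orgwave.io import roi_mask

    n_rows, n_cols = shape
    origin = ((n_rows - 1) / 2.0, (n_cols - 1) / 2.0)
    ca_traces = scene.traces.traces("calcium")
    n_frames = min(max_frames, len(ca_traces[0].values))
    stack = np.full((n_frames, n_rows, n_cols), background, dtype=np.float64)
    for tr in ca_traces:
        roi = next(r for r in scene.rois if r.cell_id == tr.cell_id)
        rr = origin[0] + roi.y_um / pixel_size_um
        cc = origin[1] + roi.x_um / pixel_size_um
        rad = roi.radius_um / pixel_size_um
        if rr - rad < 0 or rr + rad > n_rows - 1 or cc - rad < 0 or cc + rad > n_cols - 1:
            continue
        mask = roi_mask((n_rows, n_cols), (rr, cc), rad)
        stack[:, mask] += gain * np.clip(tr.values[:n_frames, None], 0.0, None)
    return np.clip(stack, 0, 65535).astype(np.uint16)
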