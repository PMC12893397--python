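"""Calcium-transient morphometry: drift removal, peak detection, features."""

import numpy as np
import pytest

from orgwave.calcium import (
    analyze_trace,
    detect_peaks,
    measure_transients,
    remove_drift,
    summarize_cell,
)
from orgwave.synthetic import generate_trace


def _triangle(dt=20.0, rise=100.0, fall=100.0, amp=1.0, pad=500.0):
    """A single triangular peak on a zero baseline."""
    t = np.arange(0.0, rise + fall + 2 * pad, dt)
    y = np.zeros_like(t)
    up = (t >= pad) & (t < pad + rise)
    y[up] = amp * (t[up] - pad) / rise
    down = (t >= pad + rise) & (t <= pad + rise + fall)
    y[down] = amp * (1 - (t[down] - pad - rise) / fall)
    return t, y


def test_pure_linear_drift_is_removed():
    dt = 20.0
    t = np.arange(0, 15000, dt)
    drift = 0.5 * t / t[-1]
    out = remove_drift(drift, dt)
    assert np.abs(out).max() < 0.02 * 0.5


def test_peak_amplitude_survives_drift_removal(control_ca):
    tr, truth = generate_trace(control_ca, n_beats=6, noise_sd=0.0, drift="none", seed=0)
    out = remove_drift(tr.values, tr.dt_ms)
    assert out.max() == pytest.approx(tr.values.max(), rel=0.02)


def test_too_short_window_raises():
    with pytest.raises(ValueError, match="3 samples"):
        remove_drift(np.zeros(100), 20.0, window_ms=40.0)


def test_single_triangle_yields_one_apex():
    dt = 4.0
    t, y = _triangle(dt=dt)
    apexes = detect_peaks(y, dt)
    assert len(apexes) == 1
    assert t[apexes[0]] == pytest.approx(600.0, abs=dt)


def test_flat_trace_has_no_peaks():
    assert len(detect_peaks(np.zeros(500), 20.0)) == 0


def test_plateau_ties_resolve_to_leftmost_sample():
    y = np.zeros(50)
    y[20:24] = 1.0
    apexes = detect_peaks(y, 20.0)
    assert list(apexes) == [20]


def test_periodic_trace_apex_count_and_positions(control_ca):
    tr, _ = generate_trace(control_ca, n_beats=7, noise_sd=0.0, drift="none", seed=0)
    det = remove_drift(tr.values, tr.dt_ms)
    apexes = detect_peaks(det, tr.dt_ms)
    assert len(apexes) == 7
    from orgwave.waveform import calibrate_transient_shape

    wf = calibrate_transient_shape(control_ca)
    expected = 400.0 + wf.peak_time_ms + control_ca.period_ms * np.arange(7)
    got = apexes * tr.dt_ms
    assert np.abs(got - expected).max() <= tr.dt_ms


def test_triangle_widths_at_20pct():
    """20% crossings of linear limbs sit at 80% of each limb duration."""
    dt = 4.0
    _, y = _triangle(dt=dt, rise=100.0, fall=100.0)
    apexes = detect_peaks(y, dt)
    (f,) = measure_transients(y, dt, apexes)
    assert f.width20_ms == pytest.approx(160.0, abs=dt)
    assert f.left_width20_ms == pytest.approx(80.0, abs=dt)
    assert f.right_width20_ms == pytest.approx(80.0, abs=dt)
    assert f.width20_ms == f.left_width20_ms + f.right_width20_ms


def test_triangle_auc_matches_dense_trapezoid_oracle():
    """AUC between the 20% crossings equals brute-force integration at 0.1 ms."""
    dt = 4.0
    _, y = _triangle(dt=dt, rise=100.0, fall=100.0, amp=2.0)
    apexes = detect_peaks(y, dt)
    (f,) = measure_transients(y, dt, apexes)
    # oracle: continuous triangle, area between the crossings at 0.2*amp
    tt = np.arange(0.0, 200.0, 0.1)
    yy = np.where(tt < 100, 2.0 * tt / 100, 2.0 * (1 - (tt - 100) / 100))
    sel = yy >= 0.4
    oracle = np.trapezoid(yy[sel], tt[sel])
    assert f.auc_aums == pytest.approx(oracle, rel=0.02)


@pytest.mark.parametrize("preset", ["control", "dox"])
def test_noise_free_roundtrip_recovers_functionals(preset, control_ca, dox_ca):
    """Sampled noise-free traces give back the continuous-time functionals
    within one sampling interval (times) and 2% (slope, AUC)."""
    params = control_ca if preset == "control" else dox_ca
    tr, truth = generate_trace(params, n_beats=7, noise_sd=0.0, drift="none", seed=1)
    _, _, _, s = analyze_trace(tr.values, tr.dt_ms)
    dt = tr.dt_ms
    assert s.width20_ms == pytest.approx(truth.peak_width20_ms, abs=dt)
    assert s.left_width20_ms == pytest.approx(truth.left_width20_ms, abs=dt)
    assert s.right_width20_ms == pytest.approx(truth.right_width20_ms, abs=dt)
    assert s.max_slope_aupms == pytest.approx(truth.max_rise_aupms, rel=0.02)
    assert s.auc_aums == pytest.approx(truth.auc_aums, rel=0.02)
    assert s.interpeak_ms == pytest.approx(params.period_ms, abs=dt)


def test_features_invariant_to_offset_and_time_shift(control_ca):
    tr, _ = generate_trace(control_ca, n_beats=6, noise_sd=0.0, drift="none", seed=2)
    base = analyze_trace(tr.values, tr.dt_ms)[3]
    shifted = analyze_trace(tr.values + 5.0, tr.dt_ms)[3]
    rolled = analyze_trace(np.concatenate([np.zeros(10), tr.values]), tr.dt_ms)[3]
    for attr in ("width20_ms", "left_width20_ms", "right_width20_ms",
                 "amplitude_au", "max_slope_aupms", "auc_aums"):
        assert getattr(shifted, attr) == pytest.approx(getattr(base, attr), rel=1e-6)
        assert getattr(rolled, attr) == pytest.approx(getattr(base, attr), rel=0.02)


def test_amplitude_scaling_scales_only_amplitude_like_features(control_ca):
    tr, _ = generate_trace(control_ca, n_beats=6, noise_sd=0.0, drift="none", seed=2)
    k = 3.0
    a = analyze_trace(tr.values, tr.dt_ms)[3]
    b = analyze_trace(k * tr.values, tr.dt_ms)[3]
    assert b.amplitude_au == pytest.approx(k * a.amplitude_au, rel=1e-6)
    assert b.max_slope_aupms == pytest.approx(k * a.max_slope_aupms, rel=1e-6)
    assert b.auc_aums == pytest.approx(k * a.auc_aums, rel=1e-6)
    for attr in ("width20_ms", "left_width20_ms", "right_width20_ms"):
        assert getattr(b, attr) == pytest.approx(getattr(a, attr), rel=1e-9)


def test_summary_of_identical_peaks_equals_single_peak(control_ca):
    tr, _ = generate_trace(control_ca, n_beats=5, noise_sd=0.0, drift="none", seed=0)
    det, apexes, feats, s = analyze_trace(tr.values, tr.dt_ms)
    good = [f for f in feats if not f.flagged]
    widths = [f.width20_ms for f in good]
    assert s.width20_ms == pytest.approx(np.mean(widths), rel=1e-12)
    assert max(widths) - min(widths) < tr.dt_ms  # near identical beats


def test_two_peaks_1000ms_apart_give_1hz():
    dt = 20.0
    t = np.arange(0.0, 3000.0, dt)
    y = np.zeros_like(t)
    for onset in (500.0, 1500.0):
        up = (t >= onset) & (t < onset + 100)
        y[up] = (t[up] - onset) / 100
        down = (t >= onset + 100) & (t <= onset + 200)
        y[down] = 1 - (t[down] - onset - 100) / 100
    apexes = detect_peaks(y, dt)
    feats = measure_transients(y, dt, apexes)
    s = summarize_cell(feats, t[-1], "c")
    assert s.frequency_hz == pytest.approx(1.0, rel=1e-6)


def test_flagged_peaks_are_excluded_from_means():
    """Means recomputed by brute force over unflagged peaks match."""
    dt = 20.0
    t = np.arange(0.0, 4000.0, dt)
    y = np.zeros_like(t)
    for onset in (200.0, 1400.0, 2600.0):
        up = (t >= onset) & (t < onset + 200)
        y[up] = (t[up] - onset) / 200
        down = (t >= onset + 200) & (t <= onset + 400)
        y[down] = 1 - (t[down] - onset - 200) / 200
    # truncate so the last peak's right crossing collides with the edge
    cut = int(2900 / dt)
    y = y[:cut]
    apexes = detect_peaks(y, dt)
    feats = measure_transients(y, dt, apexes)
    assert any(f.flagged for f in feats)
    s = summarize_cell(feats, cut * dt, "c")
    manual = np.mean([f.width20_ms for f in feats if not f.flagged])
    assert s.width20_ms == pytest.approx(manual, rel=1e-12)
    assert s.n_peaks == sum(not f.flagged for f in feats)


def test_cell_with_no_usable_peak_is_unquantifiable():
    s = summarize_cell([], 1000.0, "c")
    assert not s.quantifiable
    assert s.n_peaks == 0
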