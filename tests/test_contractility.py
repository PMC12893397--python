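"""Motion signals, beat segmentation, period normalization, census."""

import numpy as np
import pytest

from orgwave.contractility import (
    beating_census,
    compute_motion_signals,
    normalize_to_period,
    segment_beats,
    summarize_beats,
)
from orgwave.presets import DOX_2D_BEAT, ORGANOID_BEAT
from orgwave.synthetic import generate_motion_trace


def _pulse_signal(dt=0.02, rise=0.2, fall=0.3, amp=1.0, n=3, period=1.2, pad=0.5):
    t = np.arange(0.0, pad + n * period + pad, dt)
    y = np.zeros_like(t)
    for k in range(n):
        onset = pad + k * period
        up = (t >= onset) & (t < onset + rise)
        y[up] = amp * (t[up] - onset) / rise
        down = (t >= onset + rise) & (t <= onset + rise + fall)
        y[down] = amp * (1 - (t[down] - onset - rise) / fall)
    return t, y


def test_static_stack_gives_zero_signals():
    stack = np.full((12, 8, 8), 3.0)
    sig = compute_motion_signals(stack)
    np.testing.assert_allclose(sig.speed, 0.0)
    np.testing.assert_allclose(sig.amplitude, 0.0)


def test_intensity_ramp_gives_constant_speed():
    frames = np.arange(20.0)[:, None, None] * np.ones((1, 4, 4))
    sig = compute_motion_signals(frames * 0.5)
    np.testing.assert_allclose(sig.speed, 0.5)


def test_motion_signals_invariant_to_global_offset():
    _, y = _pulse_signal()
    a = compute_motion_signals(y)
    b = compute_motion_signals(y + 100.0)
    np.testing.assert_allclose(a.speed, b.speed)
    np.testing.assert_allclose(a.amplitude, b.amplitude, atol=1e-9)


def test_symmetric_pulse_systole_diastole_at_10pct_threshold():
    """Linear limbs crossed at 10% yield 0.9x of each limb duration."""
    dt = 0.02
    _, y = _pulse_signal(dt=dt, rise=0.2, fall=0.3)
    beats = segment_beats(y, dt)
    assert len(beats) == 3
    for b in beats:
        assert b.systole_s == pytest.approx(0.18, abs=dt)
        assert b.diastole_s == pytest.approx(0.27, abs=dt)
        assert b.systole_s + b.diastole_s == pytest.approx(b.beat_duration_s, rel=1e-12)


def test_organoid_preset_beat_duration_recovered_within_one_frame():
    tr, truth = generate_motion_trace(ORGANOID_BEAT, n_beats=8, noise_sd=0.0, seed=1)
    sig = compute_motion_signals(tr.values)
    beats = segment_beats(sig.amplitude, tr.dt_ms / 1000.0)
    s = summarize_beats(beats)
    assert s.beat_duration_s == pytest.approx(0.488, abs=tr.dt_ms / 1000.0)
    assert s.systole_s == pytest.approx(0.207, abs=tr.dt_ms / 1000.0)


def test_baseline_step_does_not_move_beat_durations():
    """Dynamic thresholding keeps durations fixed under a mid-recording
    baseline step of +50% of the pulse amplitude."""
    dt = 0.02
    t, y = _pulse_signal(dt=dt, n=6, period=1.2)
    step_at = t[-1] / 2
    step = np.where(t > step_at, 0.5, 0.0)
    ref = segment_beats(y, dt)
    stepped = segment_beats(y + step, dt)
    # beats clear of the threshold-adaptation window (one rolling window
    # around the step) are all recovered with unchanged durations
    by_apex = {round(b.apex_s, 2): b for b in stepped}
    clear = [b for b in ref if abs(b.apex_s - step_at) > 1.6]
    assert len(clear) >= 3
    for a in clear:
        b = by_apex[round(a.apex_s, 2)]
        assert b.beat_duration_s == pytest.approx(a.beat_duration_s, abs=dt)
        assert b.systole_s == pytest.approx(a.systole_s, abs=dt)


def test_pure_noise_is_non_beating():
    rng = np.random.default_rng(0)
    amp = np.abs(rng.normal(0, 0.02, 751))
    assert segment_beats(amp, 0.02) == []
    s = summarize_beats([], cell_id="c")
    assert not s.beating


def test_normalized_ratios_match_elementwise_oracle():
    tr, _ = generate_motion_trace(DOX_2D_BEAT, n_beats=6, noise_sd=0.0, seed=2)
    sig = compute_motion_signals(tr.values)
    beats = segment_beats(sig.amplitude, tr.dt_ms / 1000.0)
    ratios = normalize_to_period(beats)
    withp = [b for b in beats if b.period_s is not None]
    assert len(ratios) == len(withp)
    for row, b in zip(ratios.itertuples(), withp):
        assert row.systole_ratio == b.systole_s / b.period_s
        assert row.diastole_ratio == b.diastole_s / b.period_s
        assert row.beat_ratio == b.beat_duration_s / b.period_s
        assert row.systole_ratio + row.diastole_ratio == pytest.approx(row.beat_ratio, rel=1e-12)


def test_duration_equal_to_period_gives_unit_ratio():
    from orgwave.contractility import BeatFeatures

    b = BeatFeatures(onset_s=0.0, apex_s=0.5, offset_s=1.0, systole_s=0.5,
                     diastole_s=0.5, beat_duration_s=1.0, period_s=1.0,
                     amplitude_au=1.0)
    ratios = normalize_to_period([b])
    assert ratios.iloc[0]["beat_ratio"] == pytest.approx(1.0)


def test_single_beat_has_undefined_ratio():
    from orgwave.contractility import BeatFeatures

    b = BeatFeatures(onset_s=0.0, apex_s=0.2, offset_s=0.5, systole_s=0.2,
                     diastole_s=0.3, beat_duration_s=0.5, period_s=None,
                     amplitude_au=1.0)
    assert len(normalize_to_period([b])) == 0


def test_census_counts_match_brute_force(small_clean_scene):
    """The census equals a direct count over ground-truth beating flags."""
    scene = small_clean_scene
    summaries = []
    for tr in scene.traces.traces("motion"):
        if tr.cell_id == "organoid":
            continue
        sig = compute_motion_signals(tr.values)
        beats = segment_beats(sig.amplitude, tr.dt_ms / 1000.0)
        region = scene.ground_truth.set_index("cell_id").loc[tr.cell_id, "region"]
        summaries.append(summarize_beats(beats, cell_id=tr.cell_id, region=region))
    table = beating_census(summaries)
    gt = scene.ground_truth
    truth_frac = gt.loc[~gt["is_organoid"], "is_beating"].mean()
    got = table.loc[table["region"] == "All", "fraction_beating"].iloc[0]
    assert got == pytest.approx(truth_frac, abs=1e-9)


def test_all_beating_census_is_one():
    from orgwave.contractility import CellBeatSummary

    cells = [
        CellBeatSummary(cell_id=str(i), n_beats=3, systole_s=0.2, diastole_s=0.3,
                        beat_duration_s=0.5, period_s=1.0, amplitude_au=1.0,
                        frequency_hz=1.0, beating=True, region="Close")
        for i in range(5)
    ]
    table = beating_census(cells)
    assert table.loc[table["region"] == "All", "fraction_beating"].iloc[0] == 1.0
    # empty regions are reported, not omitted
    assert (table.loc[table["region"] == "Far", "n_cells"] == 0).all()


def test_census_requires_cells():
    with pytest.raises(ValueError):
        beating_census([])
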