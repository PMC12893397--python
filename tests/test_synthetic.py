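"""Generator contracts: determinism, abnormal morphologies, scene layout."""

import numpy as np
import pytest

from orgwave.presets import CONTROL, DOX
from orgwave.synthetic import (
    generate_motion_trace,
    generate_scene,
    generate_trace,
    scene_layout,
)
from orgwave.waveform import calibrate_transient_shape


@pytest.fixture(scope="module")
def control_abn(control_ca):
    """Kinetics of an abnormal control cell (1.3x slowing)."""
    return control_ca.scaled(1.3)


def test_same_seed_is_bit_identical(control_ca):
    a, _ = generate_trace(control_ca, n_beats=4, noise_sd=0.2, drift="default", seed=7)
    b, _ = generate_trace(control_ca, n_beats=4, noise_sd=0.2, drift="default", seed=7)
    assert np.array_equal(a.values, b.values)


def test_different_seeds_differ(control_ca):
    a, _ = generate_trace(control_ca, n_beats=4, noise_sd=0.2, seed=7)
    b, _ = generate_trace(control_ca, n_beats=4, noise_sd=0.2, seed=8)
    assert not np.array_equal(a.values, b.values)


def test_resolution_guard_rejects_coarse_sampling(control_ca):
    with pytest.raises(ValueError, match="sampling_interval_ms"):
        generate_trace(control_ca, sampling_interval_ms=50.0)


def _local_maxima(values, level):
    """Brute-force interior local maxima above a level."""
    out = []
    for k in range(1, len(values) - 1):
        if values[k] > values[k - 1] and values[k] >= values[k + 1] and values[k] >= level:
            out.append(k)
    return out


def test_bifid_variant_has_exactly_two_submaxima(control_abn):
    """Each bifid transient carries two maxima above 20% of amplitude."""
    wf = calibrate_transient_shape(control_abn)
    tr, _ = generate_trace(control_abn, n_beats=4, noise_sd=0.0, drift="none",
                           abnormality="bifid", seed=0)
    period = control_abn.period_ms
    dt = tr.dt_ms
    for k in range(4):
        lo = int((400 + k * period) / dt)
        hi = int((400 + k * period + wf.support_ms) / dt)
        maxima = _local_maxima(tr.values[lo:hi], 0.2 * wf.amplitude)
        assert len(maxima) == 2, f"beat {k}: {len(maxima)} maxima"


def test_plateau_variant_holds_the_rise_flat(control_abn):
    wf = calibrate_transient_shape(control_abn)
    tr, _ = generate_trace(control_abn, n_beats=3, noise_sd=0.0, drift="none",
                           abnormality="plateau_uptake", seed=0)
    dt = tr.dt_ms
    # within the first rise, a run of identical consecutive samples exists
    lo = int(400 / dt)
    hi = int((400 + 1.6 * wf.peak_time_ms) / dt)
    diffs = np.abs(np.diff(tr.values[lo:hi]))
    flat_run = 0
    best = 0
    for d in diffs:
        flat_run = flat_run + 1 if d < 1e-9 else 0
        best = max(best, flat_run)
    assert best * dt >= 0.25 * wf.peak_time_ms


def test_early_second_upstroke_stays_above_40pct(control_abn):
    wf = calibrate_transient_shape(control_abn)
    tr, _ = generate_trace(control_abn, n_beats=6, noise_sd=0.0, drift="none",
                           abnormality="early_second_upstroke", seed=0)
    v = tr.values
    apexes = _local_maxima(v, 0.5 * wf.amplitude)
    # at least one consecutive apex pair never decays below 40% of amplitude
    found = False
    for a, b in zip(apexes, apexes[1:]):
        if v[a:b + 1].min() > 0.4 * wf.amplitude:
            found = True
    assert found


def test_spontaneous_release_variant_adds_subthreshold_bumps(control_ca):
    clean, _ = generate_trace(control_ca, n_beats=5, noise_sd=0.0, drift="none",
                              abnormality="normal", seed=3)
    spont, _ = generate_trace(control_ca, n_beats=5, noise_sd=0.0, drift="none",
                              abnormality="spontaneous_release", seed=3)
    wf = calibrate_transient_shape(control_ca)
    extra = spont.values - clean.values
    assert extra.max() > 0.10 * wf.amplitude  # bumps present
    assert extra.max() < 0.30 * wf.amplitude  # and sub-threshold
    assert spont.values.max() <= clean.values.max() * 1.01  # peaks unchanged


def test_scene_layout_mean_cell_count_matches_preset():
    """Poisson cell counts average to the preset mean over 100 seeds."""
    counts = [len(scene_layout(CONTROL, seed=s)) - 1 for s in range(100)]
    sem = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - CONTROL.mean_cell_count) < 3 * sem + 1e-9


def test_layout_abnormal_fraction_within_binomial_bounds():
    """With every regional fraction at 0.5, abnormal counts are Binomial(n, .5)."""
    from dataclasses import replace

    preset = replace(CONTROL, abnormal_fraction_by_region=(0.5, 0.5, 0.5, 0.5))
    layout = scene_layout(preset, n_cells=200, seed=5)
    k = (layout.loc[~layout["is_organoid"], "abnormality"] != "normal").sum()
    # 99% binomial interval around 100
    assert 81 <= k <= 119


def test_layout_all_normal_when_fractions_zero():
    from dataclasses import replace

    preset = replace(CONTROL, abnormal_fraction_by_region=(0.0, 0.0, 0.0, 0.0))
    layout = scene_layout(preset, n_cells=60, seed=2)
    assert (layout["abnormality"] == "normal").all()


def test_zero_cell_scene_contains_only_the_organoid():
    scene = generate_scene(CONTROL, n_cells=0, seed=0)
    assert len(scene.ground_truth) == 1
    assert scene.ground_truth.iloc[0]["is_organoid"]
    assert len(scene.traces) == 2  # calcium + motion for the organoid


def test_scene_regeneration_is_bit_identical():
    a = generate_scene(CONTROL, n_cells=8, seed=99)
    b = generate_scene(CONTROL, n_cells=8, seed=99)
    for tr_a, tr_b in zip(a.traces, b.traces):
        assert tr_a.cell_id == tr_b.cell_id
        assert np.array_equal(tr_a.values, tr_b.values)
    assert a.ground_truth.equals(b.ground_truth)


def test_motion_trace_of_non_beating_cell_is_flat():
    from orgwave.presets import CONTROL_2D_BEAT

    tr, _ = generate_motion_trace(CONTROL_2D_BEAT, n_beats=5, noise_sd=0.0,
                                  beating=False, seed=0)
    assert np.all(tr.values == 0)


def test_ground_truth_widths_respect_sum_constraint(small_control_scene):
    gt = small_control_scene.ground_truth
    np.testing.assert_allclose(
        gt["left_width20_ms"] + gt["right_width20_ms"], gt["width20_ms"], rtol=1e-6
    )
    np.testing.assert_allclose(
        gt["systole_s"] + gt["diastole_s"], gt["beat_duration_s"], rtol=1e-6
    )
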