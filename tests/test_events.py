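"""Event detection: binocular combination, smoothing, gap interpolation,
velocity, thresholding, merging, filtering, and planted-stream recovery."""

import numpy as np
import pandas as pd
import pytest

from gazesal.events import (
    angular_velocity,
    binocular_combine,
    detect_events,
    detect_fixations,
    filter_fixations,
    interpolate_gaps,
    merge_fixations,
    smooth_gaze,
)
from gazesal.synth import ParticipantParams, SceneSpec, generate_gaze_stream

from conftest import binocular_frame, constant_velocity_stream


# ---------------------------------------------------------------------------
# binocular combination


@pytest.mark.parametrize(
    "left,right,valid,expected",
    [
        ((100.0, 100.0), (100.0, 100.0), (1, 1), (100.0, 100.0)),
        ((100.0, 100.0), (0.0, 0.0), (1, 0), (100.0, 100.0)),
        ((100.0, 100.0), (110.0, 100.0), (1, 1), (105.0, 100.0)),
    ],
)
def test_binocular_combination_rules(left, right, valid, expected):
    df = pd.DataFrame(
        {
            "timestamp_ms": [0.0],
            "gx_left_px": [left[0]],
            "gy_left_px": [left[1]],
            "gx_right_px": [right[0]],
            "gy_right_px": [right[1]],
            "pupil_left_mm": [3.0],
            "pupil_right_mm": [4.0],
            "valid_left": [valid[0]],
            "valid_right": [valid[1]],
        }
    )
    cyc = binocular_combine(df)
    assert (cyc.loc[0, "x"], cyc.loc[0, "y"]) == expected
    if valid == (1, 1):
        assert cyc.loc[0, "pupil"] == 3.5


def test_both_eyes_invalid_marks_missing():
    df = binocular_frame([0.0, 8.3], [100.0, np.nan], [100.0, np.nan])
    cyc = binocular_combine(df)
    assert not cyc.loc[1, "valid"]
    assert np.isnan(cyc.loc[1, "x"])


def test_empty_stream_rejected():
    with pytest.raises(ValueError):
        binocular_combine(binocular_frame([], [], []).iloc[0:0])


# ---------------------------------------------------------------------------
# smoothing


def test_constant_trace_is_smoothing_fixed_point(geometry120):
    df = binocular_frame(np.arange(50) * 8.33, np.full(50, 64.0), np.full(50, 48.0))
    cyc = binocular_combine(df)
    sm = smooth_gaze(cyc, geometry120)
    assert np.allclose(sm["x"], 64.0)
    assert np.allclose(sm["y"], 48.0)
    assert len(sm) == len(cyc)


def test_single_excursion_attenuated_toward_moving_average(geometry120):
    n = 41
    x = np.full(n, 64.0)
    excursion_px = 2.0 / geometry120.mm_per_px  # 2 mm, below the 8 mm scale
    x[20] += excursion_px
    cyc = binocular_combine(binocular_frame(np.arange(n) * 8.33, x, np.full(n, 48.0)))
    sm = smooth_gaze(cyc, geometry120, temporal_window=20)
    # oracle: a 20-sample moving average spreads the excursion to ~1/20
    # (the sub-scale spatial pass re-averages within the window, shifting the
    # result by at most excursion/window^2)
    assert sm["x"][20] == pytest.approx(
        64.0 + excursion_px / 20.0, abs=excursion_px / 100.0
    )
    assert sm["x"][20] < x[20]


def test_all_missing_trace_stays_missing(geometry120):
    n = 30
    df = binocular_frame(
        np.arange(n) * 8.33, np.full(n, np.nan), np.full(n, np.nan), valid=np.zeros(n)
    )
    sm = smooth_gaze(binocular_combine(df), geometry120)
    assert sm["x"].isna().all()


# ---------------------------------------------------------------------------
# gap interpolation (the three printed rules)


def _gap_stream(geometry, n_missing, flank_sep_deg):
    period = geometry.sample_period_ms
    n = 30 + n_missing
    t = np.arange(n) * period
    x = np.full(n, 40.0)
    sep_px = geometry.deg_to_px(flank_sep_deg)
    x[15 + n_missing :] = 40.0 + sep_px
    valid = np.ones(n)
    x = x.copy()
    x[15 : 15 + n_missing] = np.nan
    valid[15 : 15 + n_missing] = 0
    return binocular_combine(
        binocular_frame(t, x, np.full(n, 48.0), valid=valid)
    )


def test_short_gap_with_small_displacement_filled(geometry120):
    # 80 ms gap (~10 samples at 120 Hz), flanks 0.5 degrees apart
    cyc = _gap_stream(geometry120, n_missing=9, flank_sep_deg=0.5)
    out = interpolate_gaps(cyc, geometry120)
    assert out["valid"].all()
    filled = out["x"][15:24].to_numpy()
    assert np.all(np.diff(filled) > 0)  # linear ramp


def test_long_gap_not_filled(geometry120):
    # 150 ms of missing data exceeds the 100 ms cap
    cyc = _gap_stream(geometry120, n_missing=18, flank_sep_deg=0.5)
    out = interpolate_gaps(cyc, geometry120)
    assert not out["valid"][15:33].any()


def test_large_displacement_gap_not_filled(geometry120):
    # 80 ms gap but flanks 2 degrees apart: beyond the 1 degree threshold
    cyc = _gap_stream(geometry120, n_missing=9, flank_sep_deg=2.0)
    out = interpolate_gaps(cyc, geometry120)
    assert not out["valid"][15:24].any()


def test_boundary_gap_never_filled(geometry120):
    n = 20
    x = np.full(n, 40.0)
    valid = np.ones(n)
    x[:5] = np.nan
    valid[:5] = 0
    cyc = binocular_combine(
        binocular_frame(np.arange(n) * 8.33, x, np.full(n, 48.0), valid=valid)
    )
    out = interpolate_gaps(cyc, geometry120)
    assert not out["valid"][:5].any()


# ---------------------------------------------------------------------------
# velocity


def test_stationary_trace_zero_velocity(geometry120):
    cyc = binocular_combine(
        binocular_frame(np.arange(20) * 8.33, np.full(20, 64.0), np.full(20, 48.0))
    )
    v = angular_velocity(cyc, geometry120)
    assert np.allclose(v[1:], 0.0)
    assert np.isnan(v[0])


def test_one_degree_step_at_120hz_is_120_deg_per_s(geometry120):
    period = geometry120.sample_period_ms
    x = np.full(10, 40.0)
    x[5:] += geometry120.deg_to_px(1.0)
    cyc = binocular_combine(binocular_frame(np.arange(10) * period, x, np.full(10, 48.0)))
    v = angular_velocity(cyc, geometry120)
    # deg_to_px uses the isotropic pixel scale while the horizontal chord uses
    # the x-axis scale; they differ by ~0.05% on this display
    assert v[5] == pytest.approx(120.0, rel=2e-3)


# ---------------------------------------------------------------------------
# event detection


def test_stationary_500ms_trace_single_fixation(geometry120):
    n = 60  # 500 ms at 120 Hz
    cyc = binocular_combine(
        binocular_frame(np.arange(n) * geometry120.sample_period_ms, np.full(n, 64.0), np.full(n, 48.0))
    )
    seq = detect_events(cyc, geometry120)
    assert len(seq.fixations) == 1
    assert seq.fixations[0].duration_ms == pytest.approx(500.0, abs=9.0)


def test_two_stations_with_fast_sweep(geometry120):
    period = geometry120.sample_period_ms
    n1, nsw, n2 = 40, 6, 40
    sweep_v = 30.0  # deg/s, above threshold
    step = geometry120.deg_to_px(sweep_v * period / 1000.0)
    x = np.concatenate(
        [np.full(n1, 40.0), 40.0 + step * np.arange(1, nsw + 1), np.full(n2, 40.0 + step * nsw)]
    )
    cyc = binocular_combine(
        binocular_frame(np.arange(len(x)) * period, x, np.full(len(x), 48.0))
    )
    seq = detect_events(cyc, geometry120)
    assert len(seq.fixations) == 2
    assert len(seq.saccades) == 1


def test_constant_25_deg_per_s_drift_yields_no_fixation(geometry120):
    cyc = binocular_combine(constant_velocity_stream(geometry120, 25.0))
    seq = detect_events(cyc, geometry120)
    assert len(seq.fixations) == 0


def test_all_missing_stream_empty_sequence(geometry120):
    n = 20
    df = binocular_frame(
        np.arange(n) * 8.33, np.full(n, np.nan), np.full(n, np.nan), valid=np.zeros(n)
    )
    seq = detect_events(binocular_combine(df), geometry120)
    assert seq.fixations == [] and seq.saccades == []


def test_velocity_boundary_sweep_flips_exactly_at_threshold(geometry120):
    """Constant-velocity traces flip fixation -> saccade at 20 deg/s."""
    classifications = {}
    for v in np.arange(1.0, 41.0, 1.0):
        cyc = binocular_combine(constant_velocity_stream(geometry120, v))
        seq = detect_events(cyc, geometry120)
        classifications[v] = len(seq.fixations) > 0
    below = [v for v, fix in classifications.items() if fix]
    above = [v for v, fix in classifications.items() if not fix]
    assert max(below) < min(above)
    assert max(below) <= 20.0 <= min(above) + 1.0
    # the flip is within one sweep step of the printed threshold
    assert min(above) - max(below) == pytest.approx(1.0)
    assert abs(20.0 - max(below)) <= 1.0


# ---------------------------------------------------------------------------
# merging


def _station_stream(geometry, seps_deg, n_each=30):
    """Consecutive stations separated by the given angular displacements."""
    period = geometry.sample_period_ms
    xs = [40.0]
    for s in seps_deg:
        xs.append(xs[-1] + geometry.deg_to_px(s))
    x = np.concatenate([np.full(n_each, xv) for xv in xs])
    t = np.arange(len(x)) * period
    return binocular_combine(binocular_frame(t, x, np.full(len(x), 48.0)))


def test_fixations_closer_than_half_degree_merged(geometry120):
    cyc = _station_stream(geometry120, [0.3])
    seq = detect_events(cyc, geometry120)
    merged = merge_fixations(seq.fixations, cyc, geometry120)
    assert len(merged) == 1


def test_fixations_at_0_8_degree_not_merged(geometry120):
    cyc = _station_stream(geometry120, [0.8])
    seq = detect_events(cyc, geometry120)
    merged = merge_fixations(seq.fixations, cyc, geometry120)
    assert len(merged) == 2


def test_merge_centroid_is_duration_weighted(geometry120):
    """100 ms at x=0 deg and 300 ms at x=0.4 deg merge to 0.3 deg."""
    period = geometry120.sample_period_ms
    n1 = int(round(100.0 / period))
    n2 = int(round(300.0 / period))
    x0 = 40.0
    x1 = x0 + geometry120.deg_to_px(0.4)
    x = np.concatenate([np.full(n1, x0), np.full(n2, x1)])
    cyc = binocular_combine(
        binocular_frame(np.arange(len(x)) * period, x, np.full(len(x), 48.0))
    )
    seq = detect_events(cyc, geometry120)
    merged = merge_fixations(seq.fixations, cyc, geometry120)
    assert len(merged) == 1
    got_deg = geometry120.px_to_deg(merged[0].cx_px - x0)
    assert got_deg == pytest.approx(0.3, abs=0.02)


def test_merging_is_idempotent(geometry120):
    cyc = _station_stream(geometry120, [0.3, 0.8, 0.2, 0.45])
    seq = detect_events(cyc, geometry120)
    once = merge_fixations(seq.fixations, cyc, geometry120)
    twice = merge_fixations(once, cyc, geometry120)
    assert [(f.onset_ms, f.cx_px) for f in once] == [(f.onset_ms, f.cx_px) for f in twice]


# ---------------------------------------------------------------------------
# validity filter


def _fake_fixation(duration_ms, rms_deg):
    from gazesal.events import Fixation

    return Fixation(
        onset_ms=0.0,
        offset_ms=duration_ms,
        cx_px=0.0,
        cy_px=0.0,
        rms_deg=rms_deg,
        n_samples=int(duration_ms // 8),
        sample_index=np.arange(int(duration_ms // 8)),
    )


@pytest.mark.parametrize(
    "duration,rms,kept",
    [(90.0, 0.2, False), (120.0, 0.2, True), (200.0, 1.5, False), (100.0, 0.2, False)],
)
def test_duration_and_rms_filter(duration, rms, kept):
    out = filter_fixations([_fake_fixation(duration, rms)])
    assert (len(out) == 1) == kept


def test_filter_monotone_in_min_duration():
    fixes = [_fake_fixation(d, 0.2) for d in np.linspace(50, 400, 15)]
    counts = [
        len(filter_fixations(fixes, min_duration_ms=m)) for m in [50, 100, 150, 250]
    ]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# planted-stream recovery (noise-free)


@pytest.mark.parametrize("rate", [120.0, 300.0])
def test_noise_free_recovery_counts_and_onsets(rate, geometry120, geometry300):
    geometry = geometry120 if rate == 120.0 else geometry300
    params = ParticipantParams(
        pid="p0",
        jitter_sd_px=0.0,
        blink_rate=0.0,
        pupil_noise_sd_mm=0.0,
        vergence_px=0.0,
    )
    scenes = [SceneSpec("s0", "non-human", 4000.0, static_patch=True, moving_patch=False)]
    from gazesal.synth.video import generate_video

    videos = [generate_video(s, geometry, seed=4) for s in scenes]
    raw, truth = generate_gaze_stream(params, videos, geometry, seed=21)
    fixes, _, _ = detect_fixations(raw, geometry, smooth=False)
    assert len(fixes) == len(truth.fixations)
    period = geometry.sample_period_ms
    for got, planted in zip(fixes, truth.fixations):
        assert abs(got.onset_ms - planted.onset_ms) <= period + 1e-9
        assert abs(got.cx_px - planted.cx_px) < 1.0
        assert abs(got.cy_px - planted.cy_px) < 1.0
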