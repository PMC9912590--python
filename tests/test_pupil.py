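"""Pupillometry: trace cleaning, standardisation, latency-shifted responses,
and the early/late temporal decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazesal.pupil import (
    ComponentModel,
    fit_time_components,
    fixation_pupil_response,
    preprocess_pupil,
    standardize_pupil,
    varimax,
    weight_response,
)


def _trace(p, rate_hz=120.0):
    p = np.asarray(p, dtype=float)
    t = np.arange(len(p)) * 1000.0 / rate_hz
    return t, p


# ---------------------------------------------------------------------------
# preprocessing


def test_clean_constant_trace_unchanged():
    t, p = _trace(np.full(200, 3.6))
    out = preprocess_pupil(t, p)
    assert out.usable
    assert np.allclose(out.pupil_mm, 3.6)


def test_single_spike_removed_by_mad_rule_and_interpolated():
    """A one-sample 0.2 mm jump makes a dilation speed far beyond
    median + 16 * MAD of the baseline speeds (hand computation: baseline
    speeds ~ N(0, 1e-4) mm/ms, spike speed 0.024 mm/ms)."""
    rng = np.random.default_rng(5)
    p = 3.6 + rng.normal(0, 1e-3, 300)
    p[150] += 0.2
    t, p = _trace(p)
    out = preprocess_pupil(t, p, median_window=1)
    assert abs(out.pupil_mm[150] - 3.6) < 0.02  # spike gone, gap interpolated
    assert out.valid[150]


def test_all_zero_trace_flagged_unusable():
    t, p = _trace(np.zeros(100))
    out = preprocess_pupil(t, p)
    assert not out.usable


def test_implausible_diameters_removed():
    p = np.full(100, 3.6)
    p[10] = 0.4
    p[20] = 9.5
    t, p = _trace(p)
    out = preprocess_pupil(t, p)
    assert np.allclose(out.pupil_mm[out.valid], 3.6, atol=1e-9)


# ---------------------------------------------------------------------------
# standardisation


def test_constant_trace_standardizes_to_one():
    t, p = _trace(np.full(50, 3.6))
    out = standardize_pupil(preprocess_pupil(t, p))
    assert np.allclose(out.pupil_mm[out.valid], 1.0)


def test_standardized_sample_ratio():
    t, p = _trace(np.array([3.96] + [3.6] * 99))
    trace = preprocess_pupil(t, p, median_window=1, mad_multiplier=1e9)
    out = standardize_pupil(trace)
    assert out.pupil_mm[0] == pytest.approx(3.96 / np.mean(p), abs=1e-12)


@settings(deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_standardized_trace_mean_is_one(seed):
    rng = np.random.default_rng(seed)
    t, p = _trace(np.clip(rng.normal(3.6, 0.3, 120), 1.5, 8.5))
    out = standardize_pupil(preprocess_pupil(t, p, mad_multiplier=1e9))
    assert np.nanmean(out.pupil_mm[out.valid]) == pytest.approx(1.0, abs=1e-9)


def test_scale_invariance_of_standardized_response():
    """Uniform rescaling of the raw trace leaves responses unchanged."""
    rng = np.random.default_rng(9)
    t, p = _trace(np.clip(3.6 + rng.normal(0, 0.1, 400), 1.2, 8.8))
    r1 = fixation_pupil_response(
        standardize_pupil(preprocess_pupil(t, p)), 500.0, 800.0
    )
    r2 = fixation_pupil_response(
        standardize_pupil(preprocess_pupil(t, 1.7 * p)), 500.0, 800.0
    )
    assert r1 == pytest.approx(r2, abs=1e-9)


# ---------------------------------------------------------------------------
# per-fixation response


def test_flat_trace_response_is_one():
    t, p = _trace(np.full(400, 3.6))
    s = standardize_pupil(preprocess_pupil(t, p))
    assert fixation_pupil_response(s, 500.0, 800.0) == pytest.approx(1.0)


def test_empty_window_is_missing():
    t, p = _trace(np.full(100, 3.6))
    s = standardize_pupil(preprocess_pupil(t, p))
    assert np.isnan(fixation_pupil_response(s, 5000.0, 5300.0))


def test_planted_step_captured_through_latency_window():
    """A +10% step starting 300 ms after fixation onset is inside the
    [onset+200, offset+400] ms window and dominates its mean."""
    t, p = _trace(np.full(600, 3.6))
    onset, offset = 1000.0, 1400.0
    p[t >= onset + 300.0] = 3.96
    s = standardize_pupil(preprocess_pupil(t, p, mad_multiplier=1e9, median_window=1))
    r = fixation_pupil_response(s, onset, offset)
    base = np.mean(p)
    # window [1200, 1800]: step active from 1300 -> 5/6 of window at 3.96
    expect = (100.0 / 600.0) * (3.6 / base) + (500.0 / 600.0) * (3.96 / base)
    assert r == pytest.approx(expect, abs=5e-3)
    # the shifted window catches the step where an unshifted early window
    # would not: the response clearly exceeds the pre-step level
    pre_step = fixation_pupil_response(s, 200.0, 600.0)
    assert r > pre_step


# ---------------------------------------------------------------------------
# temporal components


def _two_bump_records(seed, n_participants=12, n_scenes=6, n_fix=40):
    """Responses built from an early bump plus an independent late bump."""
    rng = np.random.default_rng(seed)
    rows = []
    centers = np.linspace(125, 4875, 20)
    early = np.exp(-0.5 * ((centers - 900) / 500) ** 2)
    late = np.exp(-0.5 * ((centers - 3800) / 600) ** 2)
    for p in range(n_participants):
        for s in range(n_scenes):
            a = rng.normal(1.0, 0.5)
            b = rng.normal(1.0, 0.5)
            for _ in range(n_fix):
                tt = rng.uniform(0, 5000)
                k = np.argmin(np.abs(centers - tt))
                rows.append(
                    {
                        "participant": f"p{p}",
                        "scene": f"s{s}",
                        "t_scene_ms": tt,
                        "pupil_response": 1.0
                        + 0.1 * a * early[k]
                        + 0.1 * b * late[k]
                        + rng.normal(0, 0.005),
                    }
                )
    return pd.DataFrame(rows)


def test_pca_varimax_separates_early_and_late_bumps():
    model = fit_time_components(_two_bump_records(0))
    c1, c2 = model.loading_centroids_ms()
    assert c1 < 2500 < c2
    # the early component loads on the early bump's bins, the late on the late
    centers = 0.5 * (model.bin_edges_ms[:-1] + model.bin_edges_ms[1:])
    assert centers[np.argmax(np.abs(model.loadings[:, 0]))] < 2200
    assert centers[np.argmax(np.abs(model.loadings[:, 1]))] > 2800


def test_rotated_loadings_orthogonal():
    model = fit_time_components(_two_bump_records(1))
    dot = model.loadings[:, 0] @ model.loadings[:, 1]
    assert abs(dot) < 1e-6


def test_two_components_capture_planted_variance():
    model = fit_time_components(_two_bump_records(2))
    assert model.explained_variance_ratio.sum() > 0.5


def test_component_labels_stable_across_seeds():
    for seed in range(8):
        model = fit_time_components(_two_bump_records(seed))
        c1, c2 = model.loading_centroids_ms()
        assert c1 < c2


def test_too_few_bins_rejected():
    with pytest.raises(ValueError):
        fit_time_components(_two_bump_records(0), n_bins=2)


def test_varimax_preserves_orthonormality():
    rng = np.random.default_rng(4)
    q, _ = np.linalg.qr(rng.normal(size=(20, 2)))
    rot, R = varimax(q)
    assert np.allclose(rot.T @ rot, np.eye(2), atol=1e-8)
    assert np.allclose(R.T @ R, np.eye(2), atol=1e-10)


# ---------------------------------------------------------------------------
# response weighting


def test_weighted_response_arithmetic():
    edges = np.linspace(0, 5000, 21)
    loadings = np.zeros((20, 2))
    loadings[2, 0] = 0.5
    loadings[2, 1] = 0.0
    model = ComponentModel(
        bin_edges_ms=edges, loadings=loadings, explained_variance_ratio=np.array([0.5, 0.3])
    )
    pr1, pr2 = weight_response(1.1, 550.0, model)  # bin 2 covers [500, 750) ms
    assert pr1 == pytest.approx(0.55)
    assert pr2 == 0.0


def test_weighting_outside_window_rejected():
    edges = np.linspace(0, 5000, 21)
    model = ComponentModel(
        bin_edges_ms=edges,
        loadings=np.ones((20, 2)),
        explained_variance_ratio=np.array([0.5, 0.3]),
    )
    with pytest.raises(ValueError):
        weight_response(1.0, 5200.0, model)
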