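"""Parameter-boundary measurements of the analysis rules.

Each function recovers one of the pipeline's printed decision boundaries by
sweeping synthetic inputs through the public API and locating the flip point
(bisection), rather than reading the configured constant back.  They serve
the package's self-verification: a change that silently breaks a threshold
moves the measured boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import (
    Fixation,
    binocular_combine,
    detect_events,
    filter_fixations,
    interpolate_gaps,
    merge_fixations,
)
from .geometry import ScreenGeometry
from .scenes import SceneSegment, assign_scenes

__all__ = [
    "measured_velocity_threshold",
    "measured_duration_filter_ms",
    "measured_rms_filter_deg",
    "measured_merge_threshold_deg",
    "measured_interpolation_cap_ms",
    "measured_chop_window_ms",
    "red_frame_luminance",
    "planted_two_component_records",
]


def _binocular(t, x, y, valid=None):
    x = np.asarray(x, dtype=float)
    if valid is None:
        valid = np.isfinite(x)
    return pd.DataFrame(
        {
            "timestamp_ms": np.asarray(t, dtype=float),
            "gx_left_px": x,
            "gy_left_px": y,
            "gx_right_px": x,
            "gy_right_px": y,
            "pupil_left_mm": 3.5,
            "pupil_right_mm": 3.5,
            "valid_left": np.asarray(valid).astype(int),
            "valid_right": np.asarray(valid).astype(int),
        }
    )


def _constant_velocity_is_fixation(geometry: ScreenGeometry, deg_per_s: float) -> bool:
    period = geometry.sample_period_ms
    n = int(round(300.0 / period))
    t = np.arange(n) * period
    step = geometry.deg_to_px(deg_per_s * period / 1000.0)
    x = geometry.width_px / 2.0 + (np.arange(n) - n / 2.0) * step
    y = np.full(n, geometry.height_px / 2.0)
    cyc = binocular_combine(_binocular(t, x, y))
    return len(detect_events(cyc, geometry).fixations) > 0


def measured_velocity_threshold(
    geometry: ScreenGeometry, lo: float = 1.0, hi: float = 40.0, tol: float = 0.01
) -> float:
    """Planted angular velocity (deg/s) at which classification flips from
    fixation to saccade, located by bisection on constant-velocity traces."""
    if not _constant_velocity_is_fixation(geometry, lo):
        raise RuntimeError("lower bracket already classified as saccade")
    if _constant_velocity_is_fixation(geometry, hi):
        raise RuntimeError("upper bracket still classified as fixation")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _constant_velocity_is_fixation(geometry, mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _fabricated_fixation(duration_ms: float, rms_deg: float) -> Fixation:
    return Fixation(
        onset_ms=0.0,
        offset_ms=duration_ms,
        cx_px=0.0,
        cy_px=0.0,
        rms_deg=rms_deg,
        n_samples=max(2, int(duration_ms // 8)),
        sample_index=np.arange(2),
    )


def measured_duration_filter_ms(lo: float = 50.0, hi: float = 200.0, tol: float = 1e-3) -> float:
    """Duration (ms) at which the validity filter flips from drop to keep."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        kept = bool(filter_fixations([_fabricated_fixation(mid, 0.2)]))
        lo, hi = (lo, mid) if kept else (mid, hi)
    return 0.5 * (lo + hi)


def measured_rms_filter_deg(lo: float = 0.1, hi: float = 2.0, tol: float = 1e-5) -> float:
    """RMS dispersion (deg) at which the validity filter flips keep -> drop."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        kept = bool(filter_fixations([_fabricated_fixation(300.0, mid)]))
        lo, hi = (mid, hi) if kept else (lo, mid)
    return 0.5 * (lo + hi)


def _stations_merge(geometry: ScreenGeometry, sep_deg: float) -> bool:
    period = geometry.sample_period_ms
    n_each = int(round(200.0 / period))
    x0 = geometry.width_px * 0.4
    x1 = x0 + geometry.deg_to_px(sep_deg)
    x = np.concatenate([np.full(n_each, x0), np.full(n_each, x1)])
    t = np.arange(len(x)) * period
    cyc = binocular_combine(_binocular(t, x, np.full(len(x), geometry.height_px / 2.0)))
    seq = detect_events(cyc, geometry)
    merged = merge_fixations(seq.fixations, cyc, geometry)
    return len(merged) == 1


def measured_merge_threshold_deg(
    geometry: ScreenGeometry, lo: float = 0.1, hi: float = 1.5, tol: float = 1e-3
) -> float:
    """Centroid separation (deg) at which consecutive fixations stop merging,
    measured end-to-end through detection + merging on two-station streams."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if _stations_merge(geometry, mid) else (lo, mid)
    return 0.5 * (lo + hi)


def measured_interpolation_cap_ms(geometry: ScreenGeometry) -> float:
    """Largest missing-data duration (ms) that still gets interpolated,
    swept over gap lengths on the sampling grid (flanks 0.2 deg apart)."""
    period = geometry.sample_period_ms
    sep_px = geometry.deg_to_px(0.2)
    longest_filled = 0.0
    for n_missing in range(1, int(round(200.0 / period)) + 1):
        n = 30 + n_missing
        t = np.arange(n) * period
        x = np.full(n, geometry.width_px * 0.4)
        x[15 + n_missing :] += sep_px
        valid = np.ones(n)
        x[15 : 15 + n_missing] = np.nan
        valid[15 : 15 + n_missing] = 0
        cyc = binocular_combine(_binocular(t, x, np.full(n, 40.0), valid=valid))
        out = interpolate_gaps(cyc, geometry)
        if out["valid"].all():
            longest_filled = max(longest_filled, n_missing * period)
    return longest_filled


def measured_chop_window_ms(lo: float = 3000.0, hi: float = 7900.0, tol: float = 1e-3) -> float:
    """Time-in-scene (ms) beyond which fixations are excluded from an
    8000 ms scene, located by bisection on planted fixation onsets."""
    seg = [SceneSegment("v", "s0", "human", 0.0, 8000.0)]

    def retained(onset: float) -> bool:
        fixes = pd.DataFrame(
            {
                "fixation_id": [0],
                "onset_ms": [onset],
                "offset_ms": [onset + 100.0],
                "duration_ms": [100.0],
                "cx_px": [10.0],
                "cy_px": [10.0],
                "rms_deg": [0.1],
                "n_samples": [10],
            }
        )
        return len(assign_scenes(fixes, seg)) == 1

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if retained(mid) else (lo, mid)
    return 0.5 * (lo + hi)


def red_frame_luminance() -> float:
    """Global luminance of a pure-red linear-light frame."""
    from .features import luminance_map

    frame = np.zeros((16, 16, 3))
    frame[..., 0] = 1.0
    _, global_lum = luminance_map(frame, linearize=False)
    return global_lum


def planted_two_component_records(
    seed: int,
    n_participants: int = 12,
    n_scenes: int = 6,
    n_fix: int = 40,
    early_center_ms: float = 900.0,
    late_center_ms: float = 3800.0,
) -> pd.DataFrame:
    """Synthetic pupil-response records with independent early and late
    response components (the two-factor structure the temporal PCA targets).

    Each participant x scene profile mixes an early and a late Gaussian bump
    over time-in-scene with independent random amplitudes, so the true
    loading structure is known: one component early, one late.
    """
    rng = np.random.default_rng(seed)
    centers = np.linspace(125, 4875, 20)
    early = np.exp(-0.5 * ((centers - early_center_ms) / 500.0) ** 2)
    late = np.exp(-0.5 * ((centers - late_center_ms) / 600.0) ** 2)
    rows = []
    for p in range(n_participants):
        for s in range(n_scenes):
            a = rng.normal(1.0, 0.5)
            b = rng.normal(1.0, 0.5)
            for _ in range(n_fix):
                tt = rng.uniform(0, 5000)
                k = int(np.argmin(np.abs(centers - tt)))
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
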