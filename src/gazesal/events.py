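"""Fixation and saccade detection from raw binocular gaze streams.

The pipeline follows the velocity-threshold (I-VT) event identification used
for the study recordings: binocular combination, temporal (20-sample) and
spatial (8 mm) smoothing, linear interpolation of short gaps (<= 100 ms within
a 1 degree displacement), a 20 deg/s velocity threshold, merging of consecutive
fixations closer than 0.5 degrees, and a validity filter (> 100 ms duration,
< 1 degree RMS dispersion).

Raw streams are pandas DataFrames in the Tobii-like tab-separated layout
(``timestamp_ms, gx_left_px, gy_left_px, gx_right_px, gy_right_px,
pupil_left_mm, pupil_right_mm, valid_left, valid_right``); the cyclopean
stream produced by :func:`binocular_combine` has columns
``t_ms, x, y, pupil, valid``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

__all__ = [
    "Fixation",
    "EventSequence",
    "binocular_combine",
    "smooth_gaze",
    "interpolate_gaps",
    "angular_velocity",
    "detect_events",
    "merge_fixations",
    "filter_fixations",
    "detect_fixations",
    "fixations_to_frame",
]

GAZE_COLUMNS = [
    "timestamp_ms",
    "gx_left_px",
    "gy_left_px",
    "gx_right_px",
    "gy_right_px",
    "pupil_left_mm",
    "pupil_right_mm",
    "valid_left",
    "valid_right",
]


@dataclass
class Fixation:
    """A detected fixation: centroid, extent, and member samples."""

    onset_ms: float
    offset_ms: float
    cx_px: float
    cy_px: float
    rms_deg: float
    n_samples: int
    sample_index: np.ndarray = field(repr=False)
    scene_id: object = None
    t_scene_ms: float = float("nan")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class EventSequence:
    """Ordered fixations and saccades with per-sample labels.

    ``labels`` holds one of ``{"fixation", "saccade", "missing"}`` per input
    sample; labelled samples are partitioned between the two event classes.
    """

    fixations: list
    saccades: list  # list of (onset_ms, offset_ms) tuples
    labels: np.ndarray


def binocular_combine(samples: pd.DataFrame) -> pd.DataFrame:
    """Combine a binocular stream into a cyclopean stream.

    Gaze and pupil are the mean over valid eyes; samples with both eyes
    invalid are marked missing (NaN position/pupil, ``valid=False``).
    """
    if len(samples) == 0:
        raise ValueError("empty gaze stream")
    vl = samples["valid_left"].to_numpy().astype(bool)
    vr = samples["valid_right"].to_numpy().astype(bool)

    def _mean(lcol: str, rcol: str) -> np.ndarray:
        left = samples[lcol].to_numpy(dtype=float)
        right = samples[rcol].to_numpy(dtype=float)
        out = np.full(len(samples), np.nan)
        both = vl & vr
        out[both] = 0.5 * (left[both] + right[both])
        only_l = vl & ~vr
        out[only_l] = left[only_l]
        only_r = vr & ~vl
        out[only_r] = right[only_r]
        return out

    out = pd.DataFrame(
        {
            "t_ms": samples["timestamp_ms"].to_numpy(dtype=float),
            "x": _mean("gx_left_px", "gx_right_px"),
            "y": _mean("gy_left_px", "gy_right_px"),
            "pupil": _mean("pupil_left_mm", "pupil_right_mm"),
            "valid": vl | vr,
        }
    )
    # a "valid" sample without finite coordinates is still missing
    bad = ~np.isfinite(out["x"].to_numpy()) | ~np.isfinite(out["y"].to_numpy())
    out.loc[bad, "valid"] = False
    return out


def _nan_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average ignoring NaNs; edge windows shrink."""
    n = len(values)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    out = np.full(n, np.nan)
    finite = np.isfinite(values)
    csum = np.cumsum(np.where(finite, values, 0.0))
    ccnt = np.cumsum(finite.astype(int))
    for i in range(n):
        lo = max(0, i - half_lo)
        hi = min(n - 1, i + half_hi)
        total = csum[hi] - (csum[lo - 1] if lo > 0 else 0.0)
        cnt = ccnt[hi] - (ccnt[lo - 1] if lo > 0 else 0)
        if cnt > 0 and finite[i]:
            out[i] = total / cnt
    return out


def smooth_gaze(
    samples: pd.DataFrame,
    geometry: ScreenGeometry,
    temporal_window: int = 20,
    spatial_scale_mm: float = 8.0,
) -> pd.DataFrame:
    """Temporal then spatial smoothing of a cyclopean gaze stream.

    Temporal smoothing is a centred moving average over ``temporal_window``
    samples (missing samples are excluded from windows; edge windows shrink).
    The spatial step suppresses sub-scale excursions: each sample is replaced
    by the average of the window members lying within ``spatial_scale_mm``
    of it on screen, so structure smaller than the spatial scale is averaged
    away while larger displacements (real gaze shifts) survive.
    Missing samples stay missing; output length equals input length.
    """
    if temporal_window < 1:
        raise ValueError("temporal window must be >= 1")
    out = samples.copy()
    x = samples["x"].to_numpy(dtype=float).copy()
    y = samples["y"].to_numpy(dtype=float).copy()
    invalid = ~samples["valid"].to_numpy().astype(bool)
    x[invalid] = np.nan
    y[invalid] = np.nan

    xs = _nan_moving_average(x, temporal_window)
    ys = _nan_moving_average(y, temporal_window)

    # spatial pass on the temporally smoothed trace
    scale_px = spatial_scale_mm / geometry.mm_per_px
    n = len(xs)
    half_lo = (temporal_window - 1) // 2
    half_hi = temporal_window // 2
    xo = xs.copy()
    yo = ys.copy()
    for i in range(n):
        if not np.isfinite(xs[i]):
            continue
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi + 1)
        wx = xs[lo:hi]
        wy = ys[lo:hi]
        near = (
            np.isfinite(wx)
            & (np.hypot(wx - xs[i], wy - ys[i]) <= scale_px)
        )
        if near.sum() > 0:
            xo[i] = wx[near].mean()
            yo[i] = wy[near].mean()
    out["x"] = xo
    out["y"] = yo
    return out


def interpolate_gaps(
    samples: pd.DataFrame,
    geometry: ScreenGeometry,
    max_gap_ms: float = 100.0,
    max_displacement_deg: float = 1.0,
) -> pd.DataFrame:
    """Linearly interpolate short gaps of missing data.

    A gap is a run of missing samples flanked on both sides by valid samples.
    It is filled (gaze and pupil, linear in time) only when its duration --
    the number of missing samples times the nominal sample period -- is at
    most ``max_gap_ms`` AND the flanking gaze positions are within
    ``max_displacement_deg`` of visual angle.  Gaps touching the stream
    boundary are never filled.
    """
    out = samples.copy()
    t = out["t_ms"].to_numpy(dtype=float)
    valid = out["valid"].to_numpy().astype(bool).copy()
    x = out["x"].to_numpy(dtype=float).copy()
    y = out["y"].to_numpy(dtype=float).copy()
    p = out["pupil"].to_numpy(dtype=float).copy()
    period = geometry.sample_period_ms

    n = len(t)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        # gap is samples [i, j); flanks i-1 and j
        if i > 0 and j < n:
            gap_ms = (j - i) * period
            disp = float(
                geometry.separation_deg(x[i - 1], y[i - 1], x[j], y[j])
            )
            if gap_ms <= max_gap_ms and disp <= max_displacement_deg:
                frac = (t[i:j] - t[i - 1]) / (t[j] - t[i - 1])
                x[i:j] = x[i - 1] + frac * (x[j] - x[i - 1])
                y[i:j] = y[i - 1] + frac * (y[j] - y[i - 1])
                if np.isfinite(p[i - 1]) and np.isfinite(p[j]):
                    p[i:j] = p[i - 1] + frac * (p[j] - p[i - 1])
                valid[i:j] = True
        i = j
    out["x"] = x
    out["y"] = y
    out["pupil"] = p
    out["valid"] = valid
    return out


def angular_velocity(samples: pd.DataFrame, geometry: ScreenGeometry) -> np.ndarray:
    """Per-sample angular velocity in deg/s.

    ``v[i]`` is the angular displacement between samples ``i-1`` and ``i``
    divided by their time difference; undefined (NaN) at the first sample and
    across missing samples.
    """
    t = samples["t_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples for velocity")
    x = samples["x"].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    valid = samples["valid"].to_numpy().astype(bool)
    v = np.full(len(t), np.nan)
    ok = valid[1:] & valid[:-1]
    disp = geometry.separation_deg(x[:-1], y[:-1], x[1:], y[1:])
    dt_s = np.diff(t) / 1000.0
    with np.errstate(invalid="ignore", divide="ignore"):
        vv = disp / dt_s
    v[1:][ok] = vv[ok]
    return v


def _make_fixation(samples: pd.DataFrame, geometry: ScreenGeometry, idx: np.ndarray) -> Fixation:
    t = samples["t_ms"].to_numpy(dtype=float)[idx]
    x = samples["x"].to_numpy(dtype=float)[idx]
    y = samples["y"].to_numpy(dtype=float)[idx]
    cx = float(x.mean())
    cy = float(y.mean())
    rms = _rms_deg(x, y, cx, cy, geometry)
    period = geometry.sample_period_ms
    return Fixation(
        onset_ms=float(t[0]),
        offset_ms=float(t[-1] + period),
        cx_px=cx,
        cy_px=cy,
        rms_deg=rms,
        n_samples=len(idx),
        sample_index=np.asarray(idx, dtype=int),
    )


def _rms_deg(x, y, cx, cy, geometry: ScreenGeometry) -> float:
    d = geometry.separation_deg(cx, cy, x, y)
    return float(np.sqrt(np.mean(np.square(d))))


def detect_events(
    samples: pd.DataFrame,
    geometry: ScreenGeometry,
    velocity_threshold: float = 20.0,
) -> EventSequence:
    """Label samples fixation/saccade by the velocity threshold.

    Maximal runs of valid samples with velocity strictly below the threshold
    become fixation candidates; runs at or above it become saccades.  Each
    sample is classified by the smaller of its incoming and outgoing
    velocities, so a sample that has already arrived at a stable location
    starts the fixation even though the transition into it was fast (this
    keeps onsets sample-exact).  All-missing input yields an empty sequence.
    """
    n = len(samples)
    v = angular_velocity(samples, geometry)  # v[i]: displacement i-1 -> i
    valid = samples["valid"].to_numpy().astype(bool)
    v_in = v
    v_out = np.append(v[1:], np.nan)
    v_min = np.where(
        np.isnan(v_in), v_out, np.where(np.isnan(v_out), v_in, np.fmin(v_in, v_out))
    )
    labels = np.array(["missing"] * n, dtype=object)
    is_fix = np.isfinite(v_min) & (v_min < velocity_threshold)
    is_sac = np.isfinite(v_min) & (v_min >= velocity_threshold)
    labels[is_fix & valid] = "fixation"
    labels[is_sac & valid] = "saccade"

    fixations: list[Fixation] = []
    saccades: list[tuple[float, float]] = []
    t = samples["t_ms"].to_numpy(dtype=float)
    period = geometry.sample_period_ms
    i = 0
    while i < n:
        if labels[i] == "missing":
            i += 1
            continue
        j = i + 1
        while j < n and labels[j] == labels[i]:
            # a fast incoming transition starts a new fixation even when the
            # arriving sample itself is stable (instantaneous displacement)
            if (
                labels[i] == "fixation"
                and np.isfinite(v_in[j])
                and v_in[j] >= velocity_threshold
            ):
                break
            j += 1
        idx = np.arange(i, j)
        if labels[i] == "fixation":
            fixations.append(_make_fixation(samples, geometry, idx))
        else:
            saccades.append((float(t[i]), float(t[j - 1] + period)))
        i = j
    return EventSequence(fixations=fixations, saccades=saccades, labels=labels)


def merge_fixations(
    fixations: list,
    samples: pd.DataFrame,
    geometry: ScreenGeometry,
    merge_threshold_deg: float = 0.5,
) -> list:
    """Merge consecutive fixations closer than the displacement threshold.

    Applied iteratively left-to-right until stable.  The merged centroid is
    the duration-weighted mean of the member centroids; RMS dispersion is
    recomputed over the pooled member samples.
    """
    fixations = list(fixations)
    changed = True
    while changed:
        changed = False
        out: list[Fixation] = []
        i = 0
        while i < len(fixations):
            cur = fixations[i]
            while i + 1 < len(fixations):
                nxt = fixations[i + 1]
                sep = float(
                    geometry.separation_deg(cur.cx_px, cur.cy_px, nxt.cx_px, nxt.cy_px)
                )
                if sep < merge_threshold_deg:
                    cur = _merge_pair(cur, nxt, samples, geometry)
                    i += 1
                    changed = True
                else:
                    break
            out.append(cur)
            i += 1
        fixations = out
    return fixations


def _merge_pair(a: Fixation, b: Fixation, samples: pd.DataFrame, geometry: ScreenGeometry) -> Fixation:
    wa, wb = a.duration_ms, b.duration_ms
    cx = (a.cx_px * wa + b.cx_px * wb) / (wa + wb)
    cy = (a.cy_px * wa + b.cy_px * wb) / (wa + wb)
    idx = np.concatenate([a.sample_index, b.sample_index])
    x = samples["x"].to_numpy(dtype=float)[idx]
    y = samples["y"].to_numpy(dtype=float)[idx]
    rms = _rms_deg(x, y, cx, cy, geometry)
    return Fixation(
        onset_ms=a.onset_ms,
        offset_ms=b.offset_ms,
        cx_px=float(cx),
        cy_px=float(cy),
        rms_deg=rms,
        n_samples=a.n_samples + b.n_samples,
        sample_index=idx,
        scene_id=a.scene_id,
        t_scene_ms=a.t_scene_ms,
    )


def filter_fixations(
    fixations: list,
    min_duration_ms: float = 100.0,
    max_rms_deg: float = 1.0,
) -> list:
    """Keep only fixations with duration > min AND RMS dispersion < max."""
    return [
        f
        for f in fixations
        if f.duration_ms > min_duration_ms and f.rms_deg < max_rms_deg
    ]


def detect_fixations(
    raw: pd.DataFrame,
    geometry: ScreenGeometry,
    temporal_window: int = 20,
    spatial_scale_mm: float = 8.0,
    max_gap_ms: float = 100.0,
    max_displacement_deg: float = 1.0,
    velocity_threshold: float = 20.0,
    merge_threshold_deg: float = 0.5,
    min_duration_ms: float = 100.0,
    max_rms_deg: float = 1.0,
    smooth: bool = True,
) -> tuple[list, EventSequence, pd.DataFrame]:
    """Full event-detection pipeline from a raw binocular stream.

    Returns ``(valid_fixations, event_sequence, cyclopean_samples)``.
    """
    cyc = binocular_combine(raw)
    if smooth:
        cyc = smooth_gaze(cyc, geometry, temporal_window, spatial_scale_mm)
    cyc = interpolate_gaps(cyc, geometry, max_gap_ms, max_displacement_deg)
    seq = detect_events(cyc, geometry, velocity_threshold)
    merged = merge_fixations(seq.fixations, cyc, geometry, merge_threshold_deg)
    kept = filter_fixations(merged, min_duration_ms, max_rms_deg)
    return kept, replace(seq, fixations=merged), cyc


def fixations_to_frame(fixations: list, geometry: ScreenGeometry | None = None) -> pd.DataFrame:
    """Tabulate fixations (one row each) for TSV output / downstream joins."""
    rows = []
    for k, f in enumerate(fixations):
        row = {
            "fixation_id": k,
            "onset_ms": f.onset_ms,
            "offset_ms": f.offset_ms,
            "duration_ms": f.duration_ms,
            "cx_px": f.cx_px,
            "cy_px": f.cy_px,
            "rms_deg": f.rms_deg,
            "n_samples": f.n_samples,
            "scene_id": f.scene_id,
            "t_scene_ms": f.t_scene_ms,
        }
        if geometry is not None:
            row["cx_deg"] = geometry.px_to_deg(f.cx_px - geometry.width_px / 2.0)
            row["cy_deg"] = geometry.px_to_deg(f.cy_px - geometry.height_px / 2.0)
        rows.append(row)
    cols = [
        "fixation_id",
        "onset_ms",
        "offset_ms",
        "duration_ms",
        "cx_px",
        "cy_px",
        "rms_deg",
        "n_samples",
        "scene_id",
        "t_scene_ms",
    ]
    if geometry is not None:
        cols += ["cx_deg", "cy_deg"]
    return pd.DataFrame(rows, columns=cols)
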