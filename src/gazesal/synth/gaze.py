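"""Synthetic binocular gaze and pupil streams with planted ground truth.

The generator plants a fixation plan per scene (targets drawn among the face
AOI, the salient patches, or random locations, with configurable biases),
simulates saccades as 20-40 ms linear transitions between fixation
centroids, adds within-fixation Gaussian jitter, inserts blinks as
contiguous invalid runs, and synthesises a pupil trace as a participant
baseline plus stimulus-locked responses delayed by a configurable latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..geometry import ScreenGeometry

__all__ = ["ParticipantParams", "PlantedFixation", "StreamTruth", "generate_gaze_stream"]

VALID_RATES = (120.0, 300.0)


@dataclass
class ParticipantParams:
    """Behavioural and physiological parameters of one synthetic participant."""

    pid: str
    group: str = "TD"
    pupil_baseline_mm: float = 3.6
    jitter_sd_px: float = 2.0
    blink_rate: float = 0.05  # target fraction of invalid samples
    face_bias: float = 0.5  # probability a fixation targets the face (human scenes)
    salience_bias: float = 0.3  # probability a fixation targets a salient patch
    pupil_event_amp_mm: dict = field(
        default_factory=lambda: {"human": 0.08, "non-human": 0.08}
    )
    pupil_latency_ms: float = 300.0
    pupil_noise_sd_mm: float = 0.01
    pupil_kernel: str = "gamma"  # "gamma" | "step"
    vergence_px: float = 2.0
    fixation_mean_ms: float = 330.0
    fixation_sd_ms: float = 80.0


@dataclass
class PlantedFixation:
    onset_ms: float  # in video time
    offset_ms: float
    cx_px: float
    cy_px: float
    scene_id: str
    target: str  # "face" | "static" | "moving" | "random"


@dataclass
class StreamTruth:
    """Planted ground truth of one participant's stream."""

    pid: str
    fixations: list
    pupil_events: list  # (event_time_ms, amplitude_mm)
    seed: int
    total_duration_ms: float


def _gamma_kernel(t_ms: np.ndarray, t_max: float = 930.0, n: float = 10.1) -> np.ndarray:
    """Pupillary impulse response (unit peak at ``t_max`` ms)."""
    t = np.maximum(np.asarray(t_ms, dtype=float), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (t / t_max) ** n * np.exp(n * (1.0 - t / t_max))
    h[t <= 0] = 0.0
    return h


def _plan_scene_fixations(
    rng, scene, geometry: ScreenGeometry, params: ParticipantParams
) -> list[PlantedFixation]:
    """Fixation plan for one scene; consecutive centroids kept > 1.5 deg apart."""
    h, w = geometry.height_px, geometry.width_px
    min_sep_px = geometry.deg_to_px(1.5)
    margin = 6
    truth = getattr(scene, "truth", None)
    spec = getattr(scene, "spec", scene)
    plan: list[PlantedFixation] = []
    t = 0.0
    prev = None
    while True:
        dur = float(np.clip(rng.normal(params.fixation_mean_ms, params.fixation_sd_ms), 150, 900))
        if t + dur > spec.duration_ms:
            break
        for _ in range(50):
            u = rng.uniform()
            if (
                truth is not None
                and truth.face_center is not None
                and u < params.face_bias
            ):
                cx, cy = truth.face_center
                cx += rng.normal(0, 3)
                cy += rng.normal(0, 3)
                target = "face"
            elif truth is not None and truth.static_box is not None and u < params.face_bias + params.salience_bias:
                x0, y0, x1, y1 = truth.static_box
                cx, cy = (x0 + x1) / 2 + rng.normal(0, 2), (y0 + y1) / 2 + rng.normal(0, 2)
                target = "static"
            else:
                cx = rng.uniform(margin, w - margin)
                cy = rng.uniform(margin, h - margin)
                target = "random"
            cx = float(np.clip(cx, margin, w - margin))
            cy = float(np.clip(cy, margin, h - margin))
            if prev is None or np.hypot(cx - prev[0], cy - prev[1]) > min_sep_px:
                break
        plan.append(
            PlantedFixation(
                onset_ms=t,
                offset_ms=t + dur,
                cx_px=cx,
                cy_px=cy,
                scene_id=spec.scene_id,
                target=target,
            )
        )
        prev = (cx, cy)
        t += dur + float(rng.uniform(20, 40))  # saccade gap
    return plan


def generate_gaze_stream(
    params: ParticipantParams,
    scenes: list,
    geometry: ScreenGeometry,
    seed: int,
) -> tuple[pd.DataFrame, StreamTruth]:
    """Simulate one participant's binocular stream over the scene sequence.

    ``scenes`` is a list of :class:`~gazesal.synth.video.VideoScene` (or any
    object with ``spec`` and ``truth`` attributes); scenes are presented
    back-to-back in order.  Returns the raw stream in the Tobii-like TSV
    layout plus the planted truth.  Total simulated time equals the sum of
    scene durations.
    """
    if geometry.sampling_rate_hz not in VALID_RATES:
        raise ValueError(
            f"sampling rate must be one of {VALID_RATES} Hz "
            f"(got {geometry.sampling_rate_hz})"
        )
    rng = np.random.default_rng(seed)
    period = geometry.sample_period_ms

    # fixation plan per scene, shifted to video time
    plan: list[PlantedFixation] = []
    offset = 0.0
    total = 0.0
    for scene in scenes:
        spec = getattr(scene, "spec", scene)
        for f in _plan_scene_fixations(rng, scene, geometry, params):
            plan.append(
                PlantedFixation(
                    onset_ms=f.onset_ms + offset,
                    offset_ms=f.offset_ms + offset,
                    cx_px=f.cx_px,
                    cy_px=f.cy_px,
                    scene_id=f.scene_id,
                    target=f.target,
                )
            )
        offset += spec.duration_ms
        total += spec.duration_ms

    n = int(round(total / period))
    t = np.arange(n) * period

    # gaze trajectory: piecewise constant at centroids, linear during saccades
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    for i, f in enumerate(plan):
        sel = (t >= f.onset_ms) & (t < f.offset_ms)
        x[sel] = f.cx_px
        y[sel] = f.cy_px
        if i + 1 < len(plan) and plan[i + 1].onset_ms - f.offset_ms < 80:
            nxt = plan[i + 1]
            sel = (t >= f.offset_ms) & (t < nxt.onset_ms)
            if sel.any():
                frac = (t[sel] - f.offset_ms) / (nxt.onset_ms - f.offset_ms)
                x[sel] = f.cx_px + frac * (nxt.cx_px - f.cx_px)
                y[sel] = f.cy_px + frac * (nxt.cy_px - f.cy_px)
    # fill leading/trailing gaps by holding the nearest planned position
    if plan:
        x[t < plan[0].onset_ms] = plan[0].cx_px
        y[t < plan[0].onset_ms] = plan[0].cy_px
        x[t >= plan[-1].offset_ms] = plan[-1].cx_px
        y[t >= plan[-1].offset_ms] = plan[-1].cy_px

    if params.jitter_sd_px > 0:
        x = x + rng.normal(0, params.jitter_sd_px, n)
        y = y + rng.normal(0, params.jitter_sd_px, n)

    # pupil trace: baseline + stimulus-locked responses + noise
    pupil = np.full(n, params.pupil_baseline_mm)
    events = []
    offset = 0.0
    scene_cat = {}
    for scene in scenes:
        spec = getattr(scene, "spec", scene)
        scene_cat[spec.scene_id] = spec.category
    for f in plan:
        amp = params.pupil_event_amp_mm.get(scene_cat.get(f.scene_id, "non-human"), 0.0)
        if amp == 0.0:
            continue
        onset = f.onset_ms + params.pupil_latency_ms
        events.append((onset, amp))
        if params.pupil_kernel == "step":
            sel = (t >= onset) & (t < f.offset_ms + params.pupil_latency_ms)
            pupil[sel] += amp
        else:
            rel = t - onset
            sel = (rel > 0) & (rel < 4000)
            pupil[sel] += amp * _gamma_kernel(rel[sel])
    if params.pupil_noise_sd_mm > 0:
        pupil = pupil + rng.normal(0, params.pupil_noise_sd_mm, n)

    # blinks: contiguous invalid runs targeting the configured fraction
    valid = np.ones(n, dtype=bool)
    if params.blink_rate >= 1.0:
        valid[:] = False
    elif params.blink_rate > 0:
        mean_len = max(1, int(round(200.0 / period)))
        n_blinks = int(round(params.blink_rate * n / mean_len))
        for _ in range(n_blinks):
            start = int(rng.integers(0, n))
            length = int(rng.integers(max(1, mean_len // 2), mean_len * 2))
            valid[start : start + length] = False
    x[~valid] = np.nan
    y[~valid] = np.nan
    pupil_out = pupil.copy()
    pupil_out[~valid] = np.nan

    verg = params.vergence_px / 2.0
    stream = pd.DataFrame(
        {
            "timestamp_ms": t,
            "gx_left_px": x - verg,
            "gy_left_px": y,
            "gx_right_px": x + verg,
            "gy_right_px": y,
            "pupil_left_mm": pupil_out,
            "pupil_right_mm": pupil_out,
            "valid_left": valid.astype(int),
            "valid_right": valid.astype(int),
        }
    )
    truth = StreamTruth(
        pid=params.pid,
        fixations=plan,
        pupil_events=events,
        seed=seed,
        total_duration_ms=total,
    )
    return stream, truth
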