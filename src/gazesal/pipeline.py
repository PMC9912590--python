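"""End-to-end convenience pipeline over a synthetic (or loaded) cohort.

Ties the stages together: event detection on each participant's stream,
per-scene feature maps, pupil preprocessing and per-fixation responses,
record assembly, and the temporal pupil decomposition.  Each stage remains
individually usable; this module just sequences them with consistent keys.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import detect_fixations, fixations_to_frame
from .features import compute_scene_features
from .geometry import ScreenGeometry
from .pupil import (
    add_weighted_responses,
    fit_time_components,
    fixation_pupil_response,
    preprocess_pupil,
    standardize_pupil,
)
from .scenes import SceneSegment, assemble_records
from .synth.cohort import CohortData

__all__ = ["segments_from_videos", "analyze_cohort"]


def segments_from_videos(videos: list) -> list[SceneSegment]:
    """Scene segments for a back-to-back presentation of generated scenes."""
    segments = []
    onset = 0.0
    for v in videos:
        segments.append(
            SceneSegment(
                video_id="synthetic",
                scene_id=v.spec.scene_id,
                category=v.spec.category,
                onset_ms=onset,
                offset_ms=onset + v.spec.duration_ms,
                age_restricted=v.spec.age_restricted,
            )
        )
        onset += v.spec.duration_ms
    return segments


def analyze_cohort(
    cohort: CohortData,
    geometry: ScreenGeometry,
    smooth: bool = True,
    compute_features: bool = True,
    n_bins: int = 20,
    fit_components: bool = True,
) -> dict:
    """Run the full analysis on a cohort; returns a dict of stage outputs.

    Keys: ``records`` (long-format analysis table), ``fixations`` (pid ->
    table), ``segments``, ``component_model`` (or None), ``features``.
    ``smooth=False`` skips the 20-sample/8 mm smoothing stage, appropriate
    for noise-free streams where sample-exact onsets matter.
    """
    segments = segments_from_videos(cohort.videos)
    frame_times = {v.spec.scene_id: v.frame_times_ms for v in cohort.videos}

    feature_stacks = {}
    masks = {}
    for v in cohort.videos:
        if compute_features:
            maps = compute_scene_features(v.frames)
            feature_stacks[v.spec.scene_id] = {
                "phys": np.stack([m.physical_salience for m in maps]),
                "motion": np.stack([m.motion_salience for m in maps]),
                "lum": np.stack([m.luminance for m in maps]),
            }
        else:
            t = len(v.frames)
            h, w = v.frames.shape[1:3]
            z = np.zeros((t, h, w))
            feature_stacks[v.spec.scene_id] = {"phys": z, "motion": z, "lum": z}
        if v.masks:
            masks[v.spec.scene_id] = v.masks

    fix_tables = {}
    responses = {}
    for pid, (raw, _truth) in cohort.streams.items():
        fixes, _seq, cyc = detect_fixations(raw, geometry, smooth=smooth)
        table = fixations_to_frame(fixes, geometry)
        fix_tables[pid] = table
        trace = preprocess_pupil(
            cyc["t_ms"].to_numpy(), cyc["pupil"].to_numpy(), cyc["valid"].to_numpy()
        )
        if trace.usable:
            strace = standardize_pupil(trace)
            responses[pid] = {
                int(r["fixation_id"]): fixation_pupil_response(
                    strace, r["onset_ms"], r["offset_ms"]
                )
                for _, r in table.iterrows()
            }
        else:
            responses[pid] = {}

    records = assemble_records(
        fix_tables,
        segments,
        feature_stacks,
        frame_times,
        cohort.participants,
        masks=masks,
        pupil_responses=responses,
    )

    model = None
    if fit_components and records["pupil_response"].notna().sum() >= 10:
        try:
            model = fit_time_components(records, n_bins=n_bins)
            records = add_weighted_responses(records, model)
        except ValueError:
            model = None
    return {
        "records": records,
        "fixations": fix_tables,
        "segments": segments,
        "component_model": model,
        "features": feature_stacks,
    }
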