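"""Scene segmentation, gaze-to-map matching, AOI hits, and record assembly.

Videos are segmented at camera cuts into scenes labelled human / non-human;
each scene's analyzable window is its first 5000 ms (shorter scenes keep
their full duration).  Fixations are assigned to scenes by onset, feature
maps and AOI masks are sampled at the fixation centroid in the temporally
nearest frame, and everything is joined into the long-format analysis table
(one row per retained fixation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

__all__ = [
    "SceneSegment",
    "segment_scenes",
    "scenes_from_cuts",
    "assign_scenes",
    "sample_map_at_gaze",
    "aoi_hit",
    "assemble_records",
    "RECORD_COLUMNS",
]

ANALYSIS_WINDOW_MS = 5000.0
AOI_LABELS = ("eyes", "mouth", "face", "body")

RECORD_COLUMNS = [
    "participant",
    "group",
    "scene",
    "category",
    "age_restricted",
    "onset_ms",
    "t_scene_ms",
    "duration_ms",
    "cx_px",
    "cy_px",
    "phys_salience",
    "motion_salience",
    "luminance",
    "pupil_response",
    "pr1",
    "pr2",
    "aoi_eyes",
    "aoi_mouth",
    "aoi_face",
    "aoi_body",
]


@dataclass(frozen=True)
class SceneSegment:
    """One camera-cut-delimited scene of a video."""

    video_id: str
    scene_id: str
    category: str
    onset_ms: float
    offset_ms: float
    age_restricted: bool = False

    def __post_init__(self):
        if self.category not in ("human", "non-human"):
            raise ValueError(f"category must be human/non-human, got {self.category!r}")
        if self.offset_ms <= self.onset_ms:
            raise ValueError("scene duration must be positive")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    @property
    def window_ms(self) -> float:
        """Analyzable window: the scene's first 5000 ms."""
        return min(self.duration_ms, ANALYSIS_WINDOW_MS)


def segment_scenes(manifest: dict) -> list[SceneSegment]:
    """Build ordered scene segments from a video manifest.

    The manifest is a dict with ``video_id`` and a ``scenes`` list of dicts
    (``scene_id, category, onset_ms, offset_ms, age_restricted``).  Scenes
    must be ordered and non-overlapping.
    """
    video_id = manifest.get("video_id", "video")
    out = []
    prev_end = -np.inf
    for sc in manifest["scenes"]:
        seg = SceneSegment(
            video_id=video_id,
            scene_id=str(sc["scene_id"]),
            category=sc["category"],
            onset_ms=float(sc["onset_ms"]),
            offset_ms=float(sc["offset_ms"]),
            age_restricted=bool(sc.get("age_restricted", False)),
        )
        if seg.onset_ms < prev_end:
            raise ValueError(f"scene {seg.scene_id} overlaps the previous scene")
        prev_end = seg.offset_ms
        out.append(seg)
    return out


def scenes_from_cuts(
    video_id: str,
    cut_points_ms: list[float],
    total_duration_ms: float,
    category: str,
) -> list[SceneSegment]:
    """k ordered cut points partition a video into k+1 scenes."""
    cuts = sorted(float(c) for c in cut_points_ms)
    edges = [0.0, *cuts, float(total_duration_ms)]
    return [
        SceneSegment(
            video_id=video_id,
            scene_id=f"{video_id}_s{i}",
            category=category,
            onset_ms=a,
            offset_ms=b,
        )
        for i, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
    ]


def assign_scenes(fixations: pd.DataFrame, segments: list[SceneSegment]) -> pd.DataFrame:
    """Assign fixations to scenes by onset and apply the 5000 ms chop.

    A fixation belongs to the scene containing its onset; a fixation
    straddling a cut is truncated at the cut.  Fixations whose time-in-scene
    exceeds the scene's analyzable window are dropped.
    """
    out = fixations.copy()
    scene = np.array([None] * len(out), dtype=object)
    category = np.array([None] * len(out), dtype=object)
    restricted = np.zeros(len(out), dtype=bool)
    t_scene = np.full(len(out), np.nan)
    dur = out["duration_ms"].to_numpy(dtype=float).copy()
    onset = out["onset_ms"].to_numpy(dtype=float)
    offset = out["offset_ms"].to_numpy(dtype=float)
    for seg in segments:
        sel = (onset >= seg.onset_ms) & (onset < seg.offset_ms)
        scene[sel] = seg.scene_id
        category[sel] = seg.category
        restricted[sel] = seg.age_restricted
        t_scene[sel] = onset[sel] - seg.onset_ms
        clipped = np.minimum(offset[sel], seg.offset_ms)
        dur[sel] = clipped - onset[sel]
    out["scene"] = scene
    out["category"] = category
    out["age_restricted"] = restricted
    out["t_scene_ms"] = t_scene
    out["duration_ms"] = dur
    windows = {seg.scene_id: seg.window_ms for seg in segments}
    keep = out["scene"].notna() & out.apply(
        lambda r: r["t_scene_ms"] <= windows[r["scene"]], axis=1
    ) if len(out) else pd.Series([], dtype=bool)
    return out[keep].reset_index(drop=True)


def _nearest_frame(t_scene_ms: float, frame_times_ms: np.ndarray) -> int:
    return int(np.argmin(np.abs(np.asarray(frame_times_ms, dtype=float) - t_scene_ms)))


def sample_map_at_gaze(
    cx_px: float,
    cy_px: float,
    t_scene_ms: float,
    grids: np.ndarray,
    frame_times_ms: np.ndarray,
) -> float:
    """Grid value at the fixation centroid pixel of the nearest frame.

    ``grids`` is the (T, H, W) stack of a feature map over the scene.
    Off-screen centroids yield NaN (flagged missing, not an error).
    """
    grids = np.asarray(grids)
    if grids.ndim != 3 or grids.shape[0] == 0:
        raise ValueError("need a non-empty (T, H, W) stack of frames for the scene")
    k = _nearest_frame(t_scene_ms, frame_times_ms)
    h, w = grids.shape[1:]
    ix = int(round(cx_px))
    iy = int(round(cy_px))
    if not (0 <= ix < w and 0 <= iy < h):
        return float("nan")
    return float(grids[k, iy, ix])


def aoi_hit(
    cx_px: float,
    cy_px: float,
    t_scene_ms: float,
    masks: dict | None,
    frame_times_ms: np.ndarray,
) -> dict:
    """AOI hit flags at the fixation centroid (human scenes only).

    ``masks`` maps label -> (T, H, W) boolean stack; ``None`` (no AOI for
    this scene, e.g. a non-human scene) yields NaN for every label.
    """
    if not masks:
        return {lab: float("nan") for lab in AOI_LABELS}
    out = {}
    for lab in AOI_LABELS:
        if lab not in masks:
            out[lab] = float("nan")
            continue
        stack = np.asarray(masks[lab])
        k = _nearest_frame(t_scene_ms, frame_times_ms)
        h, w = stack.shape[1:]
        ix = int(round(cx_px))
        iy = int(round(cy_px))
        out[lab] = float(bool(stack[k, iy, ix])) if (0 <= ix < w and 0 <= iy < h) else 0.0
    return out


def assemble_records(
    fixations_by_participant: dict,
    segments: list[SceneSegment],
    feature_stacks: dict,
    frame_times: dict,
    cohort: pd.DataFrame,
    masks: dict | None = None,
    pupil_responses: dict | None = None,
) -> pd.DataFrame:
    """Join fixations, feature maps, AOI masks, pupil outputs, and covariates
    into the long-format analysis table (one row per retained fixation).

    Parameters
    ----------
    fixations_by_participant
        pid -> fixation table (from :func:`gazesal.events.fixations_to_frame`),
        in video time.
    segments
        Ordered scene segments of the presented video(s).
    feature_stacks
        scene_id -> dict with keys ``phys``, ``motion``, ``lum`` mapping to
        (T, H, W) stacks (scene-local frames).
    frame_times
        scene_id -> frame times in scene-local ms.
    cohort
        Participant table indexed by participant id (or with a
        ``participant`` column); carried covariates are joined in.
    masks
        scene_id -> {label -> (T, H, W) bool} for human scenes.
    pupil_responses
        pid -> {fixation_id -> standardized response} (optional).
    """
    cohort = cohort.set_index("participant") if "participant" in cohort.columns else cohort
    unknown = [p for p in fixations_by_participant if p not in cohort.index]
    if unknown:
        raise KeyError(f"participants missing from cohort table: {unknown}")
    seg_ids = {s.scene_id for s in segments}
    missing_feats = seg_ids - set(feature_stacks)
    if missing_feats:
        raise KeyError(f"scenes missing feature stacks: {sorted(missing_feats)}")

    rows = []
    for pid, fixes in fixations_by_participant.items():
        assigned = assign_scenes(fixes, segments)
        pr = (pupil_responses or {}).get(pid, {})
        for _, f in assigned.iterrows():
            sid = f["scene"]
            stacks = feature_stacks[sid]
            ft = frame_times[sid]
            t_local = float(f["t_scene_ms"])
            phys = sample_map_at_gaze(f["cx_px"], f["cy_px"], t_local, stacks["phys"], ft)
            mot = sample_map_at_gaze(f["cx_px"], f["cy_px"], t_local, stacks["motion"], ft)
            lum = sample_map_at_gaze(f["cx_px"], f["cy_px"], t_local, stacks["lum"], ft)
            scene_masks = (masks or {}).get(sid)
            hits = aoi_hit(f["cx_px"], f["cy_px"], t_local, scene_masks, ft)
            row = {
                "participant": pid,
                "group": cohort.loc[pid].get("group"),
                "scene": sid,
                "category": f["category"],
                "age_restricted": bool(f["age_restricted"]),
                "onset_ms": float(f["onset_ms"]),
                "t_scene_ms": t_local,
                "duration_ms": float(f["duration_ms"]),
                "cx_px": float(f["cx_px"]),
                "cy_px": float(f["cy_px"]),
                "phys_salience": phys,
                "motion_salience": mot,
                "luminance": lum,
                "pupil_response": pr.get(f.get("fixation_id"), float("nan")),
                "pr1": float("nan"),
                "pr2": float("nan"),
                **{f"aoi_{lab}": hits[lab] for lab in AOI_LABELS},
            }
            rows.append(row)
    table = pd.DataFrame(rows, columns=RECORD_COLUMNS)

    # per-participant data-quality covariates
    total_window_ms = sum(s.window_ms for s in segments)
    if len(table):
        avail = (
            table.groupby("participant")["duration_ms"].sum() / total_window_ms * 100.0
        )
        table["available_data_pct"] = table["participant"].map(avail)
    else:
        table["available_data_pct"] = pd.Series(dtype=float)
    carry = [
        c
        for c in cohort.columns
        if c
        not in ("group",)
        and c not in table.columns
    ]
    for c in carry:
        table[c] = table["participant"].map(cohort[c]) if len(table) else pd.Series(dtype=cohort[c].dtype)
    return table
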