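"""Synthetic stimulus videos with known salient patches and AOI masks.

Scenes are rendered as RGB frame stacks on a textured background with, on
request, one static high-contrast patch and one moving patch whose positions
are recorded as ground truth.  Human scenes additionally render a schematic
person (body, face, eyes, mouth) with nested binary AOI masks.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import ScreenGeometry

__all__ = ["SceneSpec", "SceneTruth", "VideoScene", "generate_video"]


@dataclass
class SceneSpec:
    """Description of one synthetic scene."""

    scene_id: str
    category: str  # "human" | "non-human"
    duration_ms: float = 4000.0
    static_patch: bool = True
    moving_patch: bool = True
    moving_speed_px: float = 2.0  # per frame
    background: str = "noise"  # "noise" | "uniform"
    age_restricted: bool = False

    def __post_init__(self):
        if self.category not in ("human", "non-human"):
            raise ValueError("category must be 'human' or 'non-human'")
        if self.duration_ms <= 0:
            raise ValueError("scene duration must be positive")


@dataclass
class SceneTruth:
    """Planted ground truth for one scene."""

    scene_id: str
    static_box: tuple | None  # (x0, y0, x1, y1) or None
    moving_track: np.ndarray | None  # (T, 4) boxes or None
    face_center: tuple | None
    aoi_labels: tuple = ()
    seed: int = 0


@dataclass
class VideoScene:
    """Rendered scene: frames, frame times, AOI masks, and truth."""

    spec: SceneSpec
    frames: np.ndarray  # (T, H, W, 3) uint8
    frame_times_ms: np.ndarray
    masks: dict = field(default_factory=dict)  # label -> (T, H, W) bool
    truth: SceneTruth | None = None
    fps: float = 25.0


def _disk(h, w, cy, cx, r):
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _ellipse(h, w, cy, cx, ry, rx):
    yy, xx = np.ogrid[:h, :w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_video(
    scene: SceneSpec,
    geometry: ScreenGeometry,
    seed: int,
    fps: float = 25.0,
    patch_size_px: int = 12,
) -> VideoScene:
    """Render one synthetic scene as an RGB frame stack with truth tracks."""
    if fps <= 0:
        raise ValueError("frame rate must be positive")
    n_frames = int(round(scene.duration_ms / 1000.0 * fps))
    if n_frames < 1:
        raise ValueError("scene would contain zero frames")
    rng = np.random.default_rng(seed)
    h, w = geometry.height_px, geometry.width_px

    if scene.background == "uniform":
        base = np.full((h, w), 96.0)
    else:
        base = 96.0 + rng.normal(0.0, 6.0, (h, w))
    frame0 = np.clip(base, 0, 255)

    # static high-contrast patch
    static_box = None
    if scene.static_patch:
        s = patch_size_px
        x0 = int(rng.integers(w // 8, w // 2 - s))
        y0 = int(rng.integers(h // 8, h - h // 8 - s))
        static_box = (x0, y0, x0 + s, y0 + s)

    # moving patch: linear trajectory with bounces
    moving_track = None
    if scene.moving_patch:
        s = patch_size_px + 2
        pos = np.array(
            [rng.uniform(w / 2 + s, w - 2 * s), rng.uniform(2 * s, h - 2 * s)]
        )
        ang = rng.uniform(0, 2 * np.pi)
        vel = scene.moving_speed_px * np.array([np.cos(ang), np.sin(ang)])
        boxes = np.zeros((n_frames, 4))
        for t in range(n_frames):
            boxes[t] = (pos[0], pos[1], pos[0] + s, pos[1] + s)
            pos = pos + vel
            if pos[0] < 0 or pos[0] + s >= w:
                vel[0] = -vel[0]
                pos[0] = np.clip(pos[0], 0, w - s - 1)
            if pos[1] < 0 or pos[1] + s >= h:
                vel[1] = -vel[1]
                pos[1] = np.clip(pos[1], 0, h - s - 1)
        moving_track = boxes

    # schematic person for human scenes, with nested AOI masks
    masks: dict[str, np.ndarray] = {}
    face_center = None
    person = None
    if scene.category == "human":
        bx = int(rng.uniform(0.55 * w, 0.8 * w))
        face_r = max(6, h // 10)
        face_cy = int(0.3 * h)
        face_center = (bx, face_cy)
        face = _disk(h, w, face_cy, bx, face_r)
        eyes = _disk(h, w, face_cy - face_r // 3, bx - face_r // 2, max(1, face_r // 5)) | _disk(
            h, w, face_cy - face_r // 3, bx + face_r // 2, max(1, face_r // 5)
        )
        mouth = _disk(h, w, face_cy + face_r // 2, bx, max(1, face_r // 4))
        body = _ellipse(h, w, face_cy + face_r + h // 5, bx, h // 4, face_r + 4) | face
        masks = {
            "eyes": np.broadcast_to(eyes & face, (n_frames, h, w)).copy(),
            "mouth": np.broadcast_to(mouth & face, (n_frames, h, w)).copy(),
            "face": np.broadcast_to(face, (n_frames, h, w)).copy(),
            "body": np.broadcast_to(body, (n_frames, h, w)).copy(),
        }
        person = {"face": face, "eyes": eyes & face, "mouth": mouth & face, "body": body}

    frames = np.zeros((n_frames, h, w, 3), dtype=np.uint8)
    for t in range(n_frames):
        img = np.stack([frame0] * 3, axis=2).copy()
        if person is not None:
            img[person["body"]] = (70, 90, 150)
            img[person["face"]] = (210, 170, 140)
            img[person["eyes"]] = (30, 30, 30)
            img[person["mouth"]] = (150, 60, 60)
        if static_box is not None:
            x0, y0, x1, y1 = static_box
            img[y0:y1, x0:x1] = (235, 235, 235)
        if moving_track is not None:
            x0, y0, x1, y1 = (int(round(v)) for v in moving_track[t])
            img[y0:y1, x0:x1] = (240, 210, 60)
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)

    truth = SceneTruth(
        scene_id=scene.scene_id,
        static_box=static_box,
        moving_track=moving_track,
        face_center=face_center,
        aoi_labels=tuple(masks),
        seed=seed,
    )
    frame_times = (np.arange(n_frames) + 0.5) * (1000.0 / fps)
    return VideoScene(
        spec=scene,
        frames=frames,
        frame_times_ms=frame_times,
        masks=masks,
        truth=truth,
        fps=fps,
    )
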