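"""Readers and writers for the pipeline's on-disk formats.

Gaze streams are tab-separated (Tobii-like layout), scene manifests are
JSON, frames and AOI masks are numbered PNG sequences (codec-free and
deterministic), AOI regions may alternatively be polygon JSON, and feature
grids are compressed NumPy archives.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import polygon as sk_polygon

from .pupil import ComponentModel

__all__ = [
    "read_gaze_tsv",
    "write_gaze_tsv",
    "read_manifest",
    "write_manifest",
    "write_frames",
    "read_frames",
    "write_aoi_masks",
    "read_aoi_masks",
    "read_aoi_polygons",
    "write_component_model",
    "read_component_model",
]


def read_gaze_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gaze_tsv(stream: pd.DataFrame, path) -> None:
    stream.to_csv(path, sep="\t", index=False, na_rep="nan")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def write_frames(frames: np.ndarray, outdir, prefix: str = "frame") -> list:
    """Write an (T, H, W, 3) uint8 stack as numbered PNGs; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = outdir / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def read_frames(indir, prefix: str = "frame") -> np.ndarray:
    paths = sorted(Path(indir).glob(f"{prefix}_*.png"))
    if not paths:
        raise FileNotFoundError(f"no {prefix}_*.png frames in {indir}")
    return np.stack([iio.imread(p) for p in paths])


def write_aoi_masks(masks: dict, outdir) -> None:
    """Write {label -> (T, H, W) bool} as per-frame binary PNGs per label."""
    outdir = Path(outdir)
    for label, stack in masks.items():
        d = outdir / label
        d.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(np.asarray(stack)):
            iio.imwrite(d / f"mask_{i:05d}.png", (m.astype(np.uint8) * 255))


def read_aoi_masks(indir) -> dict:
    indir = Path(indir)
    out = {}
    for d in sorted(p for p in indir.iterdir() if p.is_dir()):
        paths = sorted(d.glob("mask_*.png"))
        if paths:
            out[d.name] = np.stack([iio.imread(p) > 127 for p in paths])
    if not out:
        raise FileNotFoundError(f"no AOI mask directories under {indir}")
    return out


def read_aoi_polygons(path, shape: tuple, n_frames: int) -> dict:
    """Rasterize polygon-JSON AOIs ({label: [[x, y], ...]}) to mask stacks.

    Static polygons are applied to every frame of the scene.
    """
    with open(path) as fh:
        polys = json.load(fh)
    h, w = shape
    out = {}
    for label, pts in polys.items():
        pts = np.asarray(pts, dtype=float)
        rr, cc = sk_polygon(pts[:, 1], pts[:, 0], shape=(h, w))
        m = np.zeros((h, w), dtype=bool)
        m[rr, cc] = True
        out[label] = np.broadcast_to(m, (n_frames, h, w)).copy()
    return out


def write_component_model(model: ComponentModel, path) -> None:
    payload = {
        "bin_edges_ms": model.bin_edges_ms.tolist(),
        "loadings": model.loadings.tolist(),
        "explained_variance_ratio": model.explained_variance_ratio.tolist(),
        "rotation": model.rotation,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_component_model(path) -> ComponentModel:
    with open(path) as fh:
        payload = json.load(fh)
    return ComponentModel(
        bin_edges_ms=np.asarray(payload["bin_edges_ms"], dtype=float),
        loadings=np.asarray(payload["loadings"], dtype=float),
        explained_variance_ratio=np.asarray(
            payload["explained_variance_ratio"], dtype=float
        ),
        rotation=payload.get("rotation", "varimax"),
    )
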