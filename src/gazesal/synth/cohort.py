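"""Synthetic cohorts: participant tables, per-participant streams, and truth.

The cohort generator plants the group-level structure the analysis is built
to detect: a group difference in face-gaze probability (ASD lower) and a
group x scene-category interaction in the pupillary response (ASD responses
larger for non-human, smaller for human scenes), on top of covariate
distributions shaped like the study sample (age 6-30 y, perceptual IQ around
100, symptom scores with large group differences, missing-completely-at-
random symptom cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..geometry import ScreenGeometry
from .gaze import ParticipantParams, generate_gaze_stream
from .video import SceneSpec, generate_video

__all__ = ["CohortEffects", "CohortDesign", "CohortData", "generate_cohort", "default_scene_specs"]


@dataclass
class CohortEffects:
    """Planted effect sizes (recorded with every generated artifact)."""

    face_bias_td: float = 0.55
    face_bias_asd: float = 0.40
    pupil_amp_mm: float = 0.08
    # group x category modulation of the pupil event amplitude (mm):
    # ASD amplitude = amp + delta for non-human, amp - delta for human
    pupil_interaction_mm: float = 0.03
    salience_bias: float = 0.3
    pupil_latency_ms: float = 300.0
    jitter_sd_px: float = 2.0
    blink_rate: float = 0.05
    pupil_noise_sd_mm: float = 0.01
    missing_covariate_rate: float = 0.10


@dataclass
class CohortDesign:
    """Cohort layout: group sizes, covariates, scenes, planted effects."""

    n_asd: int = 2
    n_td: int = 2
    scenes: list = field(default_factory=lambda: default_scene_specs())
    effects: CohortEffects = field(default_factory=CohortEffects)

    def __post_init__(self):
        if self.n_asd < 1 or self.n_td < 1:
            raise ValueError("group sizes must be positive")
        if self.n_asd + self.n_td < 4:
            raise ValueError("need at least 2 participants per group")


@dataclass
class CohortData:
    participants: pd.DataFrame
    videos: list
    streams: dict  # pid -> (raw stream DataFrame, StreamTruth)
    design: CohortDesign
    seed: int


def default_scene_specs(n_scenes: int = 4, duration_ms: float = 4000.0) -> list:
    """Alternating human / non-human scene specs."""
    out = []
    for k in range(n_scenes):
        cat = "human" if k % 2 == 0 else "non-human"
        out.append(
            SceneSpec(
                scene_id=f"s{k:02d}",
                category=cat,
                duration_ms=duration_ms,
                static_patch=True,
                moving_patch=(cat == "non-human"),
            )
        )
    return out


def _covariates(rng, group: str, n: int) -> pd.DataFrame:
    """Participant covariates with study-like distribution shapes."""
    asd = group == "ASD"
    return pd.DataFrame(
        {
            "group": group,
            "sex": rng.choice(["female", "male"], size=n, p=[0.27, 0.73]),
            "age": rng.uniform(6.0, 30.0, n),
            "perceptual_iq": rng.normal(102.1 if asd else 104.8, 17.0, n),
            "srs_score": rng.normal(96.9 if asd else 28.0, 25.0, n),
            "adhd_score": np.clip(rng.normal(4.35 if asd else 1.22, 2.5, n), 0, None),
            "anxiety_score": np.clip(rng.normal(15.0 if asd else 6.9, 8.0, n), 0, None),
            "depression_score": np.clip(rng.normal(14.6 if asd else 5.9, 8.0, n), 0, None),
            "accuracy_z": rng.normal(0.0, 1.0, n),
            "precision_z": rng.normal(0.0, 1.0, n),
            "pupil_baseline_mm": np.clip(rng.normal(3.66, 0.5, n), 2.2, 6.0),
        }
    )


def generate_cohort(
    design: CohortDesign, seed: int, geometry: ScreenGeometry | None = None
) -> CohortData:
    """Generate the full synthetic study: videos, streams, participant table.

    Videos are shared across participants (as in the study); streams and
    covariates are per participant.  Everything derives deterministically
    from ``seed``.
    """
    if geometry is None:
        geometry = ScreenGeometry(width_px=128, height_px=96, sampling_rate_hz=120.0)
    rng = np.random.default_rng(seed)
    eff = design.effects

    videos = [
        generate_video(spec, geometry, seed=int(rng.integers(2**31)))
        for spec in design.scenes
    ]

    tables = []
    for group, n in (("ASD", design.n_asd), ("TD", design.n_td)):
        tab = _covariates(rng, group, n)
        tab["participant"] = [f"{group.lower()}{i:03d}" for i in range(n)]
        tables.append(tab)
    participants = pd.concat(tables, ignore_index=True)

    # missing-completely-at-random symptom covariates
    for col in ("srs_score", "adhd_score", "anxiety_score", "depression_score"):
        mask = rng.uniform(size=len(participants)) < eff.missing_covariate_rate
        participants.loc[mask, col] = np.nan

    streams = {}
    for _, row in participants.iterrows():
        asd = row["group"] == "ASD"
        sgn = 1.0 if asd else -1.0
        amps = {
            "human": eff.pupil_amp_mm - sgn * eff.pupil_interaction_mm,
            "non-human": eff.pupil_amp_mm + sgn * eff.pupil_interaction_mm,
        }
        params = ParticipantParams(
            pid=row["participant"],
            group=row["group"],
            pupil_baseline_mm=float(row["pupil_baseline_mm"]),
            jitter_sd_px=eff.jitter_sd_px,
            blink_rate=eff.blink_rate,
            face_bias=eff.face_bias_asd if asd else eff.face_bias_td,
            salience_bias=eff.salience_bias,
            pupil_event_amp_mm=amps,
            pupil_latency_ms=eff.pupil_latency_ms,
            pupil_noise_sd_mm=eff.pupil_noise_sd_mm,
        )
        streams[row["participant"]] = generate_gaze_stream(
            params, videos, geometry, seed=int(rng.integers(2**31))
        )

    participants = participants[
        [
            "participant",
            "group",
            "sex",
            "age",
            "perceptual_iq",
            "srs_score",
            "adhd_score",
            "anxiety_score",
            "depression_score",
            "accuracy_z",
            "precision_z",
            "pupil_baseline_mm",
        ]
    ]
    return CohortData(
        participants=participants,
        videos=videos,
        streams=streams,
        design=design,
        seed=seed,
    )
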