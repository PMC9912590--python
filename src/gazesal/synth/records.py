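"""Record-level simulator for the inference stage.

Simulates long-format fixation-record tables directly from the statistical
model the mixed-effects stage assumes -- deviation-coded group and category
effects, crossed random intercepts for participant and scene, and i.i.d.
residual noise -- without rendering videos or streams.  Effects are planted
on the standardized scale: variance components default to
``sigma_p^2 + sigma_s^2 + sigma_e^2 = 1`` so a planted coefficient is (up to
the small fixed-effect variance share) the standardized beta the fitted
model estimates.  This is the workhorse for repeated-fit studies (bias,
type-I error, power) where the full media pipeline would be needlessly
expensive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_records"]


def simulate_records(
    n_per_group: int = 40,
    n_scenes: int = 20,
    n_fix_per_scene: int = 5,
    beta_group: float = 0.0,
    beta_category: float = 0.0,
    beta_interaction: float = 0.0,
    sd_participant: float = np.sqrt(0.15),
    sd_scene: float = np.sqrt(0.10),
    sd_resid: float = np.sqrt(0.75),
    outcome: str = "pupil_response",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a fixation-record table with planted fixed effects.

    Group is coded ASD = +0.5 / TD = -0.5 and category human = +0.5 /
    non-human = -0.5 (the package's deviation coding), so
    ``beta_interaction`` is the coefficient of the product of those codes.
    Scenes alternate category; times-in-scene are uniform over [0, 5000] ms.
    """
    rng = np.random.default_rng(seed)
    pids = [f"asd{i:03d}" for i in range(n_per_group)] + [
        f"td{i:03d}" for i in range(n_per_group)
    ]
    gcode = {p: (0.5 if p.startswith("asd") else -0.5) for p in pids}
    scenes = [f"s{k:02d}" for k in range(n_scenes)]
    ccode = {s: (0.5 if k % 2 == 0 else -0.5) for k, s in enumerate(scenes)}

    b_p = {p: rng.normal(0.0, sd_participant) for p in pids}
    b_s = {s: rng.normal(0.0, sd_scene) for s in scenes}

    rows = []
    for p in pids:
        for s in scenes:
            g, c = gcode[p], ccode[s]
            mu = beta_group * g + beta_category * c + beta_interaction * g * c
            for _ in range(n_fix_per_scene):
                rows.append(
                    {
                        "participant": p,
                        "group": "ASD" if g > 0 else "TD",
                        "scene": s,
                        "category": "human" if c > 0 else "non-human",
                        "t_scene_ms": rng.uniform(0.0, 5000.0),
                        outcome: mu + b_p[p] + b_s[s] + rng.normal(0.0, sd_resid),
                    }
                )
    return pd.DataFrame(rows)
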