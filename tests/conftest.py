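import numpy as np
import pandas as pd
import pytest

from gazesal.geometry import ScreenGeometry
from gazesal.synth import CohortDesign, CohortEffects, SceneSpec, generate_cohort


@pytest.fixture(scope="session")
def geometry120() -> ScreenGeometry:
    return ScreenGeometry(width_px=128, height_px=96, sampling_rate_hz=120.0)


@pytest.fixture(scope="session")
def geometry300() -> ScreenGeometry:
    return ScreenGeometry(width_px=128, height_px=96, sampling_rate_hz=300.0)


@pytest.fixture(scope="session")
def small_cohort(geometry120):
    """A tiny noisy cohort exercised by several pipeline-level tests."""
    design = CohortDesign(
        n_asd=2,
        n_td=2,
        scenes=[
            SceneSpec("s00", "human", 3000.0, moving_patch=False),
            SceneSpec("s01", "non-human", 3000.0),
        ],
    )
    return generate_cohort(design, seed=11, geometry=geometry120)


def constant_velocity_stream(
    geometry: ScreenGeometry,
    deg_per_s: float,
    duration_ms: float = 400.0,
    pupil_mm: float = 3.5,
) -> pd.DataFrame:
    """Binocular stream drifting at a constant angular velocity.

    The trace is centred on the screen midline so the chord-angle metric
    stays in its linear range.
    """
    period = geometry.sample_period_ms
    n = int(round(duration_ms / period))
    t = np.arange(n) * period
    step_px = geometry.deg_to_px(deg_per_s * period / 1000.0)
    x = geometry.width_px / 2.0 + (np.arange(n) - n / 2.0) * step_px
    y = np.full(n, geometry.height_px / 2.0)
    return binocular_frame(t, x, y, pupil_mm)


def binocular_frame(t, x, y, pupil=3.5, valid=None) -> pd.DataFrame:
    x = np.asarray(x, dtype=float)
    if valid is None:
        valid = np.isfinite(x)
    p = np.broadcast_to(np.asarray(pupil, dtype=float), x.shape).copy()
    return pd.DataFrame(
        {
            "timestamp_ms": np.asarray(t, dtype=float),
            "gx_left_px": x,
            "gy_left_px": y,
            "gx_right_px": x,
            "gy_right_px": y,
            "pupil_left_mm": p,
            "pupil_right_mm": p,
            "valid_left": np.asarray(valid).astype(int),
            "valid_right": np.asarray(valid).astype(int),
        }
    )
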