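"""Screen geometry and visual-angle conversions.

All gaze coordinates in this package are screen pixels with the origin at the
top-left corner, x increasing rightward and y increasing downward (0-based).
Conversions between pixels and degrees of visual angle always go through a
:class:`ScreenGeometry`, which describes the physical display and the viewing
distance of the study setup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ScreenGeometry"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry and eye-tracker sampling rate.

    Defaults describe a 345 x 259 mm display viewed at 650 mm, the fixed
    presentation geometry used across recording sites.

    Parameters
    ----------
    width_px, height_px
        Display resolution in pixels.
    display_width_mm, display_height_mm
        Physical size of the display area in millimetres.
    viewing_distance_mm
        Eye-to-screen distance in millimetres.
    sampling_rate_hz
        Nominal eye-tracker sampling rate (study hardware ran at 120 or 300 Hz).
    """

    width_px: int
    height_px: int
    display_width_mm: float = 345.0
    display_height_mm: float = 259.0
    viewing_distance_mm: float = 650.0
    sampling_rate_hz: float = 120.0

    def __post_init__(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "display_width_mm",
            "display_height_mm",
            "viewing_distance_mm",
            "sampling_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # pixel aspect must be consistent with the physical aspect within 1%
        ratio = self.mm_per_px_x / self.mm_per_px_y
        if abs(ratio - 1.0) > 0.01:
            raise ValueError(
                "pixel aspect inconsistent with physical display aspect: "
                f"mm/px x={self.mm_per_px_x:.4f} vs y={self.mm_per_px_y:.4f}"
            )

    # -- unit conversions ---------------------------------------------------

    @property
    def mm_per_px_x(self) -> float:
        return self.display_width_mm / self.width_px

    @property
    def mm_per_px_y(self) -> float:
        return self.display_height_mm / self.height_px

    @property
    def mm_per_px(self) -> float:
        """Isotropic mm-per-pixel scale (mean of both axes)."""
        return 0.5 * (self.mm_per_px_x + self.mm_per_px_y)

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def px_to_mm(self, dx_px, dy_px):
        """Convert a pixel displacement to a metric on-screen displacement (mm)."""
        return np.asarray(dx_px) * self.mm_per_px_x, np.asarray(dy_px) * self.mm_per_px_y

    def separation_deg(self, x0_px, y0_px, x1_px, y1_px):
        """Angular separation (degrees) between two on-screen points.

        The angle is computed from the metric chord length on the screen over
        the viewing distance: ``theta = atan(d_mm / D)``.  This is the
        small-excursion approximation appropriate for gaze near the screen
        centre; displacements, not absolute eccentricities, drive all event
        detection thresholds.
        """
        dx_mm = (np.asarray(x1_px, dtype=float) - np.asarray(x0_px, dtype=float)) * self.mm_per_px_x
        dy_mm = (np.asarray(y1_px, dtype=float) - np.asarray(y0_px, dtype=float)) * self.mm_per_px_y
        d_mm = np.hypot(dx_mm, dy_mm)
        return np.degrees(np.arctan2(d_mm, self.viewing_distance_mm))

    def deg_to_px(self, deg: float) -> float:
        """On-screen pixel length subtending ``deg`` degrees (isotropic scale)."""
        d_mm = self.viewing_distance_mm * math.tan(math.radians(deg))
        return d_mm / self.mm_per_px

    def px_to_deg(self, px: float) -> float:
        """Degrees subtended by an on-screen displacement of ``px`` pixels."""
        d_mm = float(px) * self.mm_per_px
        return math.degrees(math.atan2(d_mm, self.viewing_distance_mm))

    def full_width_deg(self) -> float:
        """Visual angle subtended by the full display width from its centre."""
        half = self.display_width_mm / 2.0
        return 2.0 * math.degrees(math.atan2(half, self.viewing_distance_mm))
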