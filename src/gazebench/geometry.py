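"""Screen geometry and pixel <-> degrees-of-visual-angle conversions.

All spatial quantities in the pipeline are stored in screen pixels and
converted to degrees of visual angle (dva) through a :class:`ScreenGeometry`.
The conversion is per-axis because the study screen is anisotropic in
pixels per degree (1920 px / 50 dva horizontally vs 1080 px / 24 dva
vertically).

Pixel convention: 0-based, origin top-left, x rightward, y downward.
Pixel ``i`` covers the half-open interval ``[i, i + 1)``; continuous maps
are sampled at pixel centres ``i + 0.5``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScreenGeometry", "STUDY_GEOMETRY"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen layout of the free-viewing setup.

    Defaults reproduce the museum installation: a 1920 x 1080 px monitor
    spanning 50 x 24 dva at 80 cm viewing distance (the distance is kept
    as metadata only; conversions use the stated dva extents directly).
    """

    width_px: int = 1920
    height_px: int = 1080
    width_dva: float = 50.0
    height_dva: float = 24.0
    viewing_distance_cm: float = 80.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_dva", "height_dva"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")

    @property
    def px_per_deg_x(self) -> float:
        return self.width_px / self.width_dva

    @property
    def px_per_deg_y(self) -> float:
        return self.height_px / self.height_dva

    @property
    def center_px(self) -> tuple[float, float]:
        """Screen centre in continuous pixel coordinates (x, y)."""
        return self.width_px / 2.0, self.height_px / 2.0

    @property
    def shape(self) -> tuple[int, int]:
        """Grid shape as (rows, cols) = (height_px, width_px)."""
        return self.height_px, self.width_px

    def dva_to_px(self, extent_dva: float) -> tuple[float, float]:
        """Convert an angular extent to (x_px, y_px) per-axis extents."""
        return extent_dva * self.px_per_deg_x, extent_dva * self.px_per_deg_y

    def distance_dva(self, x0, y0, x1, y1):
        """Euclidean distance in dva between pixel-coordinate points.

        Accepts scalars or arrays; converts each axis with its own
        px-per-degree factor before taking the norm.
        """
        dx = (np.asarray(x1) - np.asarray(x0)) / self.px_per_deg_x
        dy = (np.asarray(y1) - np.asarray(y0)) / self.px_per_deg_y
        return np.hypot(dx, dy)

    def contains(self, x_px, y_px):
        """Whether points lie on-screen (half-open pixel bounds)."""
        x = np.asarray(x_px)
        y = np.asarray(y_px)
        return (x >= 0) & (x < self.width_px) & (y >= 0) & (y < self.height_px)


#: Geometry of the study setup (38.4 px/deg horizontal, 45.0 px/deg vertical).
STUDY_GEOMETRY = ScreenGeometry()
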