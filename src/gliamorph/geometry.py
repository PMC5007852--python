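"""Arena geometries shared by the synthetic generators and the assays.

Two behavioral apparatus layouts are modelled:

* a square scent-marking arena with one 20-cm scoring circle per
  quadrant, each tangent to the two outer edges of its quadrant, so one
  circle is centred on the female-urine spot;
* a square open field holding two cylinders in opposing corners, each
  surrounded by an annular investigation zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MarkSheetGeometry:
    """Scent-marking arena: 46×46 cm sheet, four 20-cm quadrant circles.

    Quadrant order is top-left, top-right, bottom-left, bottom-right;
    ``target_quadrant`` indexes the circle centred on the urine spot.
    ``px_per_cm`` sets the raster resolution of binarized sheets.
    """

    arena_size_cm: float = 46.0
    circle_diameter_cm: float = 20.0
    target_quadrant: int = 0
    px_per_cm: float = 4.0

    def __post_init__(self):
        if self.arena_size_cm <= 0 or self.circle_diameter_cm <= 0:
            raise ValueError("arena and circle sizes must be positive")
        if self.circle_diameter_cm > self.arena_size_cm:
            raise ValueError("circle cannot exceed the arena")
        if not 0 <= self.target_quadrant <= 3:
            raise ValueError("target_quadrant must be in 0..3")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")

    @property
    def radius_cm(self) -> float:
        return self.circle_diameter_cm / 2.0

    @property
    def sheet_shape(self) -> tuple[int, int]:
        n = int(round(self.arena_size_cm * self.px_per_cm))
        return (n, n)

    def circle_centers_cm(self) -> np.ndarray:
        """Centres of the four quadrant circles (x, y) in cm.

        Each circle is tangent to the two outer edges of its quadrant:
        its centre sits one radius in from each outer wall.
        """
        r = self.radius_cm
        s = self.arena_size_cm
        return np.array(
            [
                (r, r),          # top-left
                (s - r, r),      # top-right
                (r, s - r),      # bottom-left
                (s - r, s - r),  # bottom-right
            ]
        )

    def circle_mask(self, quadrant: int) -> np.ndarray:
        """Boolean raster of one scoring circle on the sheet grid.

        Pixel centres are at ((j+0.5)/px_per_cm, (i+0.5)/px_per_cm) cm.
        """
        cx, cy = self.circle_centers_cm()[quadrant]
        h, w = self.sheet_shape
        ys = (np.arange(h) + 0.5) / self.px_per_cm
        xs = (np.arange(w) + 0.5) / self.px_per_cm
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius_cm ** 2

    def target_circle_mask(self) -> np.ndarray:
        return self.circle_mask(self.target_quadrant)


@dataclass(frozen=True)
class SocialArenaGeometry:
    """Open-field arena (50×50 cm) with two corner cylinders (10 cm Ø).

    Cylinder walls stand 10 cm from the two adjacent arena edges, so the
    centres sit 15 cm in from opposing corners.  The investigation zone
    is the annulus within ``zone_width_cm`` of a cylinder wall; the
    animal cannot occupy the cylinder interior.
    """

    arena_size_cm: float = 50.0
    cylinder_radius_cm: float = 5.0
    zone_width_cm: float = 2.0
    social_center_cm: tuple[float, float] = (15.0, 15.0)
    object_center_cm: tuple[float, float] = (35.0, 35.0)

    def __post_init__(self):
        if min(self.arena_size_cm, self.cylinder_radius_cm, self.zone_width_cm) <= 0:
            raise ValueError("sizes must be positive")
        d = np.hypot(
            self.social_center_cm[0] - self.object_center_cm[0],
            self.social_center_cm[1] - self.object_center_cm[1],
        )
        if d <= 2 * (self.cylinder_radius_cm + self.zone_width_cm):
            raise ValueError("investigation zones overlap")

    @property
    def zone_outer_cm(self) -> float:
        return self.cylinder_radius_cm + self.zone_width_cm

    def in_zone(self, x, y, which: str) -> np.ndarray:
        """Vectorized membership of positions (cm) in one investigation zone."""
        if which == "social":
            cx, cy = self.social_center_cm
        elif which == "object":
            cx, cy = self.object_center_cm
        else:
            raise ValueError(f"unknown zone {which!r}")
        d2 = (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2
        return (d2 <= self.zone_outer_cm ** 2) & (d2 > self.cylinder_radius_cm ** 2)
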