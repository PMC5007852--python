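"""Per-cell shape descriptors for segmented microglia.

Six parameters describe each binary cell mask and its soma mask:

``cell_area``
    Number of mask pixels times the squared pixel size (µm²).
``soma_area``
    Same, for the soma mask (µm²).
``cell_spread``
    Mean Euclidean distance from the mask centre of mass to its eight
    extremal points (two per cardinal side), times the pixel size (µm).
``eccentricity``
    Ratio of the major to the minor axis of the moment-based best-fit
    ellipse; 1 for a disk, larger for elongated shapes.
``perimeter``
    Weighted boundary-step contour length (anti-aliased digital
    perimeter) times the pixel size (µm).  A naive pixel-edge count
    biases roundness badly for digital shapes, hence the weighted
    estimator.
``roundness``
    4π·area/perimeter²; 1 for an ideal circle, → 0 for filamentous
    shapes.

All pixel coordinates are 0-based ``(row, col) = (y, x)``; masks are
boolean arrays in full-frame coordinates.  Values are reported both in
raw pixel units and in µm using the configured pixel size (default
0.42 µm/px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.measure import perimeter as _weighted_perimeter

#: the six morphometric parameters, in canonical order (µm-scale columns)
PARAMETERS = (
    "cell_area",
    "soma_area",
    "cell_spread",
    "eccentricity",
    "perimeter",
    "roundness",
)

#: full column set of the per-cell measurement table
RECORD_COLUMNS = (
    "cell_id",
    "region",
    "condition",
    "animal",
    "pixel_size_um",
    "cell_area_px",
    "soma_area_px",
    "cell_spread_px",
    "perimeter_px",
    "cell_area",
    "soma_area",
    "cell_spread",
    "perimeter",
    "eccentricity",
    "roundness",
    "roundness_clipped",
    "eccentricity_degenerate",
)


def roundness(area: float, perimeter: float) -> float:
    """Isoperimetric roundness 4π·area/perimeter².

    ``area`` and ``perimeter`` must be in consistent units (the ratio is
    dimensionless).  Raises ``ValueError`` for non-positive perimeter.
    """
    if perimeter <= 0:
        raise ValueError(f"perimeter must be > 0, got {perimeter}")
    return 4.0 * math.pi * float(area) / float(perimeter) ** 2


def mask_extrema(mask: np.ndarray) -> np.ndarray:
    """Eight extremal points of a binary mask, two per cardinal side.

    Order: topmost-left, topmost-right, rightmost-top, rightmost-bottom,
    bottommost-right, bottommost-left, leftmost-bottom, leftmost-top.
    Returns an (8, 2) float array of (y, x) pixel-centre coordinates.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask has no extrema")
    top = ys.min()
    bottom = ys.max()
    left = xs.min()
    right = xs.max()
    top_cols = xs[ys == top]
    bottom_cols = xs[ys == bottom]
    left_rows = ys[xs == left]
    right_rows = ys[xs == right]
    return np.array(
        [
            (top, top_cols.min()),       # topmost-left
            (top, top_cols.max()),       # topmost-right
            (right_rows.min(), right),   # rightmost-top
            (right_rows.max(), right),   # rightmost-bottom
            (bottom, bottom_cols.max()), # bottommost-right
            (bottom, bottom_cols.min()), # bottommost-left
            (left_rows.max(), left),     # leftmost-bottom
            (left_rows.min(), left),     # leftmost-top
        ],
        dtype=float,
    )


def cell_spread(mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Mean distance from the mask centre of mass to its 8 extremal points."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("cell_spread of an empty mask is undefined")
    cy = ys.mean()
    cx = xs.mean()
    ext = mask_extrema(mask)
    d = np.hypot(ext[:, 0] - cy, ext[:, 1] - cx)
    return float(d.mean() * pixel_size_um)


def _axis_lengths(mask: np.ndarray) -> tuple[float, float]:
    # Major/minor axis lengths of the ellipse with the mask's second
    # central moments (same normalization as MATLAB/skimage regionprops:
    # length = 4*sqrt(eigenvalue), with the +1/12 pixel-variance term
    # omitted -- we use raw pixel-centre moments).
    ys, xs = np.nonzero(mask)
    n = ys.size
    cy = ys.mean()
    cx = xs.mean()
    dy = ys - cy
    dx = xs - cx
    mu20 = float(np.dot(dy, dy)) / n
    mu02 = float(np.dot(dx, dx)) / n
    mu11 = float(np.dot(dy, dx)) / n
    common = math.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11 ** 2)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    return 4.0 * math.sqrt(max(lam1, 0.0)), 4.0 * math.sqrt(max(lam2, 0.0))


def eccentricity(mask: np.ndarray) -> float:
    """Major/minor axis ratio of the moment-based best-fit ellipse (≥ 1).

    A degenerate (line-like) mask with zero minor axis returns ``inf``.
    Single-pixel masks have no orientation and return 1.0.
    """
    if not np.any(mask):
        raise ValueError("eccentricity of an empty mask is undefined")
    if int(mask.sum()) == 1:
        return 1.0
    major, minor = _axis_lengths(mask)
    if minor == 0.0:
        return math.inf
    return major / minor


def mask_perimeter(mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Weighted boundary-step contour length of the mask, in µm."""
    if not np.any(mask):
        raise ValueError("perimeter of an empty mask is undefined")
    return float(_weighted_perimeter(mask.astype(bool), neighborhood=4)) * pixel_size_um


@dataclass
class MorphometricRecord:
    """One segmented cell's six shape parameters plus identifiers.

    µm-scale values use ``pixel_size_um``; raw pixel values are kept
    alongside.  ``roundness`` is clipped to 1 only when discretization
    overshoots the isoperimetric bound, in which case
    ``roundness_clipped`` is set.  Degenerate line masks flag
    ``eccentricity_degenerate`` and should be excluded from statistics.
    """

    cell_id: int
    region: str
    condition: str
    animal: str
    pixel_size_um: float
    cell_area_px: float
    soma_area_px: float
    cell_spread_px: float
    perimeter_px: float
    eccentricity: float
    roundness: float
    roundness_clipped: bool = False
    eccentricity_degenerate: bool = False

    @property
    def cell_area(self) -> float:
        return self.cell_area_px * self.pixel_size_um ** 2

    @property
    def soma_area(self) -> float:
        return self.soma_area_px * self.pixel_size_um ** 2

    @property
    def cell_spread(self) -> float:
        return self.cell_spread_px * self.pixel_size_um

    @property
    def perimeter(self) -> float:
        return self.perimeter_px * self.pixel_size_um

    def to_row(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "region": self.region,
            "condition": self.condition,
            "animal": self.animal,
            "pixel_size_um": self.pixel_size_um,
            "cell_area_px": self.cell_area_px,
            "soma_area_px": self.soma_area_px,
            "cell_spread_px": self.cell_spread_px,
            "perimeter_px": self.perimeter_px,
            "cell_area": self.cell_area,
            "soma_area": self.soma_area,
            "cell_spread": self.cell_spread,
            "perimeter": self.perimeter,
            "eccentricity": self.eccentricity,
            "roundness": self.roundness,
            "roundness_clipped": self.roundness_clipped,
            "eccentricity_degenerate": self.eccentricity_degenerate,
        }


def measure_cell(
    cell_mask: np.ndarray,
    soma_mask: np.ndarray,
    pixel_size_um: float = 0.42,
    *,
    cell_id: int = 0,
    region: str = "",
    condition: str = "",
    animal: str = "",
) -> MorphometricRecord:
    """Measure the six morphometric parameters of one segmented cell.

    ``soma_mask`` must be a subset of ``cell_mask``.  Raises
    ``ValueError`` on empty masks or soma pixels outside the cell.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    soma_mask = np.asarray(soma_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cannot measure an empty cell mask")
    if not soma_mask.any():
        raise ValueError("cannot measure an empty soma mask")
    if np.any(soma_mask & ~cell_mask):
        raise ValueError("soma mask must be contained in the cell mask")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")

    area_px = float(cell_mask.sum())
    soma_px = float(soma_mask.sum())
    perim_px = mask_perimeter(cell_mask, 1.0)
    spread_px = cell_spread(cell_mask, 1.0)
    rnd = roundness(area_px, perim_px)
    clipped = rnd > 1.0
    if clipped:
        rnd = 1.0
    ecc = eccentricity(cell_mask)
    return MorphometricRecord(
        cell_id=cell_id,
        region=region,
        condition=condition,
        animal=animal,
        pixel_size_um=pixel_size_um,
        cell_area_px=area_px,
        soma_area_px=soma_px,
        cell_spread_px=spread_px,
        perimeter_px=perim_px,
        eccentricity=ecc,
        roundness=rnd,
        roundness_clipped=clipped,
        eccentricity_degenerate=not math.isfinite(ecc),
    )


def measure_scene(
    cells: Iterable,
    pixel_size_um: float = 0.42,
    *,
    region: str = "",
    condition: str = "",
    animal: str = "",
) -> pd.DataFrame:
    """Measure every accepted cell of a scene into one table.

    ``cells`` is an iterable of objects with ``label``, ``mask`` and
    ``soma`` attributes (see :mod:`gliamorph.segmentation`).  Returns a
    DataFrame with one row per cell and the full header even when empty.
    """
    rows = []
    for cell in cells:
        rec = measure_cell(
            cell.mask,
            cell.soma,
            pixel_size_um,
            cell_id=cell.label,
            region=region,
            condition=condition,
            animal=animal,
        )
        rows.append(rec.to_row())
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
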