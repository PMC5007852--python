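"""Scalar quantifications: phagocytic index, colocalization and cell
counts, flow-gating fractions, marking preference, and the social
interaction quotient.

Each function returns an :class:`AssayResult` carrying the scalar value
plus the denominator metadata (areas, counts, durations) needed to
audit it.  Undefined outcomes (no marks on a sheet, no time at the
object cylinder) are flagged, not raised; genuinely invalid inputs
(zero cell area, empty parent gate) raise ``ValueError``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import MarkSheetGeometry, SocialArenaGeometry


@dataclass
class AssayResult:
    """One scalar assay outcome with its denominators."""

    kind: str
    value: float
    meta: dict = field(default_factory=dict)
    undefined: bool = False


# ---------------------------------------------------------------------------
# image-based assays
# ---------------------------------------------------------------------------

def phagocytic_index(
    cell_channel: Union[np.ndarray, Iterable[np.ndarray]],
    particle_channel: np.ndarray,
) -> AssayResult:
    """Engulfed-particle area divided by total cell-marker area.

    Only particle signal *inside* the cell masks counts as phagocytosed.
    ``cell_channel`` may be one mask or an iterable of per-cell masks
    (their union is used).  Zero total cell area raises ``ValueError``.
    """
    if isinstance(cell_channel, np.ndarray):
        cells = cell_channel.astype(bool)
    else:
        masks = [np.asarray(m, dtype=bool) for m in cell_channel]
        if not masks:
            raise ValueError("no cell masks given")
        cells = np.logical_or.reduce(masks)
    particles = np.asarray(particle_channel, dtype=bool)
    cell_area = int(cells.sum())
    if cell_area == 0:
        raise ValueError("phagocytic index undefined: zero cell area")
    engulfed = int((particles & cells).sum())
    return AssayResult(
        "phagocytic_index",
        engulfed / cell_area,
        meta={"engulfed_px": engulfed, "cell_area_px": cell_area},
    )


def _soma_centroids(cells) -> np.ndarray:
    """(n, 2) integer-rounded soma centroids from cells or a label image."""
    if isinstance(cells, np.ndarray):
        labels = np.unique(cells)
        labels = labels[labels > 0]
        if labels.size == 0:
            return np.zeros((0, 2), dtype=int)
        coms = ndimage.center_of_mass(cells > 0, cells, labels)
        return np.rint(np.asarray(coms)).astype(int)
    out = []
    for c in cells:
        soma = c.soma if getattr(c, "soma", None) is not None else c.mask
        ys, xs = np.nonzero(soma)
        if ys.size:
            out.append((int(round(ys.mean())), int(round(xs.mean()))))
    return np.asarray(out, dtype=int).reshape(-1, 2)


def count_colocalized(cells, marker_mask: np.ndarray) -> AssayResult:
    """Number of cells whose soma centroid lies inside the marker mask.

    ``cells`` is either a soma label image or an iterable of segmented
    cells with soma masks.  This is the colocalization rule behind
    double-positive (e.g. proliferation-marker⁺ reporter⁺) counts.
    """
    marker = np.asarray(marker_mask, dtype=bool)
    cents = _soma_centroids(cells)
    n = sum(
        1
        for y, x in cents
        if 0 <= y < marker.shape[0] and 0 <= x < marker.shape[1] and marker[y, x]
    )
    return AssayResult(
        "coloc_count", float(n), meta={"n_cells": int(len(cents))}
    )


def count_cells(cells, window: tuple[int, int, int, int]) -> AssayResult:
    """Number of cells with soma centroid inside ``(y0, y1, x0, x1)``.

    The window is half-open, 0-based, and must satisfy y0 ≤ y1, x0 ≤ x1.
    """
    y0, y1, x0, x1 = window
    if y0 > y1 or x0 > x1:
        raise ValueError("window must satisfy y0 ≤ y1 and x0 ≤ x1")
    cents = _soma_centroids(cells)
    n = sum(1 for y, x in cents if y0 <= y < y1 and x0 <= x < x1)
    return AssayResult("cell_count", float(n), meta={"n_cells": int(len(cents))})


# ---------------------------------------------------------------------------
# flow gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """Rectangular two-step gate: fraction of a child gate inside a parent.

    ``thresholds`` maps a channel to its lo/hi partition threshold;
    ``parent`` and ``child`` name (channel, side) with side "hi" or
    "lo".  The canonical example is CD45-hi within CD11b-hi.
    """

    thresholds: dict
    parent: tuple[str, str]
    child: tuple[str, str]

    def __post_init__(self):
        for ch, thr in self.thresholds.items():
            if not np.isfinite(thr):
                raise ValueError(f"threshold for {ch!r} must be finite")
        for name, (ch, side) in (("parent", self.parent), ("child", self.child)):
            if ch not in self.thresholds:
                raise ValueError(f"{name} channel {ch!r} has no threshold")
            if side not in ("hi", "lo"):
                raise ValueError(f"{name} side must be 'hi' or 'lo'")
        if self.parent[0] == self.child[0]:
            raise ValueError("child channel must differ from parent channel")


def _passes(events: pd.DataFrame, channel: str, side: str, thr: float) -> np.ndarray:
    v = events[channel].to_numpy(dtype=float)
    return v > thr if side == "hi" else v <= thr


def gate_fraction(events: pd.DataFrame, gate: GateSpec) -> AssayResult:
    """(#events in parent ∧ child) / (#events in parent).

    Invariant under any strictly monotone transform applied jointly to
    the events and the thresholds.  An empty parent population raises
    ``ValueError``.
    """
    pch, pside = gate.parent
    cch, cside = gate.child
    parent = _passes(events, pch, pside, gate.thresholds[pch])
    n_parent = int(parent.sum())
    if n_parent == 0:
        raise ValueError("gate fraction undefined: empty parent population")
    child = _passes(events, cch, cside, gate.thresholds[cch])
    n_both = int((parent & child).sum())
    return AssayResult(
        "gate_fraction",
        n_both / n_parent,
        meta={"n_parent": n_parent, "n_child": n_both},
    )


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def marking_preference(
    sheet: np.ndarray,
    geometry: Optional[MarkSheetGeometry] = None,
) -> AssayResult:
    """Percent of total mark area falling inside the target circle.

    100 × (mark pixels inside the target quadrant circle) / (mark pixels
    in the arena).  A sheet with zero marks is flagged undefined.
    """
    geometry = geometry or MarkSheetGeometry()
    sheet = np.asarray(sheet, dtype=bool)
    if sheet.shape != geometry.sheet_shape:
        raise ValueError(
            f"sheet shape {sheet.shape} does not match geometry "
            f"{geometry.sheet_shape}"
        )
    total = int(sheet.sum())
    if total == 0:
        return AssayResult("marking_preference", float("nan"),
                           meta={"total_px": 0}, undefined=True)
    inside = int((sheet & geometry.target_circle_mask()).sum())
    return AssayResult(
        "marking_preference",
        100.0 * inside / total,
        meta={"inside_px": inside, "total_px": total},
    )


def si_quotient(
    track: pd.DataFrame,
    geometry: Optional[SocialArenaGeometry] = None,
    frame_interval_s: Optional[float] = None,
) -> AssayResult:
    """Time at the occupied cylinder divided by time at the empty one.

    Zone membership is evaluated per frame; dwell time is the frame
    count times the frame interval (inferred from the median timestamp
    step when not given).  Zero object-zone time flags the quotient
    undefined rather than raising.
    """
    geometry = geometry or SocialArenaGeometry()
    for col in ("t", "x", "y"):
        if col not in track.columns:
            raise ValueError(f"track is missing column {col!r}")
    if frame_interval_s is None:
        dt = np.diff(track["t"].to_numpy(dtype=float))
        frame_interval_s = float(np.median(dt)) if dt.size else 1.0
    x = track["x"].to_numpy(dtype=float)
    y = track["y"].to_numpy(dtype=float)
    social_s = float(geometry.in_zone(x, y, "social").sum()) * frame_interval_s
    object_s = float(geometry.in_zone(x, y, "object").sum()) * frame_interval_s
    meta = {"social_s": social_s, "object_s": object_s,
            "frame_interval_s": frame_interval_s}
    if object_s == 0.0:
        return AssayResult("si_quotient", float("nan"), meta=meta, undefined=True)
    return AssayResult("si_quotient", social_s / object_s, meta=meta)
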