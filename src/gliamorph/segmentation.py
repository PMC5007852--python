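"""Automated microglia segmentation from confocal z-stacks.

The pipeline mirrors the classic automated morphometry workflow for
GFP-labelled microglia:

1. collapse the 3D stack into a 2D maximum intensity projection (MIP);
2. find candidate cell positions as regional maxima of the smoothed MIP
   (h-maxima with a prominence given as a fraction of dynamic range);
3. around each seed, grow a cell mask by iterative thresholding: the
   threshold starts at the seed peak and decreases stepwise; at every
   level the mask is the connected component containing the seed, and
   iteration stops when the component floods into background (relative
   area growth per step exceeds ``growth_stop_ratio``); regions claimed
   by several seeds are split by geodesic distance, and the mask
   boundary is then refined on a lightly smoothed image so that the
   heavy seeding smoothing does not dilate the final masks;
4. post-segmentation QC rejects masks that are not a single connected
   cell with a single soma, are outside area bounds, or touch the frame
   border;
5. the soma is the connected supra-threshold core around the seed.

Coordinates are 0-based ``(row, col) = (y, x)``; masks are boolean
arrays in full-frame coordinates.  Connectivity is 8-neighbour
throughout.  Contested pixels between neighbouring masks are assigned
to the seed with the shorter geodesic distance inside the
supra-threshold region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric
from skimage.morphology import h_maxima

STRUCT8 = np.ones((3, 3), dtype=bool)

#: QC reason codes
QC_ACCEPTED = "accepted"
QC_EMPTY = "empty"
QC_MULTI_COMPONENT = "multi-component"
QC_MULTI_SOMA = "multi-soma"
QC_AREA = "area"
QC_BORDER = "border"


@dataclass(frozen=True)
class SeedPoint:
    """Candidate cell position: regional maximum of the smoothed MIP."""

    y: int
    x: int
    peak_intensity: float


@dataclass
class SegmentationParams:
    """Tunables the original workflow leaves implicit.

    Fractional parameters (``h_maxima_frac``, ``threshold_step_frac``)
    are relative to the dynamic range of the smoothed MIP.  Defaults are
    sized for 0.42 µm/px microglia imagery.  ``growth_guard_px`` arms
    the flooding test only once the component has outgrown the seed
    plateau, since the first levels around a 1–2 px peak always multiply
    in area.
    """

    smoothing_sigma_px: float = 2.0
    h_maxima_frac: float = 0.10
    min_seed_separation_px: float = 25.0
    threshold_step_frac: float = 0.05
    growth_stop_ratio: float = 3.0
    growth_guard_px: int = 30
    area_bounds_px: tuple[int, int] = (50, 5000)
    border_margin_px: int = 2
    soma_intensity_fraction: float = 0.5
    window_halfwidth_px: int = 96
    refine_sigma_px: float = 0.7
    refine_hi_snr: float = 6.5
    refine_lo_snr: float = 4.0
    refine_clean_hi_frac: float = 0.35
    refine_clean_lo_frac: float = 0.20

    def validate(self) -> None:
        for name in ("h_maxima_frac", "threshold_step_frac", "soma_intensity_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.area_bounds_px[0] > self.area_bounds_px[1]:
            raise ValueError("area bounds must satisfy min ≤ max")
        if self.growth_stop_ratio <= 1.0:
            raise ValueError("growth_stop_ratio must exceed 1")
        if self.smoothing_sigma_px < 0 or self.min_seed_separation_px < 0:
            raise ValueError("lengths must be non-negative")


@dataclass
class SegmentedCell:
    """One seed's mask with QC status and (after extraction) its soma."""

    label: int
    mask: np.ndarray
    seed: SeedPoint
    soma: Optional[np.ndarray] = None
    qc_status: str = "pending"
    soma_fallback: bool = False


def max_intensity_project(stack: np.ndarray) -> np.ndarray:
    """2D MIP of a (z, y, x) stack: per-pixel maximum over z."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a non-empty (z, y, x) array")
    return stack.max(axis=0)


def smooth(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Gaussian-smoothed working image used by seeding and growth."""
    img = np.asarray(image, dtype=float)
    if params.smoothing_sigma_px > 0:
        img = ndimage.gaussian_filter(img, params.smoothing_sigma_px)
    return img


def detect_seeds(image: np.ndarray, params: SegmentationParams) -> list[SeedPoint]:
    """Regional-maxima seeds with prominence and separation constraints.

    Maxima of the smoothed image with prominence ≥ ``h_maxima_frac`` ×
    dynamic range; a connected equal-intensity plateau counts as one
    maximum at (the pixel nearest) its centroid.  Seeds closer than
    ``min_seed_separation_px`` are suppressed keeping the brighter one.
    """
    params.validate()
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("image is empty")
    sm = smooth(img, params)
    dyn = float(sm.max() - sm.min())
    if dyn == 0.0:
        return []
    h = params.h_maxima_frac * dyn
    peaks = h_maxima(sm, h)
    lab, n = ndimage.label(peaks, structure=STRUCT8)
    if n == 0:
        return []
    seeds = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(lab == i)
        cy, cx = ys.mean(), xs.mean()
        j = int(np.argmin((ys - cy) ** 2 + (xs - cx) ** 2))  # snap to plateau
        y, x = int(ys[j]), int(xs[j])
        seeds.append(SeedPoint(y, x, float(sm[y, x])))
    seeds.sort(key=lambda s: (-s.peak_intensity, s.y, s.x))
    kept: list[SeedPoint] = []
    for s in seeds:
        if all(
            math.hypot(s.y - k.y, s.x - k.x) >= params.min_seed_separation_px
            for k in kept
        ):
            kept.append(s)
    return kept


def _grow_one(
    sm: np.ndarray,
    seed: SeedPoint,
    params: SegmentationParams,
    step: float,
    floor: float,
) -> Optional[np.ndarray]:
    """Iterative-threshold growth of one seed inside a local window.

    Returns the final boolean mask in full-frame coordinates, or None
    when no level is accepted (seed planted on background floods at the
    first step).  The grown region may overlap neighbouring seeds'
    regions; :func:`_resolve_overlaps` partitions contested pixels.
    """
    H, W = sm.shape
    w = params.window_halfwidth_px
    y0 = max(seed.y - w, 0)
    y1 = min(seed.y + w + 1, H)
    x0 = max(seed.x - w, 0)
    x1 = min(seed.x + w + 1, W)
    local = sm[y0:y1, x0:x1]
    sy, sx = seed.y - y0, seed.x - x0

    max_area = 2 * params.area_bounds_px[1]
    last_good: Optional[np.ndarray] = None
    level = seed.peak_intensity - step
    while level > floor:
        lab, _ = ndimage.label(local >= level, structure=STRUCT8)
        comp = lab == lab[sy, sx]
        area = int(comp.sum())
        if area > max_area:
            break  # flooded far past any plausible cell
        # component reaching the working window edge ⇒ runaway growth
        if comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any():
            break
        if last_good is not None:
            prev = int(last_good[y0:y1, x0:x1].sum())
            if prev >= params.growth_guard_px and area > params.growth_stop_ratio * prev:
                break
        full = np.zeros((H, W), dtype=bool)
        full[y0:y1, x0:x1] = comp
        last_good = full
        level -= step
    return last_good


def _refine_masks(
    cells: list[SegmentedCell],
    image: np.ndarray,
    params: SegmentationParams,
) -> None:
    """Tighten mask boundaries on a lightly smoothed image.

    The heavy seeding/growth smoothing dilates boundaries by roughly its
    sigma, so the final mask keeps only pixels above a strict intensity
    level on a ``refine_sigma_px``-smoothed image, re-bridged by the
    skeleton of a moderate-level support so that faint process arms are
    not severed at single weak pixels.  Background level and noise are
    estimated robustly (median; sd of the dimmest 80 % of pixels).
    """
    from skimage.morphology import skeletonize

    smr = np.asarray(image, dtype=float)
    if params.refine_sigma_px > 0:
        smr = ndimage.gaussian_filter(smr, params.refine_sigma_px)
    bg = float(np.median(smr))
    low = smr[smr < np.percentile(smr, 80)]
    noise = float(low.std()) if low.size else 0.0
    for c in cells:
        if not c.mask.any():
            continue
        # On effectively noiseless images the noise floor collapses to
        # ~zero and would keep the whole smoothing halo; fall back to a
        # fraction of the cell's peak contrast (half-maximum-style edge
        # estimate) whenever the noise band is negligible against it.
        peak = float(smr[c.seed.y, c.seed.x])
        contrast = max(peak - bg, 0.0)
        if params.refine_hi_snr * noise >= 0.05 * contrast:
            thr_hi = bg + params.refine_hi_snr * noise
            thr_lo = bg + params.refine_lo_snr * noise
        else:
            thr_hi = bg + params.refine_clean_hi_frac * contrast
            thr_lo = bg + params.refine_clean_lo_frac * contrast
        support = c.mask & (smr >= thr_lo)
        refined = (c.mask & (smr >= thr_hi)) | skeletonize(support)
        refined = ndimage.binary_fill_holes(refined)
        refined &= c.mask
        if not refined[c.seed.y, c.seed.x]:
            refined[c.seed.y, c.seed.x] = True
        lab, _ = ndimage.label(refined, structure=STRUCT8)
        c.mask = lab == lab[c.seed.y, c.seed.x]


def _resolve_overlaps(
    cells: list[SegmentedCell], sm: np.ndarray
) -> None:
    """Assign contested pixels by geodesic distance within the union region."""
    if len(cells) < 2:
        return
    count = np.zeros(sm.shape, dtype=np.int16)
    for c in cells:
        count += c.mask
    contested = count > 1
    if not contested.any():
        return
    involved = [c for c in cells if np.any(c.mask & contested)]
    region = np.zeros(sm.shape, dtype=bool)
    for c in involved:
        region |= c.mask
    costs = np.where(region, 1.0, np.inf)
    dists = []
    for c in involved:
        mcp = MCP_Geometric(costs)
        d, _ = mcp.find_costs([(c.seed.y, c.seed.x)])
        dists.append(d)
    dists = np.stack(dists)
    owner = np.argmin(dists, axis=0)
    for i, c in enumerate(involved):
        drop = contested & c.mask & (owner != i)
        if drop.any():
            c.mask = c.mask & ~drop
            # removal may disconnect the mask: keep the seed's component
            lab, _ = ndimage.label(c.mask, structure=STRUCT8)
            c.mask = lab == lab[c.seed.y, c.seed.x]


def segment_cells(
    image: np.ndarray,
    seeds: Sequence[SeedPoint],
    params: SegmentationParams,
) -> list[SegmentedCell]:
    """Grow one mask per seed by iterative thresholding; masks disjoint.

    Seeds whose component floods at the first level (planted on
    background) get an empty mask with ``qc_status = "empty"``.
    """
    params.validate()
    sm = smooth(np.asarray(image, dtype=float), params)
    dyn = float(sm.max() - sm.min())
    step = params.threshold_step_frac * dyn if dyn > 0 else 1.0
    floor = float(sm.min())
    cells: list[SegmentedCell] = []
    for i, seed in enumerate(seeds):
        mask = _grow_one(sm, seed, params, step, floor)
        if mask is None or not mask.any():
            cells.append(
                SegmentedCell(i + 1, np.zeros(sm.shape, dtype=bool), seed,
                              qc_status=QC_EMPTY)
            )
        else:
            cells.append(SegmentedCell(i + 1, mask, seed))
    grown = [c for c in cells if c.qc_status != QC_EMPTY]
    _resolve_overlaps(grown, sm)
    _refine_masks(grown, image, params)
    return cells


def qc_masks(
    cells: Sequence[SegmentedCell],
    image: np.ndarray,
    params: SegmentationParams,
) -> tuple[list[SegmentedCell], list[tuple[int, str]]]:
    """Post-segmentation QC: each mask must be one cell with one soma.

    Rejects masks that are empty, split into several components,
    contain more than one seed, fall outside area bounds, or intersect
    the border margin.  Returns ``(accepted, log)`` where ``log`` lists
    every cell's (label, reason); accepted cells are annotated with
    ``qc_status = "accepted"``.
    """
    params.validate()
    H, W = np.asarray(image).shape
    m = params.border_margin_px
    seed_map = np.zeros((H, W), dtype=bool)
    for c in cells:
        seed_map[c.seed.y, c.seed.x] = True
    accepted = []
    log = []
    for c in cells:
        reason = None
        if c.qc_status == QC_EMPTY or not c.mask.any():
            reason = QC_EMPTY
        else:
            _, n = ndimage.label(c.mask, structure=STRUCT8)
            area = int(c.mask.sum())
            if n != 1:
                reason = QC_MULTI_COMPONENT
            elif int((c.mask & seed_map).sum()) > 1:
                reason = QC_MULTI_SOMA
            elif not params.area_bounds_px[0] <= area <= params.area_bounds_px[1]:
                reason = QC_AREA
            elif m > 0 and (
                c.mask[:m, :].any() or c.mask[-m:, :].any()
                or c.mask[:, :m].any() or c.mask[:, -m:].any()
            ):
                reason = QC_BORDER
        if reason is None:
            c.qc_status = QC_ACCEPTED
            accepted.append(c)
            log.append((c.label, QC_ACCEPTED))
        else:
            c.qc_status = reason
            log.append((c.label, reason))
    return accepted, log


def extract_soma(
    image: np.ndarray,
    cell: SegmentedCell,
    params: SegmentationParams,
    background: Optional[float] = None,
) -> np.ndarray:
    """Soma mask: supra-threshold core of the cell around its seed.

    The cell's pixels are thresholded at ``soma_intensity_fraction`` of
    the seed peak measured above background (the image median unless
    given), and the soma is the connected component containing the
    seed.  An empty result falls back to the seed pixel and sets
    ``cell.soma_fallback``.  The soma is always a subset of the mask.
    """
    params.validate()
    sm = smooth(np.asarray(image, dtype=float), params)
    if background is None:
        background = float(np.median(sm))
    thresh = background + params.soma_intensity_fraction * (
        cell.seed.peak_intensity - background
    )
    candidate = cell.mask & (sm >= thresh)
    soma = np.zeros_like(cell.mask)
    if candidate[cell.seed.y, cell.seed.x]:
        lab, _ = ndimage.label(candidate, structure=STRUCT8)
        soma = lab == lab[cell.seed.y, cell.seed.x]
    if not soma.any():
        soma[cell.seed.y, cell.seed.x] = True
        cell.soma_fallback = True
        soma &= cell.mask
        if not soma.any():  # seed fell off its mask after overlap resolution
            ys, xs = np.nonzero(cell.mask)
            soma[ys[0], xs[0]] = True
    cell.soma = soma
    return soma


def segment_stack(
    stack: np.ndarray,
    params: Optional[SegmentationParams] = None,
) -> tuple[list[SegmentedCell], list[tuple[int, str]], np.ndarray]:
    """Full per-field pipeline: MIP → seeds → masks → QC → somas.

    Convenience wrapper returning ``(accepted_cells, qc_log, mip)``;
    every accepted cell carries its soma mask.
    """
    params = params or SegmentationParams()
    mip = max_intensity_project(stack)
    seeds = detect_seeds(mip, params)
    cells = segment_cells(mip, seeds, params)
    accepted, log = qc_masks(cells, mip, params)
    sm = smooth(np.asarray(mip, dtype=float), params)
    background = float(np.median(sm))
    for c in accepted:
        extract_soma(mip, c, params, background=background)
    return accepted, log, mip
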