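"""Synthetic ground-truth inputs for every stage of the pipeline.

The study's raw data (confocal z-stacks of GFP-labelled microglia, flow
event tables, binarized scent-mark sheets, locomotion tracks) are not
deposited, so this module generates stand-ins with *known* ground truth:

* microglia image stacks at controlled density and SNR, contrasting a
  ramified "resting" regime with a rounder, larger-soma "activated"
  regime (the morphology shift classically driven by LPS);
* two-channel phagocytosis scenes with an exactly known engulfed-area
  fraction;
* flow-cytometry event tables drawn from log-normal channel mixtures
  with exact per-event truth labels;
* binary scent-mark sheets with an exactly known in-circle area share;
* zone-dwell locomotion tracks with exact per-frame dwell truth.

Every ground-truth scalar is an exact count or ratio over the generated
masks/labels/events, recomputable with a naive loop.  Generation is
deterministic given (spec, seed): the same preset and seed reproduce
identical arrays byte for byte.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import morphometry
from .geometry import MarkSheetGeometry, SocialArenaGeometry

STRUCT8 = np.ones((3, 3), dtype=bool)


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed at the requested spacing."""


def derive_seed(seed: int, *tokens) -> int:
    """Stable sub-seed from a global seed and a tuple of string tokens.

    CRC32-based so the mapping is reproducible across sessions and
    platforms; result is a non-negative int below 2**31.
    """
    key = ":".join([str(seed), *map(str, tokens)]).encode()
    return zlib.crc32(key) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# cell morphology
# ---------------------------------------------------------------------------

@dataclass
class CellSpec:
    """Parametric description of one microglia morphology regime.

    Soma is an ellipse of geometric-mean radius ``soma_radius_px`` and
    axis ratio ``soma_axis_ratio``; processes are thickness-tapered
    random walks grown from the soma boundary with recursive branching.
    """

    soma_radius_px: float = 6.0
    soma_axis_ratio: float = 1.2
    n_primary_processes: int = 5
    process_length_px: float = 20.0
    branch_depth: int = 2
    branch_prob: float = 0.4
    process_thickness_px: float = 2.4
    intensity_scale: float = 1.0

    def validate(self) -> None:
        if self.soma_radius_px <= 0:
            raise ValueError("soma_radius_px must be > 0")
        if self.soma_axis_ratio < 1:
            raise ValueError("soma_axis_ratio must be ≥ 1")
        if self.n_primary_processes < 0 or self.branch_depth < 0:
            raise ValueError("counts must be ≥ 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        if self.n_primary_processes > 0:
            if self.process_length_px <= 0 or self.process_thickness_px <= 0:
                raise ValueError("process length/thickness must be > 0")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be > 0")


#: ramified, surveillance-state morphology (homecage-like)
RESTING_CELL = CellSpec()

#: amoeboid, activated morphology: 1.3× soma radius, few short processes
ACTIVATED_CELL = CellSpec(
    soma_radius_px=7.8,
    soma_axis_ratio=1.1,
    n_primary_processes=2,
    process_length_px=8.0,
    branch_depth=1,
    branch_prob=0.2,
    process_thickness_px=2.0,
)


def _stamp_disk(mask: np.ndarray, cy: float, cx: float, r: float) -> None:
    h, w = mask.shape
    y0 = max(int(math.floor(cy - r)), 0)
    y1 = min(int(math.ceil(cy + r)) + 1, h)
    x0 = max(int(math.floor(cx - r)), 0)
    x1 = min(int(math.ceil(cx + r)) + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _grow_process(
    mask: np.ndarray,
    rng: np.random.Generator,
    y: float,
    x: float,
    angle: float,
    length: float,
    thickness: float,
    depth: int,
    spec: CellSpec,
) -> None:
    # tapered random walk: step 1 px, direction jitter, radius shrinks
    # linearly to ~0.8 px at the tip so arms thin out distally
    n_steps = max(int(round(length)), 1)
    waypoints = []
    for i in range(n_steps):
        y += math.sin(angle)
        x += math.cos(angle)
        angle += rng.normal(0.0, 0.22)
        frac = i / n_steps
        r = max(0.8, (thickness / 2.0) * (1.0 - 0.55 * frac))
        _stamp_disk(mask, y, x, r)
        waypoints.append((y, x, angle))
    if depth < spec.branch_depth and len(waypoints) > 3:
        for _ in range(2):
            if rng.random() < spec.branch_prob:
                j = int(rng.integers(len(waypoints) // 3, len(waypoints)))
                by, bx, bang = waypoints[j]
                child_angle = bang + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.1)
                _grow_process(
                    mask, rng, by, bx, child_angle,
                    length * 0.6, thickness * 0.75, depth + 1, spec,
                )


def generate_cell(
    spec: CellSpec,
    rng: np.random.Generator,
    pixel_size_um: float = 0.42,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate one cell on a local canvas.

    Returns ``(cell_mask, soma_mask, true_params)`` where the masks are
    boolean arrays on a square canvas and ``true_params`` holds the six
    morphometric parameters computed from the noiseless masks.  The cell
    mask is a single 8-connected component containing exactly one soma,
    and the soma mask is a subset of the cell mask.
    """
    spec.validate()
    a = spec.soma_radius_px * math.sqrt(spec.soma_axis_ratio)
    b = spec.soma_radius_px / math.sqrt(spec.soma_axis_ratio)
    # canvas sized for worst-case wandering: total branch path ≤ 2×length
    half = int(math.ceil(a + 2.0 * spec.process_length_px * (1 if spec.n_primary_processes else 0) + 6))
    size = 2 * half + 1
    cell = np.zeros((size, size), dtype=bool)
    cy = cx = float(half)

    theta = rng.uniform(0.0, math.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - cy
    dx = xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    soma = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    cell |= soma

    if spec.n_primary_processes > 0:
        base = rng.uniform(0.0, 2.0 * math.pi)
        for k in range(spec.n_primary_processes):
            ang = base + 2.0 * math.pi * k / spec.n_primary_processes
            ang += rng.normal(0.0, 0.25)
            # start just inside the soma boundary along this direction
            rad = 0.95 / math.sqrt(
                (math.cos(ang - theta) / a) ** 2 + (math.sin(ang - theta) / b) ** 2
            )
            py = cy + rad * math.sin(ang)
            px = cx + rad * math.cos(ang)
            length = spec.process_length_px * rng.uniform(0.75, 1.25)
            _grow_process(cell, rng, py, px, ang, length,
                          spec.process_thickness_px, 0, spec)

    # the disk-chain construction keeps arms attached, but guard anyway
    lab, n = ndimage.label(cell, structure=STRUCT8)
    if n > 1:
        keep = lab[int(round(cy)), int(round(cx))]
        cell = lab == keep
        soma = soma & cell

    rec = morphometry.measure_cell(cell, soma, pixel_size_um)
    true_params = rec.to_row()
    return cell, soma, true_params


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

@dataclass
class ScenePreset:
    """Everything needed to render one synthetic confocal field.

    Default acquisition geometry follows the study design: 10 optical
    sections 1 µm apart at 0.42 µm/pixel.  ``snr`` is defined as
    (peak noiseless soma intensity − background mean) / background sd.
    ``dispersion`` is the multiplicative (log-normal) spread applied to
    the continuous cell-spec parameters between cells.
    """

    name: str = "resting"
    cell_spec: CellSpec = field(default_factory=CellSpec)
    dispersion: float = 0.08
    n_cells: int = 30
    min_center_spacing_px: float = 55.0
    stack_shape: tuple[int, int, int] = (10, 512, 512)
    pixel_size_um: float = 0.42
    z_step_um: float = 1.0
    background_level: float = 40.0
    background_sd: float = 5.0
    snr: float = 8.0
    poisson_gain: float = 0.5
    process_intensity_frac: float = 0.55
    z_sigma_slices: float = 0.8
    attenuation_per_slice: float = 0.015
    rng_seed: int = 0

    def validate(self) -> None:
        self.cell_spec.validate()
        nz, h, w = self.stack_shape
        if nz < 1 or h < 8 or w < 8:
            raise ValueError("stack too small")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be ≥ 0")
        if self.background_sd <= 0 or self.snr <= 0:
            raise ValueError("background_sd and snr must be positive")
        # crude capacity check: disks of half the min spacing must fit
        packed = self.n_cells * math.pi * (self.min_center_spacing_px / 2.0) ** 2
        if packed > 0.75 * h * w:
            raise ValueError(
                f"stack {h}×{w} too small for {self.n_cells} cells "
                f"at spacing {self.min_center_spacing_px}"
            )


def resting_preset(seed: int = 0, **overrides) -> ScenePreset:
    """Ramified, homecage-like field preset."""
    return replace(ScenePreset(name="resting", cell_spec=replace(RESTING_CELL),
                               rng_seed=seed), **overrides)


def activated_preset(seed: int = 0, **overrides) -> ScenePreset:
    """Amoeboid, LPS-like field preset (larger somas, short sparse arms)."""
    return replace(ScenePreset(name="activated", cell_spec=replace(ACTIVATED_CELL),
                               rng_seed=seed), **overrides)


PRESETS = {"resting": resting_preset, "activated": activated_preset}


def draw_cell_spec(preset: ScenePreset, rng: np.random.Generator) -> CellSpec:
    """Per-cell jitter of the preset's mean cell spec."""
    s = preset.cell_spec
    cv = preset.dispersion
    def ln(mean):
        return float(mean * rng.lognormal(-0.5 * cv * cv, cv))
    n_proc = s.n_primary_processes
    if n_proc > 0:
        n_proc = int(np.clip(n_proc + rng.integers(-1, 2), 1, None))
    return replace(
        s,
        soma_radius_px=ln(s.soma_radius_px),
        process_length_px=ln(s.process_length_px) if s.n_primary_processes else s.process_length_px,
        process_thickness_px=ln(s.process_thickness_px) if s.n_primary_processes else s.process_thickness_px,
        n_primary_processes=n_proc,
        intensity_scale=ln(s.intensity_scale),
    )


@dataclass
class SyntheticScene:
    """Rendered stack plus projection-level ground truth."""

    stack: np.ndarray                 # (z, y, x) float32 intensities
    truth_labels: np.ndarray          # (y, x) int32 projected cell labels
    truth_soma_labels: np.ndarray     # (y, x) int32 projected soma labels
    truth_params: pd.DataFrame        # one row per cell, true morphometrics
    preset: ScenePreset
    seed: int


TRUTH_COLUMNS = (
    "label", "cy", "cx", "z0", "soma_equiv_radius_px",
) + tuple(morphometry.RECORD_COLUMNS)


def render_scene(preset: ScenePreset) -> SyntheticScene:
    """Render one synthetic confocal field with stored ground truth.

    Cells are placed at pairwise centre spacing ≥
    ``min_center_spacing_px`` and with strictly non-overlapping masks
    (bounded rejection sampling; raises :class:`PlacementError` on
    failure).  Each cell contributes to its three nearest z-slices with
    a Gaussian falloff; slices are attenuated with depth; noise is
    Poisson shot noise on the signal plus additive Gaussian background.
    """
    preset.validate()
    rng = np.random.default_rng(preset.rng_seed)
    nz, h, w = preset.stack_shape
    margin = 3

    labels = np.zeros((h, w), dtype=np.int32)
    soma_labels = np.zeros((h, w), dtype=np.int32)
    signal = np.zeros((nz, h, w), dtype=np.float64)
    amplitude = preset.snr * preset.background_sd

    centers: list[tuple[float, float]] = []
    rows = []
    for label in range(1, preset.n_cells + 1):
        placed = False
        for _attempt in range(500):
            spec = draw_cell_spec(preset, rng)
            cell, soma, params = generate_cell(spec, rng, preset.pixel_size_um)
            ys, xs = np.nonzero(cell)
            y0, y1 = ys.min(), ys.max()
            x0, x1 = xs.min(), xs.max()
            ch, cw = cell.shape
            c_local = (ch - 1) / 2.0
            lo_y = margin - y0
            hi_y = h - margin - 1 - y1
            lo_x = margin - x0
            hi_x = w - margin - 1 - x1
            if hi_y < lo_y or hi_x < lo_x:
                continue
            oy = int(rng.integers(lo_y, hi_y + 1))
            ox = int(rng.integers(lo_x, hi_x + 1))
            cy = c_local + oy
            cx = c_local + ox
            if centers:
                cc = np.asarray(centers)
                if np.min(np.hypot(cc[:, 0] - cy, cc[:, 1] - cx)) < preset.min_center_spacing_px:
                    continue
            sl = (slice(oy + y0, oy + y1 + 1), slice(ox + x0, ox + x1 + 1))
            cell_crop = cell[y0:y1 + 1, x0:x1 + 1]
            if np.any(labels[sl][cell_crop]):
                continue
            # accept
            soma_crop = soma[y0:y1 + 1, x0:x1 + 1]
            labels[sl][cell_crop] = label
            soma_labels[sl][soma_crop] = label
            centers.append((cy, cx))
            z0 = int(rng.integers(1, nz - 1)) if nz >= 3 else nz // 2
            amp = amplitude * spec.intensity_scale
            base = np.where(soma_crop, amp, np.where(cell_crop, preset.process_intensity_frac * amp, 0.0))
            for z in range(max(z0 - 1, 0), min(z0 + 1, nz - 1) + 1):
                wz = math.exp(-((z - z0) ** 2) / (2.0 * preset.z_sigma_slices ** 2))
                signal[z][sl] += wz * base
            row = {"label": label, "cy": cy, "cx": cx, "z0": z0,
                   "soma_equiv_radius_px": math.sqrt(params["soma_area_px"] / math.pi)}
            row.update(params)
            rows.append(row)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {label}/{preset.n_cells} "
                f"at spacing {preset.min_center_spacing_px}"
            )

    atten = (1.0 - preset.attenuation_per_slice) ** np.arange(nz)
    signal *= atten[:, None, None]
    gain = preset.poisson_gain
    stack = rng.poisson(signal / gain) * gain + rng.normal(
        preset.background_level, preset.background_sd, size=signal.shape
    )
    stack = np.clip(stack, 0.0, None).astype(np.float32)

    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return SyntheticScene(
        stack=stack,
        truth_labels=labels,
        truth_soma_labels=soma_labels,
        truth_params=truth,
        preset=preset,
        seed=preset.rng_seed,
    )


# ---------------------------------------------------------------------------
# phagocytosis scenes
# ---------------------------------------------------------------------------

@dataclass
class PhagocytosisScene:
    """Two-channel assay scene with exact engulfed-area ground truth."""

    cell_channel_mask: np.ndarray      # CD11b-like cell channel, bool
    particle_channel_mask: np.ndarray  # TAMRA-like particle channel, bool
    truth_engulfed_fraction: float     # |particle ∩ cell| / |cell|, exact


def generate_phagocytosis_scene(
    n_cells: int,
    engulfed_fraction: float,
    rng: np.random.Generator,
    shape: tuple[int, int] = (256, 256),
    cell_radius_px: tuple[float, float] = (9.0, 14.0),
    particle_radius_px: tuple[float, float] = (2.0, 4.0),
    n_outside_particles: int = 3,
) -> PhagocytosisScene:
    """Scene of disk-like cells with particles engulfed to a target fraction.

    The realized ``truth_engulfed_fraction`` equals the request to within
    one pixel quantum: particle blobs are grown inside cells until the
    engulfed pixel count reaches ``round(f × cell_area)``, then trimmed
    pixel by pixel to the exact count.  Extra particles are scattered
    outside the cells and do not count toward the truth.
    """
    if n_cells <= 0:
        raise ValueError("phagocytic index is undefined without cells")
    if not 0.0 <= engulfed_fraction <= 1.0:
        raise ValueError("engulfed_fraction must be in [0, 1]")
    h, w = shape
    cells = np.zeros(shape, dtype=bool)
    centers = []
    for _ in range(n_cells):
        for _attempt in range(300):
            r = rng.uniform(*cell_radius_px)
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            if centers and np.min(
                np.hypot(np.array(centers)[:, 0] - cy, np.array(centers)[:, 1] - cx)
            ) < 2.2 * cell_radius_px[1]:
                continue
            _stamp_disk(cells, cy, cx, r)
            centers.append((cy, cx))
            break
        else:
            raise PlacementError("could not place phagocytosis cells")

    cell_area = int(cells.sum())
    target = int(round(engulfed_fraction * cell_area))
    particles = np.zeros(shape, dtype=bool)

    cell_ys, cell_xs = np.nonzero(cells)
    for _ in range(2000):
        engulfed = int((particles & cells).sum())
        if engulfed >= target:
            break
        j = int(rng.integers(cell_ys.size))
        _stamp_disk(particles, float(cell_ys[j]), float(cell_xs[j]),
                    rng.uniform(*particle_radius_px))
    # deterministic completion: add single pixels if blobs did not reach target
    engulfed = int((particles & cells).sum())
    if engulfed < target:
        free = np.flatnonzero(cells.ravel() & ~particles.ravel())
        pick = rng.choice(free, size=target - engulfed, replace=False)
        particles.ravel()[pick] = True
    # trim overshoot to the exact pixel count
    engulfed_idx = np.flatnonzero((particles & cells).ravel())
    excess = engulfed_idx.size - target
    if excess > 0:
        drop = rng.choice(engulfed_idx, size=excess, replace=False)
        particles.ravel()[drop] = False

    for _ in range(n_outside_particles):
        for _attempt in range(100):
            r = rng.uniform(*particle_radius_px)
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            blob = np.zeros(shape, dtype=bool)
            _stamp_disk(blob, cy, cx, r)
            if not np.any(blob & cells):
                particles |= blob
                break

    truth = int((particles & cells).sum()) / cell_area
    return PhagocytosisScene(cells, particles, truth)


# ---------------------------------------------------------------------------
# scent-mark sheets
# ---------------------------------------------------------------------------

@dataclass
class MarkSheetSpec:
    """Blob statistics and placement bias for one synthetic mark sheet.

    ``target_bias`` is the probability that a blob is centred uniformly
    inside the target circle; the remainder are uniform over the arena
    (``target_bias = 0`` is fully uniform placement).
    """

    geometry: MarkSheetGeometry = field(default_factory=MarkSheetGeometry)
    n_blobs_mean: float = 40.0
    blob_radius_cm: tuple[float, float] = (0.2, 0.8)
    target_bias: float = 0.3

    def validate(self) -> None:
        if self.n_blobs_mean < 0:
            raise ValueError("n_blobs_mean must be ≥ 0")
        if not 0.0 <= self.target_bias <= 1.0:
            raise ValueError("target_bias must be in [0, 1]")
        if self.blob_radius_cm[0] <= 0 or self.blob_radius_cm[1] < self.blob_radius_cm[0]:
            raise ValueError("invalid blob radius range")


@dataclass
class MarkSheet:
    """Binary sheet with exact in-target-circle truth preference (percent)."""

    sheet: np.ndarray
    geometry: MarkSheetGeometry
    truth_preference: float   # nan when undefined
    undefined: bool


def generate_mark_sheet(spec: MarkSheetSpec, rng: np.random.Generator) -> MarkSheet:
    """Binary scent-mark sheet with exact pixel-membership ground truth."""
    spec.validate()
    geo = spec.geometry
    sheet = np.zeros(geo.sheet_shape, dtype=bool)
    n_blobs = int(rng.poisson(spec.n_blobs_mean))
    cx0, cy0 = geo.circle_centers_cm()[geo.target_quadrant]
    for _ in range(n_blobs):
        if rng.random() < spec.target_bias:
            rr = geo.radius_cm * math.sqrt(rng.random())
            th = rng.uniform(0.0, 2.0 * math.pi)
            x = cx0 + rr * math.cos(th)
            y = cy0 + rr * math.sin(th)
        else:
            x = rng.uniform(0.0, geo.arena_size_cm)
            y = rng.uniform(0.0, geo.arena_size_cm)
        r_px = rng.uniform(*spec.blob_radius_cm) * geo.px_per_cm
        _stamp_disk(sheet, y * geo.px_per_cm - 0.5, x * geo.px_per_cm - 0.5, r_px)
    total = int(sheet.sum())
    if total == 0:
        return MarkSheet(sheet, geo, float("nan"), True)
    inside = int((sheet & geo.target_circle_mask()).sum())
    return MarkSheet(sheet, geo, 100.0 * inside / total, False)


# ---------------------------------------------------------------------------
# locomotion tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSpec:
    """Sticky three-state dwell model for the social-interaction arena.

    ``propensities`` are the stationary weights of (social zone, object
    zone, elsewhere); ``persistence`` is the per-frame probability of
    keeping the current state, which sets dwell-bout durations without
    changing the stationary occupancy.
    """

    geometry: SocialArenaGeometry = field(default_factory=SocialArenaGeometry)
    duration_s: float = 1800.0
    frame_interval_s: float = 0.1
    propensities: tuple[float, float, float] = (0.2, 0.2, 0.6)
    persistence: float = 0.95

    def validate(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if any(p < 0 for p in self.propensities) or sum(self.propensities) <= 0:
            raise ValueError("propensities must be non-negative, not all zero")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must be in [0, 1)")


@dataclass
class Track:
    """Time-stamped trajectory with exact per-frame dwell ground truth."""

    frames: pd.DataFrame          # columns t, x, y (s, cm, cm)
    geometry: SocialArenaGeometry
    truth_social_s: float
    truth_object_s: float
    undefined: bool               # True when no frame falls in the object zone


def _sample_in_annulus(geo: SocialArenaGeometry, center, n, rng):
    r = np.sqrt(rng.uniform(geo.cylinder_radius_cm ** 2, geo.zone_outer_cm ** 2, n))
    th = rng.uniform(0.0, 2.0 * math.pi, n)
    return center[0] + r * np.cos(th), center[1] + r * np.sin(th)


def generate_track(spec: TrackSpec, rng: np.random.Generator) -> Track:
    """Simulate one session; dwell truth is exact per-frame membership.

    States form a sticky Markov chain whose jump distribution equals the
    normalized propensities, so stationary occupancy is proportional to
    the propensities.  Positions are sampled uniformly within the
    current zone annulus (or the remaining arena), so recomputing zone
    membership from (x, y) reproduces the state sequence exactly.
    """
    spec.validate()
    geo = spec.geometry
    n = int(round(spec.duration_s / spec.frame_interval_s))
    p = np.asarray(spec.propensities, dtype=float)
    p = p / p.sum()

    jump = rng.random(n) >= spec.persistence
    jump[0] = True
    targets = rng.choice(3, size=n, p=p)
    # state persists between jumps: forward-fill the last jump index
    idx = np.where(jump, np.arange(n), 0)
    np.maximum.accumulate(idx, out=idx)
    states = targets[idx]

    x = np.empty(n)
    y = np.empty(n)
    for s, center in ((0, geo.social_center_cm), (1, geo.object_center_cm)):
        m = states == s
        if m.any():
            x[m], y[m] = _sample_in_annulus(geo, center, int(m.sum()), rng)
    m = states == 2
    if m.any():
        k = int(m.sum())
        xs = np.empty(k)
        ys = np.empty(k)
        todo = np.arange(k)
        while todo.size:
            cx = rng.uniform(0.0, geo.arena_size_cm, todo.size)
            cy = rng.uniform(0.0, geo.arena_size_cm, todo.size)
            near_s = (cx - geo.social_center_cm[0]) ** 2 + (cy - geo.social_center_cm[1]) ** 2 <= geo.zone_outer_cm ** 2
            near_o = (cx - geo.object_center_cm[0]) ** 2 + (cy - geo.object_center_cm[1]) ** 2 <= geo.zone_outer_cm ** 2
            ok = ~(near_s | near_o)
            xs[todo[ok]] = cx[ok]
            ys[todo[ok]] = cy[ok]
            todo = todo[~ok]
        x[m] = xs
        y[m] = ys

    t = np.arange(n) * spec.frame_interval_s
    frames = pd.DataFrame({"t": t, "x": x, "y": y})
    in_social = geo.in_zone(x, y, "social")
    in_object = geo.in_zone(x, y, "object")
    social_s = float(in_social.sum()) * spec.frame_interval_s
    object_s = float(in_object.sum()) * spec.frame_interval_s
    return Track(frames, geo, social_s, object_s, undefined=object_s == 0.0)


# ---------------------------------------------------------------------------
# flow-cytometry events
# ---------------------------------------------------------------------------

@dataclass
class FlowPopulation:
    """One cell population: event count and log10 channel statistics."""

    name: str
    n_events: int
    channels: dict[str, tuple[float, float]]   # channel -> (mean, sd), log10 scale

    def validate(self, channel_names: Sequence[str]) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be ≥ 0")
        for ch in channel_names:
            if ch not in self.channels:
                raise ValueError(f"population {self.name!r} missing channel {ch!r}")
            if self.channels[ch][1] <= 0:
                raise ValueError(f"sd must be > 0 for {self.name}/{ch}")


def default_flow_populations(
    n_total: int = 10_000,
    macrophage_frac: float = 0.10,
) -> list[FlowPopulation]:
    """CD11b/CD45/CD68 mixture emulating a brain myeloid prep.

    Microglia are CD11b-hi CD45-lo; infiltrating macrophages CD11b-hi
    CD45-hi.  The CD45 means are 10 population sd apart, so a midpoint
    threshold gate essentially never misassigns an event.
    """
    n_mac = int(round(n_total * macrophage_frac))
    n_mic = n_total - n_mac
    return [
        FlowPopulation("microglia", n_mic,
                       {"CD11b": (3.0, 0.15), "CD45": (1.5, 0.15), "CD68": (1.3, 0.2)}),
        FlowPopulation("macrophage", n_mac,
                       {"CD11b": (3.0, 0.15), "CD45": (3.0, 0.15), "CD68": (2.2, 0.2)}),
    ]


def generate_flow_events(
    populations: Sequence[FlowPopulation],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Event table with per-event truth labels and exact truth fractions.

    Intensities are drawn log-normally (normal on log10 scale, exported
    linear).  Returns ``(events, truth_fractions)`` where the fractions
    are exact label counts over all events.
    """
    if not populations:
        raise ValueError("need at least one population")
    channel_names = sorted({ch for p in populations for ch in p.channels})
    for p in populations:
        p.validate(channel_names)
    frames = []
    for p in populations:
        cols = {
            ch: np.power(10.0, rng.normal(*p.channels[ch], size=p.n_events))
            for ch in channel_names
        }
        cols["truth_label"] = np.repeat(p.name, p.n_events)
        frames.append(pd.DataFrame(cols))
    events = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(events):
        # fixed permutation so event order does not encode the label
        events = events.iloc[rng.permutation(len(events))].reset_index(drop=True)
    total = max(len(events), 1)
    truth = {p.name: p.n_events / total if len(events) else 0.0 for p in populations}
    return events, truth
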