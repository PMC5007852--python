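# Methods

This note documents the models, algorithms and numerical choices behind
gliamorph, and what the synthetic validation does and does not show.

## Synthetic microglia fields

Each simulated field emulates a confocal acquisition of GFP-bright
microglia: a (z, y, x) stack of 10 optical sections 1 µm apart at
0.42 µm/pixel (512×512 by default).

**Cell model.** A cell is an elliptical soma (geometric-mean radius
`soma_radius_px`, axis ratio ≥ 1, random orientation) plus processes
grown from the soma boundary as thickness-tapered random walks (step
1 px, heading jitter sd 0.22 rad, radius tapering to ~0.8 px at the
tip) with recursive branching (`branch_prob` per branch point, depth
≤ `branch_depth`). Two presets bracket the biology:

* **resting** (ramified): soma radius 6 px, 5 primary processes of
  ~20 px, branch depth 2 — the surveillance morphology;
* **activated** (amoeboid): soma radius 7.8 px (1.3×, i.e. ~1.69× soma
  area), 2 short processes of ~8 px — the LPS-like morphology.

Continuous parameters get multiplicative log-normal jitter (CV 0.08)
per cell. Each cell's "true" six parameters are measured from its
noiseless mask with the same morphometry code used downstream, so
noiseless recovery is exact by construction and noisy recovery isolates
the effect of imaging and segmentation.

**Rendering.** Cells are placed with centre spacing ≥ 55 px and
strictly non-overlapping masks (bounded rejection sampling);
overlapping-cell segmentation is deliberately out of the truth regime.
A cell occupies its three nearest z-slices with Gaussian falloff
(σ = 0.8 slices) around a random home slice; slices attenuate by 1.5 %
per step in z. Soma pixels carry the full amplitude, process pixels
55 % of it. Noise is Poisson shot noise on the signal (gain 0.5, i.e.
two photons per intensity unit — chosen so shot noise at the soma is
comparable to the background sd, a realistic confocal photon budget)
plus additive Gaussian background (mean 40, sd 5). SNR is defined as
(peak noiseless soma intensity − background mean)/background sd;
default 8. Density (30 cells per 512×512 field) and SNR are fixture
choices, not literature facts.

**Other generators.** Phagocytosis scenes place disk-like cells and
particle blobs whose engulfed pixel count is driven to exactly
`round(f × cell area)`, so the truth fraction matches the request to
one pixel quantum. Flow events are log-normal channel mixtures with
per-event truth labels (microglia CD11b-hi/CD45-lo vs macrophage
CD11b-hi/CD45-hi, 10 population-sd apart on log10 CD45, so a midpoint
gate is error-free in practice). Scent-mark sheets rasterize blob marks
on a 46×46 cm arena with four 20-cm scoring circles, each tangent to
the two outer edges of its quadrant; truth preference is the exact
pixel share inside the target circle. Locomotion tracks use a sticky
three-state chain (social zone / object zone / elsewhere) whose jump
distribution equals the normalized dwell propensities, making
stationary occupancy proportional to them; positions are sampled inside
the corresponding zone annulus (2-cm investigation band around a 10-cm
cylinder whose wall stands 10 cm from two arena edges), so per-frame
membership recomputed from (x, y) reproduces the state sequence
exactly.

Everything is deterministic given (preset, seed); sub-seeds derive from
the top-level seed by CRC32 hashing of (seed, stage tokens).

## Segmentation

The pipeline is MIP → seeding → iterative-threshold growth → contested
pixel resolution → boundary refinement → QC → soma extraction.
Defaults live in `SegmentationParams`; fractions are relative to the
dynamic range of the σ = 2 px Gaussian-smoothed MIP.

* **Seeding:** h-maxima of the smoothed MIP with prominence 10 % of
  dynamic range; an equal-intensity plateau counts once, at the pixel
  nearest its centroid. Seeds closer than 25 px are suppressed keeping
  the brighter — branch junctions of ramified cells otherwise produce
  secondary maxima within ~15 px and split cells.
* **Growth:** per seed, the threshold starts at the seed peak and drops
  in 5 %-of-range steps; at each level the candidate mask is the
  connected component (8-connectivity) containing the seed. Iteration
  stops when the component floods into background: relative area growth
  per step above 3.0 (legitimate process-arm accretion steps reach
  ~1.6×; background flooding jumps ≥ 40×), area beyond twice the upper
  area bound, or contact with the 96-px working window edge. The
  growth-ratio test arms only once the component exceeds 30 px, because
  the first levels around a 1–2 px peak always multiply in area. A seed
  whose first level already floods (planted on background) yields an
  empty, flagged mask.
* **Contested pixels:** regions claimed by several seeds are split by
  geodesic distance (uniform cost within the claimed union) to the
  seeds; each mask then keeps the component containing its seed. This
  replaces a hard "stop when another seed would be absorbed" rule,
  which truncated faint arms of adjacent cells.
* **Boundary refinement:** growth on the σ = 2 image dilates boundaries
  by roughly the smoothing radius, so the final mask keeps pixels above
  background + 6.5 × noise-sd on a σ = 0.7-smoothed MIP (background =
  median; noise-sd from the dimmest 80 % of pixels), re-bridged by the
  skeleton of a background + 4 × noise-sd support so that a single weak
  pixel cannot sever a distal arm, then hole-filled. On effectively
  noiseless images (noise band < 5 % of the cell's peak contrast) the
  thresholds fall back to 35 %/20 % of peak contrast — a half-maximum
  style edge estimate.
* **QC:** reject empty masks, multi-component masks, masks containing
  more than one seed (multi-soma), areas outside [50, 5000] px², and
  masks touching a 2-px border margin; every rejection carries a reason
  code.
* **Soma:** the connected supra-threshold core around the seed at
  background + 0.5 × (seed peak − background). The half-height fraction
  recovers the edge of a smoothed intensity step at its true position;
  on dev scenes it gives ~3 % median soma-area error where a 0.6
  fraction gave ~18 %. An empty core falls back to the seed pixel and
  is flagged.

On the standard fixture (30 resting cells, SNR 8, seed-fixed) this
yields seed-detection F1 ≈ 0.94–0.97 and median mask IoU ≈ 0.73–0.80
versus generator truth across seeds; the thin, dim distal process arms
dominate the residual IoU gap.

## Morphometry

Areas are pixel counts; perimeter is the weighted boundary-step
estimator (isothetic steps weigh 1, diagonal √2, corners (1+√2)/2) —
naive pixel-edge counting overestimates perimeter and drags roundness
down badly. Eccentricity is the major/minor axis ratio of the
second-central-moment ellipse, reported ≥ 1 (an interpretation: the
usual verbal definitions of "eccentricity" for cells are not
self-consistent); a zero minor axis flags the record and excludes it
from statistics. Cell spread uses the standard 8-extremal-point
convention (two per cardinal side) around the unweighted centre of
mass. Roundness 4π·area/perimeter² is clipped to 1 only when
discretization overshoots the isoperimetric bound, with a flag. All
values are stored in both pixel and µm units; "cell area" is the mask
area, distinct from soma area.

## Group statistics

Normalization strata are (region × parameter): each value is divided by
the control-stratum mean and ×100, so the control mean is exactly
100 %; strata with an absent or zero-mean control are flagged and
excluded. The statistical unit for group tests is the field mean
(cells within a field are not independent). Inference is a textbook
one-way ANOVA followed by classical Bonferroni pairwise t tests using
the pooled MSE on the within-group df (not Welch), adjusted
p = min(1, m·p) over the m = k(k−1)/2 pairs; the six parameters are
tested independently with no cross-parameter correction.
`anova_from_summary` reconstructs group variances as n·SEM² to recover
F from printed summary tables; for balanced raw data it reproduces the
raw-data F exactly. Spearman correlation uses average ranks with the
t-approximation p-value and flags constant input as undefined.

## What the synthetic validation shows — and does not

Passing tests show the *pipeline* is correct and well calibrated: exact
agreement with brute-force oracles, exact assay recovery at the
count level, control-mean 100 % normalization, type-I error at nominal
α, and recovery of a known activation contrast (roundness and soma area
up, perimeter down) with a clean null between same-regime groups. They
do not certify performance on real tissue: the generator has no
optics-accurate PSF, no photobleaching, no anisotropic background
(vessels, autofluorescence), no touching or overlapping cells, and its
process architecture is a random walk rather than real microglial
arborization. Direction-of-effect and calibration results are the
transferable claims; absolute IoU/F1 values are generator-specific.

## Problem sizes and determinism

Default study sizes (kept modest by design): 30 cells per 512×512×10
field; 6 fields per group and 4 groups for the direction-of-effect
study; 500 simulations for null calibration; 100 scenes per assay for
exact-recovery checks; 200 cells for oracle equivalence. Stochastic
checks (type-I rate inside the exact 95 % binomial CI; absence of
same-regime false positives at Bonferroni level) fail for an honest
~5–10 % of seeds by construction; seeds in the test suite are fixed via
a CRC32 derivation from a single base seed.

## Known limitations

* 2D only: truth and analysis live at the projection level; no 3D
  segmentation, deconvolution, tracking, skeletonization or Sholl
  analysis.
* The iterative-threshold stopping rule is a reconstruction; the
  original routine it emulates is not publicly specified.
* Soma-area recovery is calibrated for smoothed-step edges; very dim
  cells (SNR ≲ 4) will bias soma and cell areas low.
* Flow gating is rectangular thresholding with truth-label pre-filters
  standing in for scatter/DAPI/doublet gates; no compensation or gate
  learning.
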