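"""Recovery metrics against synthetic ground truth.

Used by the test suite and the acceptance script to score how well
seeding and segmentation recover the generator's known cells: greedy
distance matching of detected seeds to true centroids (match radius =
each cell's true soma-equivalent radius, with a floor), detection
precision/recall/F1, and per-cell mask intersection-over-union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DetectionScore:
    n_truth: int
    n_detected: int
    n_matched: int
    matches: list  # (truth_label, seed_index, distance)

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def match_seeds_to_truth(
    seeds,
    truth_params: pd.DataFrame,
    radius_floor_px: float = 5.0,
) -> DetectionScore:
    """Greedy one-to-one matching of seeds to true cell centroids.

    Candidate pairs within each cell's match radius (its true
    soma-equivalent radius, floored at ``radius_floor_px``) are accepted
    in order of increasing distance, each seed and each truth cell used
    at most once.
    """
    coords = np.array([(s.y, s.x) for s in seeds], dtype=float).reshape(-1, 2)
    n_truth = len(truth_params)
    if n_truth == 0 or coords.shape[0] == 0:
        return DetectionScore(n_truth, coords.shape[0], 0, [])
    ty = truth_params["cy"].to_numpy(dtype=float)
    tx = truth_params["cx"].to_numpy(dtype=float)
    radius = np.maximum(
        truth_params["soma_equiv_radius_px"].to_numpy(dtype=float), radius_floor_px
    )
    d = np.hypot(ty[:, None] - coords[None, :, 0], tx[:, None] - coords[None, :, 1])
    pairs = [
        (d[i, j], i, j)
        for i in range(n_truth)
        for j in range(coords.shape[0])
        if d[i, j] <= radius[i]
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_s: set[int] = set()
    matches = []
    for dist, i, j in pairs:
        if i in used_t or j in used_s:
            continue
        used_t.add(i)
        used_s.add(j)
        matches.append((int(truth_params["label"].iloc[i]), j, float(dist)))
    return DetectionScore(n_truth, coords.shape[0], len(matches), matches)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int((a | b).sum())
    if union == 0:
        return 0.0
    return int((a & b).sum()) / union


def matched_mask_ious(
    cells,
    truth_labels: np.ndarray,
    truth_params: pd.DataFrame,
    radius_floor_px: float = 5.0,
) -> list[float]:
    """IoU of each matched (truth cell, segmented mask) pair.

    Matching reuses :func:`match_seeds_to_truth` on the cells' seeds, so
    a truth cell missed by seeding simply contributes no IoU entry.
    """
    score = match_seeds_to_truth([c.seed for c in cells], truth_params,
                                 radius_floor_px)
    ious = []
    for truth_label, cell_idx, _dist in score.matches:
        ious.append(mask_iou(truth_labels == truth_label, cells[cell_idx].mask))
    return ious
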