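"""Independent brute-force oracles used by the tests.

Every function here recomputes a quantity with naive pixel/event loops
and shares no code with the package implementation, so agreement is
evidence of correctness rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


def pixel_area(mask) -> float:
    n = 0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                n += 1
    return float(n)


def _is_border(mask, y, x) -> bool:
    # border pixel: foreground with at least one 4-neighbour background
    if not mask[y, x]:
        return False
    h, w = mask.shape
    for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        yy, xx = y + dy, x + dx
        if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
            return True
    return False


def weighted_perimeter(mask) -> float:
    """Weighted boundary-step perimeter, re-derived with explicit loops.

    Border pixels are classified by how many of their 4-neighbours and
    diagonal neighbours are also border pixels; isothetic steps weigh 1,
    diagonal steps sqrt(2), corner configurations (1+sqrt(2))/2.
    """
    h, w = mask.shape
    border = [[_is_border(mask, y, x) for x in range(w)] for y in range(h)]
    weights = {}
    for code in (5, 7, 15, 17, 25, 27):
        weights[code] = 1.0
    for code in (21, 33):
        weights[code] = math.sqrt(2.0)
    for code in (13, 23):
        weights[code] = (1.0 + math.sqrt(2.0)) / 2.0
    total = 0.0
    for y in range(h):
        for x in range(w):
            if not border[y][x]:
                continue
            n4 = 0
            nd = 0
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and border[yy][xx]:
                    n4 += 1
            for dy, dx in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and border[yy][xx]:
                    nd += 1
            total += weights.get(1 + 2 * n4 + 10 * nd, 0.0)
    return total


def centroid(mask) -> tuple[float, float]:
    sy = sx = n = 0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                sy += y
                sx += x
                n += 1
    return sy / n, sx / n


def spread(mask) -> float:
    """Mean distance from the centroid to the 8 independently located extrema."""
    h, w = mask.shape
    pts = [(y, x) for y in range(h) for x in range(w) if mask[y, x]]
    ys = [p[0] for p in pts]
    xs = [p[1] for p in pts]
    top, bottom = min(ys), max(ys)
    left, right = min(xs), max(xs)
    top_cols = [x for y, x in pts if y == top]
    bottom_cols = [x for y, x in pts if y == bottom]
    left_rows = [y for y, x in pts if x == left]
    right_rows = [y for y, x in pts if x == right]
    extrema = [
        (top, min(top_cols)),
        (top, max(top_cols)),
        (min(right_rows), right),
        (max(right_rows), right),
        (bottom, max(bottom_cols)),
        (bottom, min(bottom_cols)),
        (max(left_rows), left),
        (min(left_rows), left),
    ]
    cy, cx = centroid(mask)
    return sum(math.hypot(y - cy, x - cx) for y, x in extrema) / 8.0


def eccentricity(mask) -> float:
    """Axis ratio from second central moments, computed by loops."""
    cy, cx = centroid(mask)
    mu20 = mu02 = mu11 = 0.0
    n = 0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                mu20 += (y - cy) ** 2
                mu02 += (x - cx) ** 2
                mu11 += (y - cy) * (x - cx)
                n += 1
    if n == 1:
        return 1.0
    mu20 /= n
    mu02 /= n
    mu11 /= n
    common = math.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11 ** 2)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    if lam2 <= 0.0:
        return math.inf
    return math.sqrt(lam1 / lam2)


def roundness(area: float, perimeter: float) -> float:
    return 4.0 * math.pi * area / perimeter ** 2


def six_parameters(cell_mask, soma_mask) -> dict:
    """All six morphometric parameters in pixel units, by brute force."""
    area = pixel_area(cell_mask)
    perim = weighted_perimeter(cell_mask)
    return {
        "cell_area_px": area,
        "soma_area_px": pixel_area(soma_mask),
        "cell_spread_px": spread(cell_mask),
        "perimeter_px": perim,
        "eccentricity": eccentricity(cell_mask),
        "roundness": min(roundness(area, perim), 1.0),
    }


def rank_with_ties(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Pearson correlation of average ranks, by loops."""
    rx = rank_with_ties(list(x))
    ry = rank_with_ties(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    return sxy / math.sqrt(sxx * syy)


def anova_f(groups) -> float:
    """Direct sum-of-squares F statistic."""
    allv = [v for g in groups for v in g]
    grand = sum(allv) / len(allv)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)
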