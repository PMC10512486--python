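"""Independent brute-force oracles used to check the implementation.

Everything here is written as plainly as possible (explicit loops, BFS,
exhaustive search) and deliberately shares no code with the package
internals beyond the documented conventions (8-connectivity; structuring
element = offsets with dr^2 + dc^2 <= r*(r+1); 4-neighbour exposed-edge
perimeter).
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np

NEIGHBORS8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
              if (dr, dc) != (0, 0)]


def flood_fill_label(mask: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """8-connected components by BFS; returns labels (raster order) and areas."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    areas = []
    next_label = 0
    for r, c in product(range(mask.shape[0]), range(mask.shape[1])):
        if not mask[r, c] or labels[r, c]:
            continue
        next_label += 1
        queue = deque([(r, c)])
        labels[r, c] = next_label
        area = 0
        while queue:
            cr, cc = queue.popleft()
            area += 1
            for dr, dc in NEIGHBORS8:
                nr, nc = cr + dr, cc + dc
                if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                        and mask[nr, nc] and not labels[nr, nc]):
                    labels[nr, nc] = next_label
                    queue.append((nr, nc))
        areas.append(area)
    return labels, areas


def element_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * (radius + 1)
    ]


def brute_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    offs = element_offsets(radius)
    for r, c in zip(*np.nonzero(mask)):
        for dr, dc in offs:
            nr, nc = r + dr, c + dc
            if 0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]:
                out[nr, nc] = True
    return out


def brute_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    offs = element_offsets(radius)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            ok = True
            for dr, dc in offs:
                nr, nc = r + dr, c + dc
                if not (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                        and mask[nr, nc]):
                    ok = False
                    break
            out[r, c] = ok
    return out


def brute_opening(mask: np.ndarray, radius: int) -> np.ndarray:
    return brute_dilate(brute_erode(mask, radius), radius)


def brute_perimeter(mask: np.ndarray) -> int:
    """Exposed 4-neighbour pixel edges, counted one pixel side at a time."""
    mask = np.asarray(mask, dtype=bool)
    total = 0
    for r, c in zip(*np.nonzero(mask)):
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if not (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                    and mask[nr, nc]):
                total += 1
    return total


def local_maxima_count(values: np.ndarray, mask: np.ndarray,
                       min_distance: int) -> int:
    """Greedy count of strict-or-plateau local maxima separated by min_distance.

    Candidates are mask pixels not smaller than any 8-neighbour; they are
    accepted in decreasing-value order if no previously accepted peak lies
    within Euclidean ``min_distance``. Mirrors the seed-selection contract
    used for watershed splitting.
    """
    values = np.asarray(values, dtype=float)
    cands = []
    for r, c in zip(*np.nonzero(mask)):
        v = values[r, c]
        is_max = True
        for dr, dc in NEIGHBORS8:
            nr, nc = r + dr, c + dc
            if (0 <= nr < values.shape[0] and 0 <= nc < values.shape[1]
                    and values[nr, nc] > v):
                is_max = False
                break
        if is_max:
            cands.append((v, r, c))
    cands.sort(reverse=True)
    accepted: list[tuple[int, int]] = []
    for v, r, c in cands:
        if all((r - ar) ** 2 + (c - ac) ** 2 > min_distance**2
               for ar, ac in accepted):
            accepted.append((r, c))
    return len(accepted)


def nearest_seed_partition(mask: np.ndarray, seed_labels: np.ndarray
                           ) -> np.ndarray:
    """Assign each foreground pixel to the label of its nearest seed pixel."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=int)
    seeds = [(r, c, int(seed_labels[r, c])) for r, c in
             zip(*np.nonzero(seed_labels))]
    for r, c in zip(*np.nonzero(mask)):
        best, best_d = 0, None
        for sr, sc, label in seeds:
            d = (r - sr) ** 2 + (c - sc) ** 2
            if best_d is None or d < best_d:
                best, best_d = label, d
        out[r, c] = best
    return out


def otsu_exhaustive(values: np.ndarray) -> float:
    """Threshold minimizing intra-class variance over all candidate splits."""
    v = np.sort(np.asarray(values, dtype=float))
    best_score, best_thr = None, None
    for i in range(len(v) - 1):
        if v[i] == v[i + 1]:
            continue
        thr = 0.5 * (v[i] + v[i + 1])
        lo, hi = v[v <= thr], v[v > thr]
        score = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best_score is None or score < best_score:
            best_score, best_thr = score, thr
    if best_thr is None:
        raise ValueError("no valid split")
    return best_thr


def bh_stepup(pvalues) -> np.ndarray:
    """Naive Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = q_sorted
    return out


def anova_ss(values, factor_a, factor_b):
    """Direct sums-of-squares two-way ANOVA F statistics (balanced designs)."""
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    levels_a, levels_b = np.unique(a), np.unique(b)
    n = len(y) / (len(levels_a) * len(levels_b))
    grand = y.mean()
    ss_a = sum(
        (y[a == la].size) * (y[a == la].mean() - grand) ** 2 for la in levels_a
    )
    ss_b = sum(
        (y[b == lb].size) * (y[b == lb].mean() - grand) ** 2 for lb in levels_b
    )
    ss_cells = 0.0
    ss_resid = 0.0
    for la in levels_a:
        for lb in levels_b:
            cell = y[(a == la) & (b == lb)]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
            ss_resid += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a, df_b = len(levels_a) - 1, len(levels_b) - 1
    df_ab = df_a * df_b
    df_resid = len(y) - len(levels_a) * len(levels_b)
    ms_resid = ss_resid / df_resid
    return (
        ss_a / df_a / ms_resid,
        ss_b / df_b / ms_resid,
        max(ss_ab, 0.0) / df_ab / ms_resid,
    )


def simplex_grid_search(S: np.ndarray, b: np.ndarray, resolution: float = 0.01
                        ) -> np.ndarray:
    """Exhaustive search over the proportion simplex minimizing ||S p - b||.

    Only practical for 3 cell types at resolution 0.01 (~5k candidates).
    """
    steps = int(round(1.0 / resolution))
    best, best_err = None, None
    for i in range(steps + 1):
        for j in range(steps + 1 - i):
            k = steps - i - j
            p = np.array([i, j, k], dtype=float) / steps
            err = np.linalg.norm(S @ p - b)
            if best_err is None or err < best_err:
                best, best_err = p, err
    return best
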