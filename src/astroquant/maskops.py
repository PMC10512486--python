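"""Low-level binary-mask primitives shared by the imaging modules.

All morphology in this package uses a single structuring-element convention:
``footprint(r)`` is the set of integer offsets ``(dr, dc)`` with
``dr**2 + dc**2 <= r*(r + 1)`` — a Euclidean disk inflated by half a pixel.
For ``r = 1`` this is the full 3x3 square (the 8-neighbourhood), which keeps
dilation consistent with the 8-connectivity used for connected components.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "footprint",
    "dilate",
    "erode",
    "binary_opening",
    "exposed_edge_perimeter",
    "relabel_sequential_pair",
    "otsu_threshold_exact",
]


def footprint(radius: int) -> np.ndarray:
    """Half-pixel-inflated disk structuring element of the given radius.

    Offsets (dr, dc) are included iff dr^2 + dc^2 <= radius*(radius+1).
    radius 0 is the single-pixel element; radius 1 the 3x3 square.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr * dr + dc * dc) <= r * (r + 1)


def dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius == 0:
        return mask.astype(bool).copy()
    return ndi.binary_dilation(mask, structure=footprint(radius))


def erode(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius == 0:
        return mask.astype(bool).copy()
    return ndi.binary_erosion(mask, structure=footprint(radius))


def binary_opening(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion followed by dilation with the package structuring element."""
    if radius == 0:
        return mask.astype(bool).copy()
    return dilate(erode(mask, radius), radius)


def exposed_edge_perimeter(mask: np.ndarray) -> int:
    """Count exposed pixel edges of a binary mask (4-neighbour convention).

    Each foreground pixel contributes one unit per side (up/down/left/right)
    not shared with another foreground pixel; image borders count as exposed.
    A solid 10x10 square therefore has perimeter 40.
    """
    m = np.asarray(mask, dtype=bool)
    area = int(m.sum())
    if area == 0:
        return 0
    horiz = int((m[:, :-1] & m[:, 1:]).sum())
    vert = int((m[:-1, :] & m[1:, :]).sum())
    return 4 * area - 2 * (horiz + vert)


def relabel_sequential_pair(
    cells: np.ndarray, nuclei: np.ndarray, keep: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Keep only the listed labels in both maps and relabel them 1..n.

    ``keep`` holds the (sorted or unsorted) label values to retain; the same
    old->new mapping is applied to both maps so the cell/nucleus pairing by
    equal label value is preserved.
    """
    keep = np.asarray(sorted(int(k) for k in keep), dtype=np.int64)
    lut = np.zeros(max(int(cells.max()), int(nuclei.max()), 1) + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return lut[cells], lut[nuclei]


def otsu_threshold_exact(values: np.ndarray) -> float:
    """Exact Otsu threshold over a 1-D sample (no histogram binning).

    Minimizes the weighted intra-class variance over every split between
    consecutive distinct sorted values; returns the midpoint of the best
    split boundary. Requires at least two distinct values.
    """
    v = np.sort(np.asarray(values, dtype=float))
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("Otsu threshold undefined: fewer than 2 distinct values")
    n = v.size
    best = (np.inf, 0.0)
    csum = np.cumsum(v)
    csum2 = np.cumsum(v * v)
    # split after index i: low = v[:i+1], high = v[i+1:]
    for i in range(n - 1):
        if v[i] == v[i + 1]:
            continue
        n_lo = i + 1
        n_hi = n - n_lo
        ss_lo = csum2[i] - csum[i] ** 2 / n_lo
        s_hi = csum[-1] - csum[i]
        ss_hi = (csum2[-1] - csum2[i]) - s_hi**2 / n_hi
        within = ss_lo + ss_hi
        if within < best[0]:
            best = (within, 0.5 * (v[i] + v[i + 1]))
    return best[1]
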