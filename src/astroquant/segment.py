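"""Nucleus- and cell-level segmentation for high-content astrocyte fields.

The pipeline is deliberately parameter-light and threshold-based: Gaussian
smoothing, global thresholding (Otsu or fixed), watershed on the distance
transform to split touching nuclei, and a nucleus-seeded watershed on the
inverted marker channel to partition cytoplasmic territory. 8-connectivity
is used for components and structuring elements throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .maskops import dilate, relabel_sequential_pair

__all__ = [
    "SegmentationParams",
    "segment_nuclei",
    "segment_cells",
    "perinuclear_zones",
    "filter_border_cells",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs for nucleus/cell segmentation.

    ``threshold_mode`` is "otsu" (global Otsu on the smoothed image) or
    "fixed" (use ``fixed_threshold``, required in that mode and only then).
    ``min_peak_distance_px`` sets the minimum separation of distance-
    transform maxima used as watershed seeds when splitting touching nuclei.
    """

    smoothing_sigma_px: float = 2.0
    threshold_mode: str = "otsu"
    fixed_threshold: Optional[float] = None
    min_nucleus_area_px: int = 30
    min_cell_area_px: int = 100
    ring_width_px: int = 5
    exclude_border: bool = True
    min_peak_distance_px: int = 5

    def __post_init__(self) -> None:
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be >= 0")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if (self.threshold_mode == "fixed") != (self.fixed_threshold is not None):
            raise ValueError("fixed_threshold is required iff threshold_mode='fixed'")
        for name in ("min_nucleus_area_px", "min_cell_area_px", "ring_width_px"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.min_peak_distance_px < 1:
            raise ValueError("min_peak_distance_px must be >= 1")


def _smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if sigma > 0:
        img = gaussian(img, sigma=sigma, preserve_range=True)
    return img


def _threshold(img: np.ndarray, params: SegmentationParams) -> Optional[float]:
    """Threshold of the smoothed image, or None if undefined (flat image)."""
    if params.threshold_mode == "fixed":
        return float(params.fixed_threshold)
    if img.min() == img.max():
        return None
    return float(threshold_otsu(img))


def segment_nuclei(nuclei: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Label nuclei: smooth, threshold, split touching nuclei by watershed.

    The watershed runs on the negated Euclidean distance transform, seeded
    at its local maxima (separated by ``min_peak_distance_px``). Components
    smaller than ``min_nucleus_area_px`` are dropped; survivors are
    relabelled 1..n in raster order. A constant image under Otsu yields an
    empty label map, not an error.
    """
    nuclei = np.asarray(nuclei, dtype=float)
    if nuclei.size == 0:
        raise ValueError("empty image")
    img = _smooth(nuclei, params.smoothing_sigma_px)
    thr = _threshold(img, params)
    labels = np.zeros(nuclei.shape, dtype=np.int32)
    if thr is None:
        return labels
    mask = img > thr
    if not mask.any():
        return labels

    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        min_distance=params.min_peak_distance_px,
        labels=ndi.label(mask, structure=np.ones((3, 3)))[0],
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers=markers, mask=mask, connectivity=2)

    # drop undersized nuclei and relabel 1..n
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= params.min_nucleus_area_px)
    keep = keep[keep > 0]
    lut = np.zeros(sizes.size, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return lut[labels]


def segment_cells(
    marker: np.ndarray, nuclei_labels: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Partition marker-positive territory among nuclei by seeded watershed.

    Foreground is the smoothed marker above threshold, unioned with the
    nucleus supports; it is partitioned by a watershed on the inverted
    smoothed marker seeded at the nuclei. Foreground components containing
    no nucleus are discarded, as are cells below ``min_cell_area_px``
    (together with their nuclei). Returns ``(cell_labels, nuclei_labels)``
    relabelled consistently so each cell and its nucleus share a label.
    """
    marker = np.asarray(marker, dtype=float)
    nuclei_labels = np.asarray(nuclei_labels)
    if marker.shape != nuclei_labels.shape:
        raise ValueError("marker and nuclei_labels shapes differ")
    if nuclei_labels.max() == 0:
        z = np.zeros(marker.shape, dtype=np.int32)
        return z, z.copy()

    img = _smooth(marker, params.smoothing_sigma_px)
    thr = _threshold(img, params)
    fg = (img > thr) if thr is not None else np.zeros(marker.shape, dtype=bool)
    fg |= nuclei_labels > 0
    cells = watershed(-img, markers=nuclei_labels.astype(np.int32), mask=fg,
                      connectivity=2)

    sizes = np.bincount(cells.ravel())
    keep = np.flatnonzero(sizes >= params.min_cell_area_px)
    keep = keep[keep > 0]
    return relabel_sequential_pair(cells, nuclei_labels.astype(np.int32), keep)


def perinuclear_zones(
    nuclei_labels: np.ndarray, cell_labels: np.ndarray, ring_width_px: int
) -> np.ndarray:
    """Annular perinuclear zone per cell, clipped to the cell's own support.

    zone(l) = (nucleus l dilated by ``ring_width_px``) minus the nucleus,
    intersected with cell l; the zone carries the cell label. Nuclei and
    cells must be label-paired (equal values); a nucleus without a matching
    cell raises an error naming the label.
    """
    if ring_width_px < 1:
        raise ValueError("ring_width_px must be >= 1")
    nuclei_labels = np.asarray(nuclei_labels)
    cell_labels = np.asarray(cell_labels)
    if nuclei_labels.shape != cell_labels.shape:
        raise ValueError("label maps must share a shape")

    zones = np.zeros(nuclei_labels.shape, dtype=np.int32)
    objects = ndi.find_objects(nuclei_labels)
    cell_values = set(np.unique(cell_labels).tolist())
    pad = ring_width_px
    for label, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        if label not in cell_values:
            raise ValueError(f"nucleus {label} has no matching cell label")
        rsl = (
            slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, zones.shape[0])),
            slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, zones.shape[1])),
        )
        nuc = nuclei_labels[rsl] == label
        ring = dilate(nuc, ring_width_px) & ~nuc & (cell_labels[rsl] == label)
        zones[rsl][ring] = label
    return zones


def filter_border_cells(
    cell_labels: np.ndarray, nuclei_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop cells touching the field border (with their nuclei); relabel 1..n."""
    cell_labels = np.asarray(cell_labels)
    nuclei_labels = np.asarray(nuclei_labels)
    if cell_labels.shape != nuclei_labels.shape:
        raise ValueError("label maps must share a shape")
    border = np.unique(
        np.concatenate(
            [cell_labels[0], cell_labels[-1], cell_labels[:, 0], cell_labels[:, -1]]
        )
    )
    border = set(border[border > 0].tolist())
    present = np.unique(cell_labels)
    keep = [int(l) for l in present if l > 0 and l not in border]
    return relabel_sequential_pair(
        cell_labels.astype(np.int32), nuclei_labels.astype(np.int32), keep
    )
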