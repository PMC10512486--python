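"""Per-cell and per-field astrocyte morphometrics.

Implements the single-cell readouts used to contrast astrocyte
differentiation protocols: soma/process decomposition by morphological
opening, pixel-count areas, an exposed-edge process perimeter, perinuclear
GFAP mean (the per-cell quantity behind GFAP+ calling), whole-cell Vimentin
mean, and field-level summed-ratio summaries:

    soma_to_cell            = sum(soma area)    / sum(cell area)
    process_to_soma         = sum(process area) / sum(soma area)
    process_to_cell         = sum(process area) / sum(cell area)
    process_perimeter_to_cell = sum(process perimeter) / sum(cell area)

By default the morphology sums run over GFAP+ cells only, while the GFAP+
fraction counts all cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .maskops import binary_opening, dilate, exposed_edge_perimeter, otsu_threshold_exact
from .types import ChannelStack

__all__ = [
    "CellRecord",
    "FieldSummary",
    "EmptyPerinuclearZoneError",
    "decompose_soma_processes",
    "measure_cell",
    "classify_gfap_positive",
    "summarize_field",
]

log = logging.getLogger(__name__)

DEFAULT_OPENING_RADIUS_PX = 8


class EmptyPerinuclearZoneError(ValueError):
    """The perinuclear zone of a cell is empty, its GFAP mean undefined."""


@dataclass(frozen=True)
class CellRecord:
    """Measured features of one segmented cell (areas in pixels)."""

    cell_id: int
    nucleus_centroid: tuple[float, float]
    cell_area_px: int
    soma_area_px: int
    process_area_px: int
    process_perimeter_px: int
    perinuclear_gfap_mean: float
    vimentin_mean: Optional[float] = None
    gfap_positive: Optional[bool] = None


@dataclass(frozen=True)
class FieldSummary:
    """Field-level summary built from summed per-cell quantities."""

    n_cells: int
    gfap_positive_fraction: float
    soma_to_cell: float
    process_to_soma: float
    process_to_cell: float
    process_perimeter_to_cell: float


def decompose_soma_processes(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    opening_radius_px: int = DEFAULT_OPENING_RADIUS_PX,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a cell mask into soma and processes by morphological opening.

    The candidate soma is the opening of the cell mask with a disk of
    ``opening_radius_px``, restricted to the 8-connected component holding
    (or nearest to) the nucleus centroid. If the opening is empty (a cell
    thinner than the element everywhere) the soma falls back to the nucleus
    dilated by 2 px within the cell. Processes are the remainder.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    nucleus = np.asarray(nucleus_mask, dtype=bool)
    if opening_radius_px < 1:
        raise ValueError("opening_radius_px must be >= 1")
    if not cell.any():
        raise ValueError("empty cell mask")
    if (nucleus & ~cell).any():
        raise ValueError("nucleus extends outside the cell mask")

    opened = binary_opening(cell, opening_radius_px)
    if not opened.any():
        soma = dilate(nucleus, 2) & cell
    else:
        comp, n_comp = ndi.label(opened, structure=np.ones((3, 3)))
        if n_comp == 1:
            soma = opened
        else:
            centroid = ndi.center_of_mass(nucleus)
            cr, cc = (int(round(centroid[0])), int(round(centroid[1])))
            cr = min(max(cr, 0), cell.shape[0] - 1)
            cc = min(max(cc, 0), cell.shape[1] - 1)
            if comp[cr, cc] > 0:
                soma = comp == comp[cr, cc]
            else:
                # nearest component to the centroid, by EDT feature transform
                idx = ndi.distance_transform_edt(
                    comp == 0, return_distances=False, return_indices=True
                )
                soma = comp == comp[idx[0][cr, cc], idx[1][cr, cc]]
    process = cell & ~soma
    return soma, process


def measure_cell(
    cell_id: int,
    cell_mask: np.ndarray,
    soma_mask: np.ndarray,
    process_mask: np.ndarray,
    perinuclear_mask: np.ndarray,
    channels: ChannelStack,
    nucleus_centroid: Optional[tuple[float, float]] = None,
) -> CellRecord:
    """Measure one cell's areas, process perimeter and channel intensities.

    Raises ``EmptyPerinuclearZoneError`` if the perinuclear zone has no
    pixels (the perinuclear GFAP mean is then undefined and the caller is
    expected to log and drop the cell).
    """
    cell = np.asarray(cell_mask, dtype=bool)
    soma = np.asarray(soma_mask, dtype=bool)
    process = np.asarray(process_mask, dtype=bool)
    peri = np.asarray(perinuclear_mask, dtype=bool)
    if (soma & process).any() or not np.array_equal(soma | process, cell):
        raise ValueError("soma and process masks must partition the cell mask")
    if not peri.any():
        raise EmptyPerinuclearZoneError(
            f"cell {cell_id}: perinuclear zone is empty"
        )
    if nucleus_centroid is None:
        nucleus_centroid = tuple(float(x) for x in ndi.center_of_mass(soma))
    vim = (
        float(channels.vimentin[cell].mean())
        if channels.vimentin is not None
        else None
    )
    return CellRecord(
        cell_id=int(cell_id),
        nucleus_centroid=(float(nucleus_centroid[0]), float(nucleus_centroid[1])),
        cell_area_px=int(cell.sum()),
        soma_area_px=int(soma.sum()),
        process_area_px=int(process.sum()),
        process_perimeter_px=exposed_edge_perimeter(process),
        perinuclear_gfap_mean=float(channels.gfap[peri].mean()),
        vimentin_mean=vim,
    )


def classify_gfap_positive(
    records: Sequence[CellRecord],
    mode: str = "otsu",
    fixed_threshold: Optional[float] = None,
) -> tuple[list[CellRecord], float]:
    """Call each cell GFAP+ from its perinuclear GFAP mean.

    In ``fixed`` mode the supplied threshold is used directly. In ``otsu``
    mode an exact (unbinned) Otsu threshold is computed once over the
    pooled per-cell means of the whole batch — pass all fields of a
    condition together, not one field at a time. Returns the updated
    records and the threshold used; a cell is positive iff its mean
    exceeds the threshold.
    """
    if not records:
        raise ValueError("no cell records to classify")
    if mode not in ("fixed", "otsu"):
        raise ValueError(f"unknown mode {mode!r}")
    if (mode == "fixed") != (fixed_threshold is not None):
        raise ValueError("fixed_threshold is required iff mode='fixed'")
    means = np.array([r.perinuclear_gfap_mean for r in records], dtype=float)
    if mode == "fixed":
        thr = float(fixed_threshold)
    else:
        thr = otsu_threshold_exact(means)
    updated = [replace(r, gfap_positive=bool(m > thr)) for r, m in zip(records, means)]
    return updated, thr


def summarize_field(
    records: Sequence[CellRecord],
    gfap_positive_only_for_morphology: bool = True,
) -> FieldSummary:
    """Summed-ratio field summary over a list of classified cell records."""
    if not records:
        raise ValueError("cannot summarize a field with zero cells")
    if any(r.gfap_positive is None for r in records):
        raise ValueError("records must be classified before summarizing")
    n = len(records)
    n_pos = sum(1 for r in records if r.gfap_positive)
    morpho = (
        [r for r in records if r.gfap_positive]
        if gfap_positive_only_for_morphology
        else list(records)
    )
    if not morpho:
        raise ValueError("no GFAP+ cells to summarize morphology over")
    cell = sum(r.cell_area_px for r in morpho)
    soma = sum(r.soma_area_px for r in morpho)
    proc = sum(r.process_area_px for r in morpho)
    perim = sum(r.process_perimeter_px for r in morpho)
    if cell == 0 or soma == 0:
        raise ValueError("zero summed area; cannot form ratios")
    return FieldSummary(
        n_cells=n,
        gfap_positive_fraction=n_pos / n,
        soma_to_cell=soma / cell,
        process_to_soma=proc / soma,
        process_to_cell=proc / cell,
        process_perimeter_to_cell=perim / cell,
    )
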