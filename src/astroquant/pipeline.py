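"""End-to-end imaging analysis: channels in, per-cell and per-field tables out.

Ties the segmentation and morphometry stages together the way the readouts
are defined: nuclei are segmented from the Hoechst channel, cellular
territory from a marker channel (Vimentin when present — it stains mature
and immature astrocytes alike — else GFAP), the soma/process split is
computed per cell by morphological opening, the perinuclear GFAP mean is
measured per cell, and GFAP+ calling is done once over the pooled cells of
the whole batch before fields are summarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import morpho, segment
from .morpho import CellRecord, EmptyPerinuclearZoneError, FieldSummary
from .segment import SegmentationParams
from .types import ChannelStack

__all__ = ["FieldAnalysis", "analyze_field", "run_imaging", "records_to_frame",
           "summaries_to_frame"]

log = logging.getLogger(__name__)


@dataclass
class FieldAnalysis:
    """Unclassified per-cell records plus the label maps behind them."""

    records: list[CellRecord]
    cell_labels: np.ndarray
    nuclei_labels: np.ndarray
    perinuclear_labels: np.ndarray
    n_dropped: int = 0
    summary: Optional[FieldSummary] = field(default=None)


def _pick_marker(stack: ChannelStack, cell_marker: str) -> np.ndarray:
    if cell_marker == "auto":
        cell_marker = "vimentin" if stack.vimentin is not None else "gfap"
    if cell_marker == "vimentin":
        if stack.vimentin is None:
            raise ValueError("cell_marker='vimentin' but no Vimentin channel")
        return stack.vimentin
    if cell_marker == "gfap":
        return stack.gfap
    raise ValueError(f"unknown cell_marker {cell_marker!r}")


def analyze_field(
    stack: ChannelStack,
    params: SegmentationParams = SegmentationParams(),
    opening_radius_px: int = morpho.DEFAULT_OPENING_RADIUS_PX,
    cell_marker: str = "auto",
) -> FieldAnalysis:
    """Segment one field and measure every cell (GFAP calling deferred).

    Cells whose perinuclear zone comes out empty are logged and dropped;
    their count is reported in the result.
    """
    nuclei = segment.segment_nuclei(stack.nuclei, params)
    marker = _pick_marker(stack, cell_marker)
    cells, nuclei = segment.segment_cells(marker, nuclei, params)
    if params.exclude_border:
        cells, nuclei = segment.filter_border_cells(cells, nuclei)
    if cells.max() == 0:
        z = np.zeros(stack.shape, dtype=np.int32)
        return FieldAnalysis([], cells, nuclei, z)
    zones = segment.perinuclear_zones(nuclei, cells, params.ring_width_px)

    records: list[CellRecord] = []
    n_dropped = 0
    objects = ndi.find_objects(cells)
    pad = 2
    for label, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        rsl = (
            slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, cells.shape[0])),
            slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, cells.shape[1])),
        )
        cell_mask = cells[rsl] == label
        nucleus_mask = nuclei[rsl] == label
        peri_mask = zones[rsl] == label
        soma, process = morpho.decompose_soma_processes(
            cell_mask, nucleus_mask, opening_radius_px
        )
        crop = ChannelStack(
            nuclei=stack.nuclei[rsl],
            gfap=stack.gfap[rsl],
            vimentin=stack.vimentin[rsl] if stack.vimentin is not None else None,
        )
        cr, cc = ndi.center_of_mass(nucleus_mask)
        centroid = (cr + rsl[0].start, cc + rsl[1].start)
        try:
            records.append(
                morpho.measure_cell(
                    label, cell_mask, soma, process, peri_mask, crop,
                    nucleus_centroid=centroid,
                )
            )
        except EmptyPerinuclearZoneError as exc:
            log.warning("dropping cell: %s", exc)
            n_dropped += 1
    return FieldAnalysis(records, cells, nuclei, zones, n_dropped=n_dropped)


def run_imaging(
    stacks: Sequence[ChannelStack],
    params: SegmentationParams = SegmentationParams(),
    opening_radius_px: int = morpho.DEFAULT_OPENING_RADIUS_PX,
    cell_marker: str = "auto",
    gfap_mode: str = "otsu",
    gfap_fixed_threshold: Optional[float] = None,
    gfap_positive_only_for_morphology: bool = True,
    field_names: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Analyze a batch of fields of one condition.

    GFAP+ calling is performed once over the pooled per-cell perinuclear
    means of the whole batch (in ``otsu`` mode the threshold must be shared
    across fields of the condition). Returns the per-cell records table,
    the per-field summary table, and the GFAP threshold used.
    """
    if field_names is None:
        field_names = [f"field_{i:03d}" for i in range(len(stacks))]
    analyses = [
        analyze_field(s, params, opening_radius_px, cell_marker) for s in stacks
    ]
    pooled = [r for a in analyses for r in a.records]
    if not pooled:
        raise ValueError("no cells found in any field")
    classified, threshold = morpho.classify_gfap_positive(
        pooled, mode=gfap_mode, fixed_threshold=gfap_fixed_threshold
    )
    it = iter(classified)
    for a in analyses:
        a.records = [next(it) for _ in a.records]
        if a.records:
            a.summary = morpho.summarize_field(
                a.records,
                gfap_positive_only_for_morphology=gfap_positive_only_for_morphology,
            )
    records = records_to_frame(analyses, field_names)
    summaries = summaries_to_frame(analyses, field_names)
    return records, summaries, threshold


def records_to_frame(
    analyses: Sequence[FieldAnalysis], field_names: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for name, a in zip(field_names, analyses):
        for r in a.records:
            rows.append(
                dict(
                    field=name,
                    cell_id=r.cell_id,
                    nucleus_row=r.nucleus_centroid[0],
                    nucleus_col=r.nucleus_centroid[1],
                    cell_area_px=r.cell_area_px,
                    soma_area_px=r.soma_area_px,
                    process_area_px=r.process_area_px,
                    process_perimeter_px=r.process_perimeter_px,
                    perinuclear_gfap_mean=r.perinuclear_gfap_mean,
                    vimentin_mean=r.vimentin_mean,
                    gfap_positive=r.gfap_positive,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "field", "cell_id", "nucleus_row", "nucleus_col", "cell_area_px",
            "soma_area_px", "process_area_px", "process_perimeter_px",
            "perinuclear_gfap_mean", "vimentin_mean", "gfap_positive",
        ],
    )


def summaries_to_frame(
    analyses: Sequence[FieldAnalysis], field_names: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for name, a in zip(field_names, analyses):
        if a.summary is None:
            continue
        s = a.summary
        rows.append(
            dict(
                field=name,
                n_cells=s.n_cells,
                gfap_positive_fraction=s.gfap_positive_fraction,
                soma_to_cell=s.soma_to_cell,
                process_to_soma=s.process_to_soma,
                process_to_cell=s.process_to_cell,
                process_perimeter_to_cell=s.process_perimeter_to_cell,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "field", "n_cells", "gfap_positive_fraction", "soma_to_cell",
            "process_to_soma", "process_to_cell", "process_perimeter_to_cell",
        ],
    )
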