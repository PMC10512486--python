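"""Core in-memory containers for the imaging side of the pipeline.

Label maps are plain ``numpy`` integer arrays (0 = background, labels forming
a contiguous range ``1..n``), the convention used throughout ``scikit-image``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class ChannelStack:
    """Co-registered single-plane fluorescence channels for one field.

    nuclei is the Hoechst channel, gfap the astrocyte-marker channel and
    vimentin the optional immature-astrocyte marker. All grids share one
    shape and hold finite, non-negative intensities. ``pixel_size_um`` is
    carried as metadata only; features are reported in pixels.
    """

    nuclei: np.ndarray
    gfap: np.ndarray
    vimentin: Optional[np.ndarray] = None
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.nuclei = np.asarray(self.nuclei, dtype=float)
        self.gfap = np.asarray(self.gfap, dtype=float)
        if self.vimentin is not None:
            self.vimentin = np.asarray(self.vimentin, dtype=float)
        grids = [self.nuclei, self.gfap] + (
            [self.vimentin] if self.vimentin is not None else []
        )
        shapes = {g.shape for g in grids}
        if len(shapes) != 1 or self.nuclei.ndim != 2:
            raise ValueError("channels must be 2-D grids of identical shape")
        for name, g in zip(("nuclei", "gfap", "vimentin"), grids):
            if not np.all(np.isfinite(g)) or (g < 0).any():
                raise ValueError(f"channel {name!r} must be finite and >= 0")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei.shape


def validate_label_map(labels: np.ndarray) -> np.ndarray:
    """Check the label-map contract: non-negative ints, labels 1..max."""
    lab = np.asarray(labels)
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValueError("label map must be integer-valued")
    if (lab < 0).any():
        raise ValueError("label map must be non-negative")
    present = np.unique(lab)
    present = present[present > 0]
    if present.size and (present[-1] != present.size):
        raise ValueError("labels must form a contiguous range 1..n")
    return lab


@dataclass
class FieldTruth:
    """Ground truth for one synthetic field.

    The four label maps share the field shape; soma and process supports
    partition each cell; every nucleus label has exactly one cell label with
    the same value. ``cell_table`` holds one row per cell with the true
    pixel areas, the exposed-edge process perimeter and the GFAP class.
    """

    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    soma_labels: np.ndarray
    process_labels: np.ndarray
    cell_table: pd.DataFrame = field(repr=False, default=None)
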