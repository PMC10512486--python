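"""File-format bindings: single-plane TIFF channels/labels and CSV tables.

Channel TIFFs are written as 16-bit grayscale with the suffix convention
``_ch1`` (nuclei), ``_ch2`` (GFAP), ``_ch3`` (Vimentin); label maps as
32-bit integer TIFFs. Writes are deterministic (no datetime tags) so
identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .types import ChannelStack, FieldTruth

CHANNEL_SUFFIXES = {"nuclei": "_ch1", "gfap": "_ch2", "vimentin": "_ch3"}
TRUTH_SUFFIXES = {
    "nuclei_labels": "_truth_nuclei",
    "cell_labels": "_truth_cells",
    "soma_labels": "_truth_soma",
    "process_labels": "_truth_processes",
}


def write_channel_tiff(path: Path, image: np.ndarray) -> None:
    data = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 65535).astype(
        np.uint16
    )
    tifffile.imwrite(path, data, photometric="minisblack")


def write_label_tiff(path: Path, labels: np.ndarray) -> None:
    tifffile.imwrite(
        path, np.asarray(labels, dtype=np.int32), photometric="minisblack"
    )


def read_tiff(path: Path) -> np.ndarray:
    return tifffile.imread(path)


def save_field(
    prefix: Path, stack: ChannelStack, truth: Optional[FieldTruth] = None
) -> list[Path]:
    """Write one field's channels (and optional truth) next to ``prefix``.

    Returns the list of files written. ``prefix`` is a path without
    extension, e.g. ``out/field_000``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    channels = {"nuclei": stack.nuclei, "gfap": stack.gfap}
    if stack.vimentin is not None:
        channels["vimentin"] = stack.vimentin
    for name, image in channels.items():
        path = prefix.with_name(prefix.name + CHANNEL_SUFFIXES[name] + ".tif")
        write_channel_tiff(path, image)
        written.append(path)
    if truth is not None:
        for attr, suffix in TRUTH_SUFFIXES.items():
            path = prefix.with_name(prefix.name + suffix + ".tif")
            write_label_tiff(path, getattr(truth, attr))
            written.append(path)
        csv_path = prefix.with_name(prefix.name + "_truth_cells.csv")
        truth.cell_table.to_csv(csv_path, index=False)
        written.append(csv_path)
    return written


def load_field(prefix: Path) -> ChannelStack:
    """Read a field's channels back from the ``_ch1/_ch2[/_ch3]`` TIFFs."""
    prefix = Path(prefix)

    def chan(name: str) -> Path:
        return prefix.with_name(prefix.name + CHANNEL_SUFFIXES[name] + ".tif")

    nuclei = read_tiff(chan("nuclei")).astype(float)
    gfap = read_tiff(chan("gfap")).astype(float)
    vim_path = chan("vimentin")
    vimentin = read_tiff(vim_path).astype(float) if vim_path.exists() else None
    return ChannelStack(nuclei=nuclei, gfap=gfap, vimentin=vimentin)


def discover_fields(directory: Path) -> list[Path]:
    """Field prefixes in a directory, identified by their ``_ch1`` TIFFs."""
    directory = Path(directory)
    prefixes = []
    for path in sorted(directory.glob("*_ch1.tif")):
        prefixes.append(path.with_name(path.name[: -len("_ch1.tif")]))
    return prefixes


def read_matrix_csv(path: Path) -> pd.DataFrame:
    """Genes-in-rows matrix CSV/TSV (first column = gene identifiers)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_design_csv(path: Path) -> pd.DataFrame:
    """Sample design table indexed by its ``sample`` (or first) column."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    index_col = "sample" if "sample" in df.columns else df.columns[0]
    return df.set_index(index_col)
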