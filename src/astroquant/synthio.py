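"""Synthetic astrocyte fields and synthetic bulk mixtures with ground truth.

The generator emulates the two morphology classes the imaging pipeline is
meant to separate: *stellate* astrocytes (small soma, many long thin
processes — the prototypical mature morphology) and *flat* fibroblast-like
astrocytes (large soma, few short thick processes). Every cell is rendered
as an elliptical soma, a concentric nuclear disk and straight radial
processes; channels carry a uniform class intensity on the rendered support
plus additive Gaussian noise. The full pixel-level ground truth (label maps
and a per-cell table) is returned alongside the channels so every downstream
measurement can be checked against what was drawn.

All randomness flows from explicit integer seeds; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .maskops import dilate, exposed_edge_perimeter, footprint
from .types import ChannelStack, FieldTruth

__all__ = [
    "CellSpec",
    "MORPHOLOGY_PRESETS",
    "morphology_preset",
    "populate_field",
    "generate_field",
    "generate_bulk_mixtures",
]

NUCLEUS_RADIUS_FACTOR = 0.6  # nucleus disk radius = 0.6 * min(soma_radii)


@dataclass(frozen=True)
class CellSpec:
    """Geometry and intensity recipe for one rendered cell."""

    center: tuple[float, float]  # (row, col), pixels
    soma_radii: tuple[float, float]  # semi-axes (a, b) >= 2, pixels
    orientation: float = 0.0  # radians
    n_processes: int = 0
    process_length: float = 0.0  # pixels
    process_width: int = 1  # pixels, rendered as the nearest odd width
    gfap_class: str = "positive"  # {"positive", "negative"}
    gfap_mean: float = 8000.0
    vimentin_mean: float = 3000.0
    nucleus_mean: float = 10000.0

    def __post_init__(self) -> None:
        a, b = self.soma_radii
        if min(a, b) < 2:
            raise ValueError("soma_radii must both be >= 2")
        if self.n_processes < 0 or self.process_length < 0:
            raise ValueError("process count/length must be non-negative")
        if self.process_width < 1:
            raise ValueError("process_width must be >= 1")
        if self.process_width > min(a, b):
            raise ValueError("process_width must not exceed min(soma_radii)")
        if self.gfap_class not in ("positive", "negative"):
            raise ValueError(f"unknown gfap_class {self.gfap_class!r}")
        for name in ("gfap_mean", "vimentin_mean", "nucleus_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def reach(self) -> float:
        """Radius of the largest footprint this cell can occupy."""
        return max(self.soma_radii) + (
            self.process_length + self.process_width if self.n_processes else 0.0
        )


# Default class presets. Soma semi-axes are kept above the default soma
# opening radius (8 px) so morphological opening isolates the soma for both
# classes, while preserving the defining contrast: stellate cells have a
# smaller soma and more, longer, thinner processes than flat cells.
MORPHOLOGY_PRESETS: Dict[str, dict] = {
    "stellate": dict(
        soma_radii=(10.0, 12.0),
        n_processes=6,
        process_length=40.0,
        process_width=3,
    ),
    "flat": dict(
        soma_radii=(22.0, 26.0),
        n_processes=2,
        process_length=14.0,
        process_width=7,
    ),
}


def morphology_preset(
    class_name: str,
    seed: Optional[int] = None,
    *,
    center: tuple[float, float] = (0.0, 0.0),
    gfap_class: str = "positive",
) -> CellSpec:
    """A CellSpec drawn from the named class preset with mild seeded jitter.

    Jitter (orientation, +-1 px on soma semi-axes, +-10% process length)
    keeps within-class variety without ever crossing the between-class
    ordering of soma size, process number, length or width.
    """
    if class_name not in MORPHOLOGY_PRESETS:
        raise ValueError(
            f"unknown morphology class {class_name!r}; "
            f"expected one of {sorted(MORPHOLOGY_PRESETS)}"
        )
    base = MORPHOLOGY_PRESETS[class_name]
    rng = np.random.default_rng(seed)
    a, b = base["soma_radii"]
    spec = CellSpec(
        center=center,
        soma_radii=(a + rng.uniform(-1, 1), b + rng.uniform(-1, 1)),
        orientation=rng.uniform(0, math.pi),
        n_processes=base["n_processes"],
        process_length=base["process_length"] * rng.uniform(0.9, 1.1),
        process_width=base["process_width"],
        gfap_class=gfap_class,
    )
    return spec


def populate_field(
    n_per_class: Dict[str, int],
    shape: tuple[int, int] = (1024, 1024),
    *,
    gfap_positive_fraction: float = 1.0,
    margin: int = 4,
    seed: int = 0,
) -> list[CellSpec]:
    """Lay out preset cells on a jittered grid guaranteed collision-free.

    ``n_per_class`` maps class names to counts. Exactly
    ``round(gfap_positive_fraction * n_total)`` cells are flagged GFAP+,
    assigned uniformly at random across classes and positions.
    """
    if not 0.0 <= gfap_positive_fraction <= 1.0:
        raise ValueError("gfap_positive_fraction must lie in [0, 1]")
    n_total = sum(n_per_class.values())
    rng = np.random.default_rng(seed)

    # worst-case reach over requested classes, including preset jitter
    reach = 0.0
    for cls in n_per_class:
        base = MORPHOLOGY_PRESETS.get(cls)
        if base is None:
            raise ValueError(f"unknown morphology class {cls!r}")
        reach = max(
            reach,
            max(base["soma_radii"])
            + 1
            + base["process_length"] * 1.1
            + base["process_width"],
        )
    jitter = 3
    edge = int(math.ceil(reach)) + jitter + 2
    spacing = 2 * (int(math.ceil(reach)) + jitter) + margin + 2
    rows = np.arange(edge, shape[0] - edge + 1, spacing)
    cols = np.arange(edge, shape[1] - edge + 1, spacing)
    if rows.size * cols.size < n_total:
        raise ValueError(
            f"field {shape} fits only {rows.size * cols.size} cells of these "
            f"classes; {n_total} requested — use a larger field"
        )
    positions = [(float(r), float(c)) for r in rows for c in cols]
    rng.shuffle(positions)

    classes = [cls for cls, n in sorted(n_per_class.items()) for _ in range(n)]
    rng.shuffle(classes)
    n_pos = int(round(gfap_positive_fraction * n_total))
    gfap_flags = np.array(["positive"] * n_pos + ["negative"] * (n_total - n_pos))
    rng.shuffle(gfap_flags)

    specs = []
    for i, (cls, pos) in enumerate(zip(classes, positions)):
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = morphology_preset(cls, child_seed, gfap_class=str(gfap_flags[i]))
        dr, dc = rng.uniform(-jitter, jitter, size=2)
        specs.append(replace(spec, center=(pos[0] + dr, pos[1] + dc)))
    return specs


def _ellipse_mask(spec: CellSpec, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = skdraw.ellipse(
        spec.center[0],
        spec.center[1],
        spec.soma_radii[0],
        spec.soma_radii[1],
        rotation=spec.orientation,
    )
    if rr.size == 0:
        raise ValueError("soma renders to zero pixels")
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
        raise ValueError("soma extends outside field bounds")
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _nucleus_mask(spec: CellSpec, shape: tuple[int, int]) -> np.ndarray:
    radius = NUCLEUS_RADIUS_FACTOR * min(spec.soma_radii)
    rr, cc = skdraw.disk(spec.center, radius)
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
        raise ValueError("nucleus extends outside field bounds")
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _ellipse_radius(spec: CellSpec, theta: float) -> float:
    """Distance from center to the soma boundary along global direction theta."""
    a, b = spec.soma_radii
    phi = theta - spec.orientation
    du, dv = math.cos(phi), math.sin(phi)
    return 1.0 / math.sqrt((du / a) ** 2 + (dv / b) ** 2)


def _process_mask(
    spec: CellSpec, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Straight processes radiating from the soma boundary.

    Angles are spread evenly around the cell with a small seeded jitter;
    each process is a line of the requested length rooted just inside the
    soma boundary, thickened to the nearest odd width by dilation.
    """
    mask = np.zeros(shape, dtype=bool)
    if spec.n_processes == 0 or spec.process_length <= 0:
        return mask
    half_width = (spec.process_width - 1) // 2
    n = spec.n_processes
    base_angles = spec.orientation + 2 * math.pi * np.arange(n) / n
    jitters = rng.uniform(-math.pi / (3 * n), math.pi / (3 * n), size=n)
    line = np.zeros(shape, dtype=bool)
    for theta in base_angles + jitters:
        rho = _ellipse_radius(spec, theta)
        dr, dc = math.sin(theta), math.cos(theta)
        r0 = spec.center[0] + 0.8 * rho * dr
        c0 = spec.center[1] + 0.8 * rho * dc
        r1 = spec.center[0] + (rho + spec.process_length) * dr
        c1 = spec.center[1] + (rho + spec.process_length) * dc
        rr, cc = skdraw.line(
            int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1))
        )
        lo = half_width
        if (
            rr.min() < lo
            or cc.min() < lo
            or rr.max() >= shape[0] - lo
            or cc.max() >= shape[1] - lo
        ):
            raise ValueError("process extends outside field bounds")
        line[rr, cc] = True
    mask = dilate(line, half_width) if half_width else line
    return mask


def generate_field(
    specs: Sequence[CellSpec],
    shape: tuple[int, int] = (1024, 1024),
    *,
    noise_sd: float = 0.0,
    background: float = 100.0,
    seed: int = 0,
    margin: int = 2,
    blur_sigma: float = 0.0,
) -> tuple[ChannelStack, FieldTruth]:
    """Render cells into a three-channel field and return channels + truth.

    Channels hold ``background`` outside any rendered support and the flat
    class intensity inside it (so at ``noise_sd = 0`` the pixel sum of a
    channel over a mask equals intensity x area exactly): the nuclei channel
    is bright only on nucleus disks; the GFAP channel carries ``gfap_mean``
    on soma+processes of GFAP+ cells only; the Vimentin channel carries
    ``vimentin_mean`` on the full mask of every cell. Additive Gaussian
    noise of sd ``noise_sd`` is applied per channel and clipped at zero.

    Raises ``ValueError`` naming the offending cell indices if any cell
    leaves the field or two cells come within ``margin`` pixels.
    """
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError("field shape must be at least 64x64")
    if noise_sd < 0 or background < 0:
        raise ValueError("noise_sd and background must be non-negative")
    rng = np.random.default_rng(seed)

    nuclei_lab = np.zeros(shape, dtype=np.int32)
    cell_lab = np.zeros(shape, dtype=np.int32)
    soma_lab = np.zeros(shape, dtype=np.int32)
    proc_lab = np.zeros(shape, dtype=np.int32)
    occupancy = np.zeros(shape, dtype=np.int32)

    rows = []
    for idx, spec in enumerate(specs):
        label = idx + 1
        try:
            soma = _ellipse_mask(spec, shape)
            nucleus = _nucleus_mask(spec, shape)
            processes = _process_mask(spec, shape, rng)
        except ValueError as exc:
            raise ValueError(f"cell {idx}: {exc}") from exc
        cell = soma | processes
        padded = dilate(cell, margin) if margin else cell
        hit = np.unique(occupancy[padded])
        hit = hit[hit > 0]
        if hit.size:
            others = ", ".join(str(int(h) - 1) for h in hit)
            raise ValueError(
                f"cell {idx} overlaps cells [{others}] within margin {margin}"
            )
        occupancy[cell] = label
        proc_only = processes & ~soma
        nuclei_lab[nucleus] = label
        cell_lab[cell] = label
        soma_lab[soma] = label
        proc_lab[proc_only] = label
        rows.append(
            dict(
                cell_id=label,
                gfap_class=spec.gfap_class,
                center_row=spec.center[0],
                center_col=spec.center[1],
                cell_area_px=int(cell.sum()),
                soma_area_px=int(soma.sum()),
                process_area_px=int(proc_only.sum()),
                nucleus_area_px=int(nucleus.sum()),
                process_perimeter_px=exposed_edge_perimeter(proc_only),
            )
        )

    columns = [
        "cell_id",
        "gfap_class",
        "center_row",
        "center_col",
        "cell_area_px",
        "soma_area_px",
        "process_area_px",
        "nucleus_area_px",
        "process_perimeter_px",
    ]
    table = pd.DataFrame(rows, columns=columns)

    chan_nuc = np.full(shape, background, dtype=float)
    chan_gfap = np.full(shape, background, dtype=float)
    chan_vim = np.full(shape, background, dtype=float)
    for idx, spec in enumerate(specs):
        label = idx + 1
        chan_nuc[nuclei_lab == label] = spec.nucleus_mean
        chan_vim[cell_lab == label] = spec.vimentin_mean
        if spec.gfap_class == "positive":
            chan_gfap[cell_lab == label] = spec.gfap_mean

    if blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        chan_nuc = gaussian_filter(chan_nuc, blur_sigma)
        chan_gfap = gaussian_filter(chan_gfap, blur_sigma)
        chan_vim = gaussian_filter(chan_vim, blur_sigma)
    if noise_sd > 0:
        chan_nuc = np.clip(chan_nuc + rng.normal(0, noise_sd, shape), 0, None)
        chan_gfap = np.clip(chan_gfap + rng.normal(0, noise_sd, shape), 0, None)
        chan_vim = np.clip(chan_vim + rng.normal(0, noise_sd, shape), 0, None)

    stack = ChannelStack(nuclei=chan_nuc, gfap=chan_gfap, vimentin=chan_vim)
    truth = FieldTruth(
        nuclei_labels=nuclei_lab,
        cell_labels=cell_lab,
        soma_labels=soma_lab,
        process_labels=proc_lab,
        cell_table=table,
    )
    return stack, truth


def generate_bulk_mixtures(
    signature: Union["pd.DataFrame", "object"],
    proportions: pd.DataFrame,
    noise_sd_log: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy bulk expression as mixtures of cell-type signature columns.

    Each sample (column of the result) is ``signature @ p`` for its
    proportion row, multiplied elementwise by lognormal noise whose log has
    sd ``noise_sd_log``; with zero noise the mixture is exact. ``signature``
    may be a genes x cell-types DataFrame or any object exposing a
    ``mean_profile`` DataFrame (e.g. a fitted SignatureMatrix).
    """
    profile = getattr(signature, "mean_profile", signature)
    if not isinstance(profile, pd.DataFrame):
        raise TypeError("signature must be a DataFrame or expose mean_profile")
    props = pd.DataFrame(proportions)
    if not props.columns.equals(pd.Index(profile.columns)):
        props = props.reindex(columns=profile.columns)
        if props.isna().any().any():
            raise ValueError("proportions columns must match signature cell types")
    vals = props.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("proportions must be non-negative")
    if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each proportion row must sum to 1 within 1e-9")
    if noise_sd_log < 0:
        raise ValueError("noise_sd_log must be non-negative")

    rng = np.random.default_rng(seed)
    clean = profile.to_numpy(dtype=float) @ vals.T  # genes x samples
    if noise_sd_log > 0:
        clean = clean * np.exp(rng.normal(0.0, noise_sd_log, size=clean.shape))
    sample_names = [str(s) for s in props.index]
    return pd.DataFrame(clean, index=profile.index, columns=sample_names)
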