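# Methods

This note documents the models, conventions and parameter choices behind
`astroquant`, and what the synthetic-data experiments do and do not show
about real data.

## Conventions used everywhere

* **Coordinates and connectivity.** Masks are dense `(row, col)` 0-based
  integer label grids; connected components use 8-connectivity.
* **Structuring element.** All dilations, erosions and openings use a
  half-pixel-inflated disk: offsets `(dr, dc)` with
  `dr² + dc² ≤ r·(r+1)`. For `r = 1` this is the full 3×3 square, keeping
  dilation consistent with 8-connectivity; for larger radii it is an
  octagonal approximation of the Euclidean disk. A strict Euclidean disk
  of radius 1 would be the 4-neighbour cross, which contradicts the
  8-connected component convention.
* **Perimeter.** The process perimeter counts exposed 4-neighbour pixel
  edges (a solid 10×10 square has perimeter 40). This integer convention
  is exactly testable, unlike contour-length estimators; it overestimates
  the geometric length of diagonal boundaries by up to √2.
* **Determinism.** All randomness flows from explicit integer seeds
  through `numpy.random.default_rng`; derived child seeds stay below
  2³¹. TIFF and CSV writers embed no timestamps, so identical configs
  reproduce byte-identical outputs.

## Synthetic fields (`synthio`)

Each cell is an elliptical soma, a concentric nuclear disk of radius
0.6·min(soma semi-axes) (guaranteeing exactly one nucleus per cell), and
straight processes rooted just inside the soma boundary, spread evenly in
angle with a small seeded jitter and thickened to the nearest odd width by
dilation. Channels carry a flat class intensity on the rendered support
(nuclei 10 000 on nucleus disks; GFAP 8 000 on soma+processes of GFAP⁺
cells only; Vimentin 3 000 on every cell) over a background of 100, plus
additive Gaussian noise clipped at zero. Intensities are plateaus rather
than background-additive so that, without noise, the channel sum over a
mask equals intensity × area exactly. An optional Gaussian pre-blur flag
exists but is off by default: the pipeline is threshold-based and the
recovery experiments are about segmentation and measurement, not PSF
modelling.

Class presets (pixels):

| class    | soma semi-axes | processes | length | width |
|----------|----------------|-----------|--------|-------|
| stellate | 10, 12         | 6         | 40     | 3     |
| flat     | 22, 26         | 2         | 14     | 7     |

Presets jitter mildly per cell (±1 px on semi-axes, ±10% on length,
random orientation) without ever crossing the between-class ordering.
Soma semi-axes of both classes exceed the default soma-opening radius
(8 px) while all process widths stay below it, so a single opening radius
separates soma from processes for both classes. Layout places cells on a
jittered grid with a worst-case-reach spacing, so fields are
collision-free by construction; `generate_field` still verifies bounds and
pairwise margins and names offending cell indices.

What the generator does **not** emulate: uneven illumination, photo-
bleaching, texture inside cells, out-of-focus light, curving or branching
processes, touching cells. Passing recovery tests therefore demonstrates
correctness of the measurement chain, not robustness to those real-world
effects.

## Segmentation (`segment`)

Nuclei: Gaussian smoothing, global threshold (Otsu or fixed), Euclidean
distance transform, watershed seeded at distance maxima separated by
`min_peak_distance_px` (default 5), components below
`min_nucleus_area_px = 30` dropped, labels made sequential. Cells:
foreground = smoothed marker above threshold ∪ nucleus supports,
partitioned by a watershed on the inverted smoothed marker seeded at the
nuclei; foreground components without a nucleus are discarded; cells below
`min_cell_area_px = 100` are dropped with their nuclei; cell and nucleus
share a label. The perinuclear zone of a cell is its nucleus dilated by
`ring_width_px = 5`, minus the nucleus, clipped to the cell's own support.
Border-touching cells are removed by default.

Defaults are `smoothing_sigma_px = 2` with Otsu thresholding — a robust
general-purpose setting for noisy images. The synthetic recovery
experiments instead use `sigma = 1` with fixed half-range thresholds
(1 550 for the Vimentin plateau 3 000 over background 100): thresholding a
smoothed step edge at half its height localizes the boundary at the true
edge independent of sigma, and sigma 1 keeps the smoothed centre of a
3-px-wide process (≈ 6 800) well above that threshold, whereas sigma 2
would push thin processes below any global threshold that still separates
background. These are analysis settings derived from the edge model, fixed
before the experiments and used identically in tests, acceptance script
and examples.

The cellular mask is seeded from the Vimentin channel when present (it
marks immature and mature astrocytes alike, so GFAP-negative cells retain
a measurable territory and a non-empty perinuclear ring), falling back to
GFAP otherwise; the choice is exposed as `cell_marker`.

## Morphometry (`morpho`)

Soma = morphological opening of the cell mask with radius
`opening_radius_px = 8`, restricted to the component containing (or
nearest to) the nucleus centroid; if the opening is empty the soma falls
back to the nucleus dilated by 2 px within the cell; processes are the
remainder, so soma + process = cell by construction. Per-cell features are
pixel-count areas, the exposed-edge process perimeter, the perinuclear
GFAP mean and the whole-cell Vimentin mean. A cell whose perinuclear zone
is empty has no defined GFAP readout; it is logged and dropped.

GFAP⁺ calling thresholds the perinuclear mean, either at a fixed value or
by an exact (unbinned) Otsu minimizer of intra-class variance computed
once over the pooled per-cell means of an analysis batch — pooling across
fields of a condition avoids per-field threshold drift. Field summaries
use summed ratios (Σsoma/Σcell etc.), not means of per-cell ratios, and by
default restrict the morphology sums to GFAP⁺ cells while the GFAP⁺
fraction counts all cells.

Extension points deliberately left out: skeleton-based branch counts,
Sholl profiles, per-branch statistics.

## Expression statistics (`exprstats`)

* Low-expression filter: keep a gene iff CPM ≥ cutoff (default 1.0) in at
  least k samples, k defaulting to the smallest (line × protocol) group
  size — an explicit, documented stand-in for count-filter heuristics
  whose exact parameters vary between tools.
* BH adjustment implements the step-up rule directly; note it is *not*
  idempotent in general (p = [0.25, 1] → q = [0.5, 1] → [1, 1]), so the
  guaranteed invariants are order preservation, q ≥ p and q ≤ 1.
* Row Z-scores use the n−1 denominator; constant rows map to zeros (both
  stated because heatmap conventions vary).
* qPCR: ΔCt subtracts the arithmetic mean Ct of *ACTB* and *L27* (the
  geometric mean in linear space), ΔΔCt subtracts the reference-group mean
  ΔCt, RQ = 2^−ΔΔCt; amplification efficiency is fixed at 100% (a
  doubling per cycle) since no efficiency calibration is modelled.
  Post-hoc pairwise comparisons behind significance asterisks are out of
  scope.
* Two-way ANOVA is restricted to balanced complete designs with n ≥ 2 per
  cell, where all sums-of-squares types coincide; unbalanced input is
  rejected with advice rather than silently choosing a type. p-values come
  from the F distribution.

## Deconvolution (`deconv`)

Signature building: cells are normalized to relative abundance, averaged
per (subject, cell type), then averaged across subjects; the cross-subject
variance (ddof = 1, zero for a single subject) is retained per gene and
type; mean columns are renormalized to sum to 1. Estimation intersects
bulk and signature genes (≥ 50 required by default), normalizes both sides
to unit mass and solves NNLS; the result is renormalized to a composition.
The weighted variant iterates NNLS with gene weights
`w_g = 1/(Σ_k var[g,k]·x_k² + r_g² + ε)`, ε = 1e−8 — the first term is
the variance of the predicted bulk value if each cell type's profile
varies independently across subjects, scaled by the current solution; the
second is the squared current residual. Iteration stops when the largest
proportion change falls below `tol = 1e-6` or after `max_iter = 50`
rounds; non-convergence is flagged on the result, not raised. With zero
variance and homoscedastic residuals the weights are flat and the solution
equals the unweighted one; a noiseless mixture converges immediately with
zero residual.

This estimator is intentionally simplified: one bulk sample at a time, no
tree-guided recursive estimation over cell-type hierarchies, no shared
multi-sample modelling. It is suited to synthetic-recovery evaluation and
rough composition estimates, not to reproducing published multi-subject
deconvolution results.

## Problem sizes in tests and acceptance

The recovery experiments use 1 056×1 056 px fields of 50 cells per
morphology class (5 fields per class, noise sd = 400 = 5% of the GFAP
plateau), 200 cells for GFAP⁺-fraction recovery, 500-gene/4-type
deconvolution with 20 mixtures plus 50 paired heteroscedastic replicates,
1 000 random p-vectors and 100 random balanced designs for the statistics
oracles. These sizes give stable statistics while keeping a full run in
the order of a minute on a single CPU.

## Known limitations

* Threshold-based segmentation assumes roughly bimodal intensity; dim or
  highly textured markers need externally supplied fixed thresholds.
* Watershed territory assignment near equidistant boundaries depends on
  flooding order for exactly tied pixels.
* The soma opening under-segments somata whose smallest semi-axis is near
  the opening radius and merges process roots into the soma within one
  element radius of it.
* The qPCR model ignores efficiency differences between genes; the ANOVA
  requires balance by design.
* Synthetic recovery results bound measurement error of the pipeline, not
  its behaviour on real microscopy artifacts (see the generator's
  non-goals above).
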