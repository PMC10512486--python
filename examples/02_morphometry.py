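"""Single-cell morphometry: recover the stellate-vs-flat contrast.

Generates one field per morphology class at 5% channel noise, runs the full
imaging pipeline (nucleus segmentation, Vimentin-seeded cell segmentation,
soma/process decomposition, perinuclear GFAP measurement) and prints the
field-level summed-ratio readouts. Stellate fields should show a much
higher process/soma ratio and lower soma/cell ratio than flat fields.
"""

from astroquant import (
    SegmentationParams,
    generate_field,
    populate_field,
    run_imaging,
)

# half-range fixed thresholds; sigma 1 preserves the 3-px-wide processes
params = SegmentationParams(
    smoothing_sigma_px=1.0, threshold_mode="fixed", fixed_threshold=1550.0
)

for cls in ("stellate", "flat"):
    specs = populate_field({cls: 20}, (1056, 1056), seed=21)
    stack, truth = generate_field(specs, (1056, 1056), noise_sd=400.0, seed=22)
    records, summary, threshold = run_imaging(
        [stack], params, gfap_mode="fixed", gfap_fixed_threshold=2000.0
    )
    s = summary.iloc[0]
    print(f"{cls:9s}  n_cells={s.n_cells}  GFAP+={s.gfap_positive_fraction:.2f}  "
          f"soma/cell={s.soma_to_cell:.3f}  process/soma={s.process_to_soma:.3f}  "
          f"process/cell={s.process_to_cell:.3f}  "
          f"perimeter/cell={s.process_perimeter_to_cell:.3f}")

print("\nsoma/cell near 1 means almost everything is cell body (flat "
      "morphology); a large process/soma ratio marks the prototypical "
      "stellate astrocyte.")
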