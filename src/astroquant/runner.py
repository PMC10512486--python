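"""Workflow execution behind the CLI: validate, run, write a manifest.

Each workflow writes its outputs under the chosen directory and a
``manifest.json`` listing the effective parameters, the seed, the inputs
and a sha256 checksum for every output file, so identical configs can be
verified to reproduce identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__, deconv, exprstats, fileio, pipeline, synthio
from .config import apply_defaults, validate_config
from .deconv import SignatureMatrix
from .segment import SegmentationParams

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The configuration failed schema validation."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run(
    cfg: dict,
    out_dir: Path,
    seed_override: Optional[int] = None,
    base_dir: Path = Path("."),
) -> dict:
    """Validate and execute a workflow config; return the manifest."""
    errors = validate_config(cfg, base_dir=base_dir)
    if errors:
        raise ConfigError("; ".join(errors))
    eff = apply_defaults(cfg)
    if seed_override is not None:
        eff["seed"] = int(seed_override)
    wf = eff["workflow"]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    log.info("stage=%s status=start out=%s", wf, out_dir)
    runner = {
        "synth": _run_synth,
        "imaging": _run_imaging,
        "deconv": _run_deconv,
        "stats": _run_stats,
    }[wf]
    written, inputs = runner(eff, out_dir, base_dir)
    log.info("stage=%s status=done elapsed=%.2fs n_outputs=%d",
             wf, time.perf_counter() - t0, len(written))

    manifest = {
        "workflow": wf,
        "version": __version__,
        "seed": eff["seed"],
        "parameters": eff[wf],
        "inputs": sorted(str(p) for p in inputs),
        "outputs": {
            str(p.relative_to(out_dir)): _sha256(p) for p in sorted(written)
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_synth(eff: dict, out_dir: Path, base_dir: Path):
    p = eff["synth"]
    rng = np.random.default_rng(eff["seed"])
    shape = tuple(p["shape"])
    written: list[Path] = []
    for i in range(p["n_fields"]):
        layout_seed = int(rng.integers(0, 2**31 - 1))
        render_seed = int(rng.integers(0, 2**31 - 1))
        specs = synthio.populate_field(
            {"stellate": p["n_stellate"], "flat": p["n_flat"]},
            shape,
            gfap_positive_fraction=p["gfap_positive_fraction"],
            margin=p["margin"],
            seed=layout_seed,
        )
        stack, truth = synthio.generate_field(
            specs, shape,
            noise_sd=p["noise_sd"], background=p["background"],
            seed=render_seed, margin=min(p["margin"], 2),
        )
        written += fileio.save_field(out_dir / f"field_{i:03d}", stack, truth)
        log.info("stage=synth field=%03d n_cells=%d", i, len(specs))
    return written, []


def _run_imaging(eff: dict, out_dir: Path, base_dir: Path):
    p = eff["imaging"]
    input_dir = base_dir / p["input_dir"]
    prefixes = fileio.discover_fields(input_dir)
    if not prefixes:
        raise ValueError(f"no *_ch1.tif fields found in {input_dir}")
    stacks = [fileio.load_field(pref) for pref in prefixes]
    params = SegmentationParams(**p["segment"])
    records, summaries, threshold = pipeline.run_imaging(
        stacks,
        params=params,
        opening_radius_px=p["opening_radius_px"],
        cell_marker=p["cell_marker"],
        gfap_mode=p["gfap_mode"],
        gfap_fixed_threshold=p["gfap_fixed_threshold"],
        gfap_positive_only_for_morphology=p["gfap_positive_only_for_morphology"],
        field_names=[pref.name for pref in prefixes],
    )
    for df in (records, summaries):
        df.insert(1, "line", p["line"])
        df.insert(2, "protocol", p["protocol"])
        df.insert(3, "replicate", p["replicate"])
    records_path = out_dir / "cell_records.csv"
    summary_path = out_dir / "field_summary.csv"
    records.to_csv(records_path, index=False)
    summaries.to_csv(summary_path, index=False)
    log.info("stage=imaging n_fields=%d n_cells=%d gfap_threshold=%.3f",
             len(stacks), len(records), threshold)
    return [records_path, summary_path], prefixes


def _run_deconv(eff: dict, out_dir: Path, base_dir: Path):
    p = eff["deconv"]
    mean = fileio.read_matrix_csv(base_dir / p["signature_csv"])
    var = (
        fileio.read_matrix_csv(base_dir / p["variance_csv"])
        if p["variance_csv"]
        else None
    )
    signature = SignatureMatrix(
        mean_profile=mean / mean.sum(axis=0),
        cross_subject_variance=var,
        n_subjects=p["n_subjects"],
    )
    bulk = fileio.read_matrix_csv(base_dir / p["bulk_csv"])
    rows = []
    for sample in bulk.columns:
        if p["weighted"]:
            est = deconv.estimate_proportions_weighted(
                bulk[sample], signature,
                max_iter=p["max_iter"], tol=p["tol"],
                min_shared_genes=p["min_shared_genes"],
            )
        else:
            est = deconv.estimate_proportions_nnls(
                bulk[sample], signature, min_shared_genes=p["min_shared_genes"]
            )
        row = {"sample": sample, **est.proportions.to_dict(),
               "residual_norm": est.residual_norm,
               "n_iterations": est.n_iterations, "converged": est.converged}
        rows.append(row)
    props = pd.DataFrame(rows)
    path = out_dir / "proportions.csv"
    props.to_csv(path, index=False)
    log.info("stage=deconv n_samples=%d n_types=%d",
             bulk.shape[1], signature.mean_profile.shape[1])
    inputs = [base_dir / p["signature_csv"], base_dir / p["bulk_csv"]]
    return [path], inputs


def _run_stats(eff: dict, out_dir: Path, base_dir: Path):
    p = eff["stats"]
    counts = fileio.read_matrix_csv(base_dir / p["counts_csv"])
    design = fileio.read_design_csv(base_dir / p["design_csv"])
    inputs = [base_dir / p["counts_csv"], base_dir / p["design_csv"]]
    written: list[Path] = []

    filtered = exprstats.filter_low_expression(
        counts, design, cpm_cutoff=p["cpm_cutoff"], min_samples=p["min_samples"]
    )
    filtered_path = out_dir / "filtered_counts.csv"
    filtered.to_csv(filtered_path)
    written.append(filtered_path)
    log.info("stage=stats step=filter kept=%d of=%d", len(filtered), len(counts))

    # heatmap-style row Z-scores on log2(CPM + 1) of the filtered genes
    cpm = filtered / filtered.sum(axis=0) * 1e6
    z = exprstats.row_zscore(np.log2(cpm + 1))
    z_path = out_dir / "zscores.csv"
    z.to_csv(z_path)
    written.append(z_path)

    panel_rows = []
    for panel_path in p["panels"]:
        panel = pd.read_csv(base_dir / panel_path)
        scores, matched = exprstats.marker_panel_score(np.log2(cpm + 1), panel)
        name = Path(panel_path).stem
        for sample, score in scores.items():
            panel_rows.append(dict(panel=name, sample=sample, score=score,
                                   n_genes_matched=len(matched)))
        inputs.append(base_dir / panel_path)
    if panel_rows:
        panel_out = out_dir / "panel_scores.csv"
        pd.DataFrame(panel_rows).to_csv(panel_out, index=False)
        written.append(panel_out)

    if p.get("qpcr"):
        q = p["qpcr"]
        ct = pd.read_csv(base_dir / q["ct_csv"])
        rq = exprstats.qpcr_relative_expression(
            ct, targets=q["targets"], housekeeping=tuple(q["housekeeping"]),
            reference_group=q["reference_group"], design=design,
            group_column=q["group_column"],
        )
        rq_path = out_dir / "qpcr_relative_expression.csv"
        rq.to_csv(rq_path, index=False)
        written.append(rq_path)
        inputs.append(base_dir / q["ct_csv"])

    if p.get("anova"):
        a = p["anova"]
        table = pd.read_csv(base_dir / a["table_csv"])
        res = exprstats.two_way_anova(
            table[a["value_column"]], table[a["factor_a"]], table[a["factor_b"]]
        )
        frame = res.as_frame().reset_index(names="effect")
        frame["df_resid"] = res.df_resid
        anova_path = out_dir / "anova.csv"
        frame.to_csv(anova_path, index=False)
        written.append(anova_path)
        inputs.append(base_dir / a["table_csv"])
    return written, inputs
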