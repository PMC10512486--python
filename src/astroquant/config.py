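"""Run-configuration schema and strict validation for the CLI workflows.

Configs are YAML or JSON mappings with a ``workflow`` selector, an optional
``out_dir``/``seed``, and one parameter block named after the workflow.
Unknown keys are rejected anywhere; every violation message names the
offending key or constraint. ``apply_defaults`` returns the fully explicit
effective configuration so the manifest can echo every parameter value.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any, Callable, Optional

import yaml

WORKFLOWS = ("synth", "imaging", "deconv", "stats")

Check = Callable[[Any], Optional[str]]


def _positive(name: str) -> Check:
    return lambda v: None if v > 0 else f"{name} must be > 0"


def _non_negative(name: str) -> Check:
    return lambda v: None if v >= 0 else f"{name} must be >= 0"


def _ge(name: str, bound) -> Check:
    return lambda v: None if v >= bound else f"{name} must be >= {bound}"


def _in(name: str, choices) -> Check:
    return lambda v: None if v in choices else f"{name} must be one of {choices}"


def _fraction(name: str) -> Check:
    return lambda v: None if 0 <= v <= 1 else f"{name} must lie in [0, 1]"


# field spec: (types, default_or_REQUIRED, check_or_None)
REQUIRED = object()

_SEGMENT_SCHEMA = {
    "smoothing_sigma_px": ((int, float), 2.0, _non_negative("smoothing_sigma_px")),
    "threshold_mode": (str, "otsu", _in("threshold_mode", ("otsu", "fixed"))),
    "fixed_threshold": ((int, float, type(None)), None, None),
    "min_nucleus_area_px": (int, 30, _ge("min_nucleus_area_px", 1)),
    "min_cell_area_px": (int, 100, _ge("min_cell_area_px", 1)),
    "ring_width_px": (int, 5, _ge("ring_width_px", 1)),
    "exclude_border": (bool, True, None),
    "min_peak_distance_px": (int, 5, _ge("min_peak_distance_px", 1)),
}

SCHEMAS: dict[str, dict] = {
    "synth": {
        "shape": (list, [1024, 1024], None),
        "n_fields": (int, 1, _ge("n_fields", 1)),
        "n_stellate": (int, 0, _ge("n_stellate", 0)),
        "n_flat": (int, 0, _ge("n_flat", 0)),
        "gfap_positive_fraction": (
            (int, float), 1.0, _fraction("gfap_positive_fraction")),
        "noise_sd": ((int, float), 0.0, _non_negative("noise_sd")),
        "background": ((int, float), 100.0, _non_negative("background")),
        "margin": (int, 4, _ge("margin", 0)),
    },
    "imaging": {
        "input_dir": (str, REQUIRED, None),
        "line": (str, "", None),
        "protocol": (str, "", None),
        "replicate": (int, 1, None),
        "cell_marker": (str, "auto", _in("cell_marker", ("auto", "gfap", "vimentin"))),
        "opening_radius_px": (int, 8, _ge("opening_radius_px", 1)),
        "gfap_mode": (str, "otsu", _in("gfap_mode", ("otsu", "fixed"))),
        "gfap_fixed_threshold": ((int, float, type(None)), None, None),
        "gfap_positive_only_for_morphology": (bool, True, None),
        "segment": (dict, {}, None),
    },
    "deconv": {
        "signature_csv": (str, REQUIRED, None),
        "variance_csv": ((str, type(None)), None, None),
        "n_subjects": (int, 1, _ge("n_subjects", 1)),
        "bulk_csv": (str, REQUIRED, None),
        "weighted": (bool, True, None),
        "min_shared_genes": (int, 50, _ge("min_shared_genes", 1)),
        "max_iter": (int, 50, _ge("max_iter", 1)),
        "tol": ((int, float), 1e-6, _positive("tol")),
    },
    "stats": {
        "counts_csv": (str, REQUIRED, None),
        "design_csv": (str, REQUIRED, None),
        "cpm_cutoff": ((int, float), 1.0, _non_negative("cpm_cutoff")),
        "min_samples": ((str, int), "auto", None),
        "panels": (list, [], None),
        "qpcr": ((dict, type(None)), None, None),
        "anova": ((dict, type(None)), None, None),
    },
}

_QPCR_SCHEMA = {
    "ct_csv": (str, REQUIRED, None),
    "targets": (list, REQUIRED, None),
    "housekeeping": (list, ["ACTB", "L27"], None),
    "reference_group": (str, REQUIRED, None),
    "group_column": (str, "protocol", None),
}

_ANOVA_SCHEMA = {
    "table_csv": (str, REQUIRED, None),
    "value_column": (str, REQUIRED, None),
    "factor_a": (str, REQUIRED, None),
    "factor_b": (str, REQUIRED, None),
}

_PATH_KEYS = {
    "input_dir", "signature_csv", "variance_csv", "bulk_csv", "counts_csv",
    "design_csv", "ct_csv", "table_csv",
}


def load_config(path: Path) -> dict:
    """Parse a YAML or JSON config file into a mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping at the top level")
    return cfg


def _check_block(
    block: dict, schema: dict, prefix: str, base_dir: Path, errors: list[str]
) -> None:
    for key in block:
        if key not in schema:
            errors.append(f"unknown key {prefix}{key!r}")
    for key, (types, default, check) in schema.items():
        if key in block:
            value = block[key]
            if not isinstance(value, types) or (
                isinstance(value, bool) and bool not in np_types(types)
            ):
                errors.append(
                    f"{prefix}{key}: expected {type_names(types)}, "
                    f"got {type(value).__name__}"
                )
                continue
            if check is not None:
                msg = check(value)
                if msg:
                    errors.append(f"{prefix}{msg}")
            if key in _PATH_KEYS and isinstance(value, str):
                if not (base_dir / value).exists():
                    errors.append(f"{prefix}{key}: path does not exist: {value}")
        elif default is REQUIRED:
            errors.append(f"missing required key {prefix}{key!r}")


def np_types(types) -> tuple:
    return types if isinstance(types, tuple) else (types,)


def type_names(types) -> str:
    return "/".join(t.__name__ for t in np_types(types))


def validate_config(cfg: dict, base_dir: Path = Path(".")) -> list[str]:
    """Return a list of schema violations (empty means valid)."""
    errors: list[str] = []
    allowed_top = {"workflow", "seed", "out_dir"} | set(WORKFLOWS)
    for key in cfg:
        if key not in allowed_top:
            errors.append(f"unknown key {key!r}")
    wf = cfg.get("workflow")
    if wf not in WORKFLOWS:
        errors.append(f"workflow must be one of {WORKFLOWS}, got {wf!r}")
        return errors
    for other in WORKFLOWS:
        if other != wf and other in cfg:
            errors.append(f"block {other!r} does not match workflow {wf!r}")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        errors.append("seed must be an integer")
    if wf == "synth" and not isinstance(cfg.get("seed"), int):
        errors.append("missing required key 'seed' (mandatory for synth)")

    block = cfg.get(wf, {})
    if not isinstance(block, dict):
        errors.append(f"block {wf!r} must be a mapping")
        return errors
    _check_block(block, SCHEMAS[wf], f"{wf}.", base_dir, errors)

    if wf == "imaging" and isinstance(block.get("segment"), dict):
        _check_block(block["segment"], _SEGMENT_SCHEMA, "imaging.segment.",
                     base_dir, errors)
        mode = block["segment"].get("threshold_mode", "otsu")
        fixed = block["segment"].get("fixed_threshold")
        if (mode == "fixed") != (fixed is not None):
            errors.append(
                "imaging.segment.fixed_threshold is required iff "
                "threshold_mode='fixed'")
    if wf == "imaging":
        if (block.get("gfap_mode", "otsu") == "fixed") != (
            block.get("gfap_fixed_threshold") is not None
        ):
            errors.append(
                "imaging.gfap_fixed_threshold is required iff gfap_mode='fixed'")
    if wf == "stats":
        if isinstance(block.get("qpcr"), dict):
            _check_block(block["qpcr"], _QPCR_SCHEMA, "stats.qpcr.", base_dir,
                         errors)
        if isinstance(block.get("anova"), dict):
            _check_block(block["anova"], _ANOVA_SCHEMA, "stats.anova.", base_dir,
                         errors)
        for p in block.get("panels", []):
            if not isinstance(p, str) or not (base_dir / p).exists():
                errors.append(f"stats.panels: path does not exist: {p}")
    if wf == "synth":
        shape = block.get("shape", [1024, 1024])
        if (
            not isinstance(shape, list) or len(shape) != 2
            or not all(isinstance(s, int) and s >= 64 for s in shape)
        ):
            errors.append("synth.shape must be [rows, cols] with both >= 64")
    return errors


def _fill(block: dict, schema: dict) -> dict:
    out = {}
    for key, (types, default, _check) in schema.items():
        out[key] = copy.deepcopy(block.get(key, None if default is REQUIRED
                                           else default))
    return out


def apply_defaults(cfg: dict) -> dict:
    """Effective configuration with every default made explicit."""
    wf = cfg["workflow"]
    eff = {
        "workflow": wf,
        "seed": cfg.get("seed"),
        "out_dir": cfg.get("out_dir"),
        wf: _fill(cfg.get(wf, {}), SCHEMAS[wf]),
    }
    if wf == "imaging":
        eff[wf]["segment"] = _fill(cfg.get(wf, {}).get("segment", {}) or {},
                                   _SEGMENT_SCHEMA)
    if wf == "stats":
        block = cfg.get(wf, {})
        if isinstance(block.get("qpcr"), dict):
            eff[wf]["qpcr"] = _fill(block["qpcr"], _QPCR_SCHEMA)
        if isinstance(block.get("anova"), dict):
            eff[wf]["anova"] = _fill(block["anova"], _ANOVA_SCHEMA)
    return eff
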