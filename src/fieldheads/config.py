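"""Run configuration: defaults, YAML round-trip, and validation.

One YAML document parameterizes every pipeline stage.  Unknown keys are
warnings, not errors, so configs written for a newer version still load.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "config_hash"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "field": {
        "n_rows": 8,
        "row_spacing_m": 0.75,
        "row_length_m": 20.0,
        "orientation_deg": 3.0,
        "heads_per_m": 5.0,
        "cross_jitter_sd_m": 0.02,
        "gap_spans": [],          # [row_index, start_m, end_m] triples
        "head_diameter_cm": 8.0,
        "ref_lat": -27.45,
        "ref_lon": 151.53,
    },
    "capture": {
        "gsd_cm_px": 0.25,
        "image_w_px": 2000,
        "image_h_px": 1500,
        "overlap_fraction": 0.8,
        "camera_yaw_deg": 0.0,
    },
    "noise": {
        "fp_rate_per_m2": 0.0,
        "fn_prob": 0.0,
        "box_jitter_px_sd": 0.0,
    },
    "preprocess": {
        "edge_fraction": 0.10,
        "target_gsd_cm_px": 0.25,
    },
    "ransac": {
        "n": 2,
        "k": 500,
        "t": None,                # null -> 0.35 x row spacing in px
        "d": 5,
    },
    "rows": {
        "direction_tol_deg": 10.0,
    },
    "mosaic": {
        "cell_fraction": 0.5,     # cell side as a fraction of the smallest footprint side
    },
    "stats": {
        "gap_threshold_cm": 50.0,
        "window_px": 100,
        "scale_cm_px": 1.0,
        "profile_window_cm": 100,
        "profile_sigma_cm": 25.0,
        "length_basis": "row_span",
    },
    "eval": {
        "iou_thresh": 0.5,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config merged over the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config root must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def validate_config(cfg: dict) -> tuple[list[str], list[str]]:
    """Schema and range checks.  Returns (errors, warnings)."""
    errors: list[str] = []
    warnings_: list[str] = []

    def positive(section: str, key: str) -> None:
        v = cfg.get(section, {}).get(key)
        if v is None or not isinstance(v, (int, float)) or v <= 0:
            errors.append(f"{section}.{key}: must be a positive number, got {v!r}")

    for section, key in [
        ("field", "n_rows"), ("field", "row_spacing_m"), ("field", "row_length_m"),
        ("capture", "gsd_cm_px"), ("capture", "image_w_px"), ("capture", "image_h_px"),
        ("preprocess", "target_gsd_cm_px"),
        ("mosaic", "cell_fraction"),
        ("stats", "gap_threshold_cm"), ("stats", "window_px"), ("stats", "scale_cm_px"),
    ]:
        positive(section, key)
    if cfg.get("field", {}).get("heads_per_m", 0) < 0:
        errors.append("field.heads_per_m: must be non-negative")
    ef = cfg.get("preprocess", {}).get("edge_fraction", 0.0)
    if not 0.0 <= ef < 0.5:
        errors.append(f"preprocess.edge_fraction: must be in [0, 0.5), got {ef!r}")
    ov = cfg.get("capture", {}).get("overlap_fraction", 0.0)
    if not 0.0 <= ov < 1.0:
        errors.append(f"capture.overlap_fraction: must be in [0, 1), got {ov!r}")
    fn = cfg.get("noise", {}).get("fn_prob", 0.0)
    if not 0.0 <= fn <= 1.0:
        errors.append(f"noise.fn_prob: must be in [0, 1], got {fn!r}")
    if cfg.get("noise", {}).get("fp_rate_per_m2", 0.0) < 0:
        errors.append("noise.fp_rate_per_m2: must be non-negative")
    r = cfg.get("ransac", {})
    if r.get("n", 2) < 2:
        errors.append("ransac.n: must be >= 2")
    if r.get("k", 1) < 1:
        errors.append("ransac.k: must be >= 1")
    if r.get("t") is not None and not r["t"] > 0:
        errors.append("ransac.t: must be positive or null")
    if r.get("d", 2) < r.get("n", 2):
        errors.append("ransac.d: must be >= ransac.n")
    if not isinstance(cfg.get("seed"), int):
        errors.append("seed: must be an integer")
    for key in cfg:
        if key not in DEFAULT_CONFIG:
            warnings_.append(f"unknown top-level key {key!r} ignored")
    for section, defaults in DEFAULT_CONFIG.items():
        if isinstance(defaults, dict):
            for key in cfg.get(section, {}):
                if key not in defaults:
                    warnings_.append(f"unknown key {section}.{key!r} ignored")
    return errors, warnings_


def config_hash(cfg: dict) -> str:
    """Stable content hash of a config (order-independent)."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
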