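"""Pipeline configuration: defaults, YAML loading, strict validation.

The demo configuration drives a fully synthetic end-to-end run sized for a
laptop: per independent experiment it renders reporter fields, one
colocalization field and one small MEA well per condition, then pushes the
measurements through grouping, control-normalization and paired testing.
Disease effects are multiplicative on the generating parameters
(0.7 = 30% reduction in the PD group; 1.0 = null metric).
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

__all__ = ["default_config", "load_config", "merge_config", "config_hash"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scheme": "neuronal",
    "n_experiments": 10,
    "fields_per_experiment": 6,
    "timepoint": 70,
    "effects": {
        # multiplicative PD effects on the generating process
        "autolysosome": 0.7,  # scales PD vesicle counts (density and area)
        "firing_rate": 0.7,  # scales PD tonic spike rates
        "coloc": 1.0,  # scales the PD overlap target (1.0 = null)
    },
    "imaging": {
        "field_shape": [1, 192, 192],
        "n_cells": 5,
        "reporter_fraction": 0.55,
        "base_counts": {
            "red_only_small": 18,
            "red_only_medium": 12,
            "red_only_large": 6,
            "dual_positive_small": 3,
            "dual_positive_medium": 2,
            "dual_positive_large": 0,
        },
        "noise": {"kind": "gaussian", "sigma_rel": 0.2, "gain": 1.0},
        "robust_k": 3.0,
        "cell_smooth_sigma": 1.5,
        "dual_positive_cutoff": 0.5,
        "min_voxels": 2,
    },
    "coloc": {
        "markers": ["aSyn", "Proteostat"],
        "target_fraction": 0.5,
        "jitter_sd": 0.05,
        "mask_voxels": 2000,
        "denominator_mode": "reference_marker",
    },
    "mea": {
        "n_electrodes": 4,
        "duration_s": 60.0,
        "fs": 12500.0,
        "base_rate_hz": 2.0,
        "noise_sd": 1.0,
        "spike_amplitude_sd": 12.0,
        "threshold_k": 6.0,
        "min_rate_per_min": 5.0,
    },
    "stats": {
        "normalization": "per_timepoint",
        "normality_alpha": 0.05,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def merge_config(user: dict, defaults: dict | None = None, path: str = "") -> dict:
    """Overlay ``user`` on the defaults, rejecting unknown keys."""
    defaults = default_config() if defaults is None else copy.deepcopy(defaults)
    for key, value in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and key != "base_counts":
            if not isinstance(value, dict):
                raise ValueError(f"config key {where} must be a mapping")
            defaults[key] = merge_config(value, defaults[key], where)
        else:
            defaults[key] = value
    return defaults


def load_config(path: str | None) -> dict:
    """Load a YAML config (or the built-in demo when ``path`` is None)."""
    if path is None:
        return default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return merge_config(user)


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved config, for output traceability."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_config(config: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
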