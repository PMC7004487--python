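"""Pipeline configuration: YAML/JSON structure, defaults, validation.

Every tunable parameter of the demo pipeline lives here with its
default, and a loaded config is validated strictly — unknown keys are
rejected by name so typos cannot silently fall back to defaults. The
fully merged config (defaults plus overrides) is echoed into the run
manifest for auditability.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "stack_shape": [12, 80, 80],
        "voxel_size": [0.2, 0.2, 1.0],
        "n_buds": 1,
        "bud_semiaxes_um": [5.0, 7.0, 7.0],
        "cells_per_bud": {"type_ii": 3, "type_iii": 3},
        "noise_sd": 6.0,
        "poisson_gain": 1.0,
        "groups": {
            "WT": {"fiber_density": 0.20, "channel_overlap_fraction": 0.6,
                    "n_stacks": 2},
            "KO": {"fiber_density": 0.10, "channel_overlap_fraction": 0.6,
                    "n_stacks": 2},
        },
    },
    "preprocess": {
        "background_radius_px": 50,
        "median_radius_px": 2,
    },
    "quantify": {
        "min_area_px": 20,
    },
    "stats": {
        "dunn_adjust": "none",
    },
}


def _validate_tree(given: dict, template: dict, path: str = "") -> dict:
    merged = copy.deepcopy(template)
    for key, value in given.items():
        here = f"{path}.{key}" if path else key
        if key not in template:
            raise ValueError(f"unknown configuration key: {here!r}")
        if isinstance(template[key], dict) and key not in (
            "groups",
            "cells_per_bud",
        ):
            if not isinstance(value, dict):
                raise ValueError(f"configuration key {here!r} must be a mapping")
            merged[key] = _validate_tree(value, template[key], here)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


_GROUP_KEYS = {"fiber_density", "channel_overlap_fraction", "n_stacks"}


def validate_config(config: dict) -> dict:
    """Merge a partial config over the defaults, rejecting unknown keys."""
    merged = _validate_tree(config or {}, DEFAULT_CONFIG)
    for group, group_cfg in merged["simulate"]["groups"].items():
        unknown = set(group_cfg) - _GROUP_KEYS
        if unknown:
            raise ValueError(
                f"unknown configuration key(s) in simulate.groups.{group}: "
                f"{sorted(unknown)}"
            )
    return merged


def load_config(path: Path | str | None) -> dict:
    """Load a YAML config file (or defaults when ``path`` is None)."""
    if path is None:
        return validate_config({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration file must contain a mapping")
    return validate_config(raw)
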