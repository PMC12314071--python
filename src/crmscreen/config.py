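"""Structured configuration: defaults, YAML files, CLI overrides.

One nested key -> value mapping drives the pipeline; every CLI flag has a
config twin and the CLI wins.  Only keys present in the defaults are
accepted, so typos fail loudly.
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict = {
    "scan": {
        "p_threshold": 1e-3,
        "pseudocount": 0.1,
        "granularity": 1e-3,
        "strands": "both",
        "background": "uniform",  # uniform | estimate
    },
    "regions": {
        "core_upstream": 200,
        "crm_upstream": 2000,
        "isoform": "longest",
    },
    "core": {
        "y_patch_p": 4e-4,
        "y_patch_model": "builtin",  # builtin | rule | <motif id in library>
        "tata_hexamers": ["TATAAA", "ATTAAA"],
    },
    "crm": {
        "window_bp": 300,
        "family_p": {
            "WRKY": 1e-3,
            "G2like": 1e-3,
            "MYBR_B": 1e-4,
            "DOF": 1e-4,
            "IDD": 1e-4,
            "DPBF": 1e-4,
        },
    },
    "expression": {
        "tpm_min": 1.0,
        "min_samples": 3,
    },
    "quantify": {
        "test": "wilcoxon",  # wilcoxon | t
        "alpha": 0.05,
    },
}


def merge_config(base: dict, override: dict, path: str = "") -> dict:
    """Recursive merge; keys absent from ``base`` are rejected."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in out:
            raise KeyError(f"unknown config key {here!r}")
        if isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = merge_config(out[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(DEFAULTS, user)
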