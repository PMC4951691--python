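"""Configuration loading.

All empirical constants (charge-hydropathy boundary, Rh scaling-law
coefficients, Q-factor bands, Kratky thresholds, classifier weights) live in
``data/defaults.yaml`` and can be overridden by a user YAML file merged on
top of the defaults.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

_DEFAULTS_CACHE: dict | None = None


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config() -> dict:
    """Return a deep copy of the packaged default configuration."""
    global _DEFAULTS_CACHE
    if _DEFAULTS_CACHE is None:
        text = resources.files("foldstate").joinpath("data/defaults.yaml").read_text()
        _DEFAULTS_CACHE = yaml.safe_load(text)
    return copy.deepcopy(_DEFAULTS_CACHE)


def load_config(path: str | Path | None = None) -> dict:
    """Load configuration, merging an optional user YAML over the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg
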