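"""Access to the package's versioned default configuration."""

from __future__ import annotations

import copy
from importlib import resources

import yaml

_cache: dict | None = None

#: canonical order of the six test times of the assay
TEST_TIMES = ("baseline", "5min", "40min", "70min", "5h", "24h")

#: the two experimental groups
GROUPS = ("control", "concussed")

#: number of vibratory stimuli per test
N_STIMULI = 20


def load_defaults() -> dict:
    """Return a deep copy of the packaged default configuration."""
    global _cache
    if _cache is None:
        with resources.files("startlehab.data").joinpath("defaults.yaml").open() as fh:
            _cache = yaml.safe_load(fh)
    return copy.deepcopy(_cache)


def load_config(path=None) -> dict:
    """Load a user YAML config merged over the packaged defaults.

    Top-level sections present in the user file replace keys of the same
    name in the defaults (shallow per-section merge).
    """
    cfg = load_defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(value)
            else:
                cfg[section] = value
    return cfg
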