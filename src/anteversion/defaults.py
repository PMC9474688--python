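"""Shipped calibration defaults for the statistical cohort generator."""

from __future__ import annotations

import functools
from importlib import resources

import yaml

__all__ = ["table2_defaults", "load_config"]


@functools.lru_cache(maxsize=1)
def table2_defaults() -> dict:
    """The shipped cohort calibration (PSA moments, per-method cells)."""
    path = resources.files("anteversion").joinpath("data/table2_defaults.yaml")
    return yaml.safe_load(path.read_text())


def load_config(path=None) -> dict:
    """Load a cohort calibration YAML, falling back to the shipped defaults."""
    if path is None:
        return table2_defaults()
    with open(path) as fh:
        return yaml.safe_load(fh)
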