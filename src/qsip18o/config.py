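"""YAML configuration loading for the simulator and the analysis pipeline.

A config file may carry any of the top-level sections ``design`` (simulator
experimental design), ``gradient`` (fractionation/sequencing parameters),
``qsip`` (isotope calibration constants) and ``run`` (bootstrap iterations,
CI level, seed, cutoff).  Unknown keys raise a config error so typos do not
silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .core import IsotopeConstants
from .simulate import DesignConfig, GradientConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}' config: {sorted(unknown)}")
    coerced = {}
    for k, v in section.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' config: {exc}") from exc


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config into constructed objects plus the raw run section."""
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config file must contain a mapping")
    unknown = set(doc) - {"design", "gradient", "qsip", "run"}
    if unknown:
        raise ConfigError(f"unknown top-level config section(s): {sorted(unknown)}")
    return {
        "design": _build(DesignConfig, doc.get("design", {}), "design"),
        "gradient": _build(GradientConfig, doc.get("gradient", {}), "gradient"),
        "constants": _build(IsotopeConstants, doc.get("qsip", {}), "qsip"),
        "run": dict(doc.get("run", {})),
    }
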