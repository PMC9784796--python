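"""Run configuration: YAML/JSON loading of all pipeline parameters.

A config file holds up to five sections, each mapping onto one dataclass::

    preprocess:   PreprocessConfig
    segment:      SegmentConfig
    geometry:     ChipGeometry
    health:       HealthThresholds (list of {upper_bound, category, action})
    logging:      {level: INFO, file: run.log}

Unknown sections or keys are rejected with a clear error so that typos
never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from math import inf
from pathlib import Path

import yaml

from .preprocessing import ConfigError, PreprocessConfig
from .quantify import ChipGeometry, HealthBand, HealthThresholds
from .segmentation import SegmentConfig

__all__ = ["RunConfig", "load_config", "ConfigError"]


@dataclass(frozen=True)
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    geometry: ChipGeometry = field(default_factory=ChipGeometry)
    health: HealthThresholds = field(default_factory=HealthThresholds)
    log_level: str = "INFO"
    log_file: str | None = None
    seed: int | None = None


def _build(cls, section: dict, name: str):
    if not isinstance(section, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    coerced = dict(section)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    return cls(**coerced)


def _build_health(section) -> HealthThresholds:
    if not isinstance(section, list):
        raise ConfigError("config section 'health' must be a list of bands")
    bands = []
    for i, entry in enumerate(section):
        unknown = set(entry) - {"upper_bound", "category", "action"}
        if unknown:
            raise ConfigError(f"unknown keys in health band {i + 1}: {sorted(unknown)}")
        upper = entry.get("upper_bound", "inf")
        upper = inf if upper in ("inf", ".inf", None) else float(upper)
        bands.append(HealthBand(upper, str(entry["category"]), str(entry["action"])))
    return HealthThresholds(bands=tuple(bands))


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file (None → all defaults)."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")

    known = {"preprocess", "segment", "geometry", "health", "logging", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")

    logging_sec = data.get("logging", {})
    if not isinstance(logging_sec, dict) or set(logging_sec) - {"level", "file"}:
        raise ConfigError("config section 'logging' accepts only 'level' and 'file'")

    return RunConfig(
        preprocess=_build(PreprocessConfig, data.get("preprocess", {}), "preprocess"),
        segment=_build(SegmentConfig, data.get("segment", {}), "segment"),
        geometry=_build(ChipGeometry, data.get("geometry", {}), "geometry"),
        health=_build_health(data["health"]) if "health" in data else HealthThresholds(),
        log_level=str(logging_sec.get("level", "INFO")),
        log_file=logging_sec.get("file"),
        seed=data.get("seed"),
    )
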