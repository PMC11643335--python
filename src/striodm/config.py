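"""Scenario configuration: YAML parsing, schema validation, seed derivation."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._utils import derive_seed
from .exceptions import InvalidParameterError

__all__ = ["ScenarioConfig", "load_config", "ValidationError", "KNOWN_SCENARIOS"]

KNOWN_SCENARIOS = (
    "psychometric_sweep",
    "prediction_error",
    "rebound",
    "dimensionality_map",
    "incubation",
    "synchrony_calibration",
)

#: required top-level keys and their expected types
_SCHEMA = {"scenario": str, "seed": int, "output_dir": str}


class ValidationError(InvalidParameterError):
    """Config violates the scenario schema; message lists offending keys."""


@dataclass
class ScenarioConfig:
    """A validated scenario: name, master seed, output dir, free parameters."""

    scenario: str
    seed: int
    output_dir: str
    params: dict = field(default_factory=dict)
    source_text: str = ""

    def derived_seed(self, operation: str) -> int:
        """Seed for a named operation, derived from the master seed."""
        return derive_seed(self.seed, f"{self.scenario}/{operation}")

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()


def validate_mapping(data: dict) -> list[str]:
    problems = []
    for key, typ in _SCHEMA.items():
        if key not in data:
            problems.append(f"missing required key: {key}")
        elif not isinstance(data[key], typ):
            problems.append(f"key {key!r} must be {typ.__name__}, got {type(data[key]).__name__}")
    if "scenario" in data and data.get("scenario") not in KNOWN_SCENARIOS:
        problems.append(
            f"unknown scenario {data.get('scenario')!r}; choose one of {', '.join(KNOWN_SCENARIOS)}"
        )
    params = data.get("params", {})
    if not isinstance(params, dict):
        problems.append("key 'params' must be a mapping")
    return problems


def load_config(path) -> ScenarioConfig:
    """Parse and validate a YAML scenario config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError("config must be a YAML mapping")
    problems = validate_mapping(data)
    if problems:
        raise ValidationError("; ".join(problems))
    return ScenarioConfig(
        scenario=data["scenario"],
        seed=data["seed"],
        output_dir=data["output_dir"],
        params=data.get("params", {}),
        source_text=text,
    )
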