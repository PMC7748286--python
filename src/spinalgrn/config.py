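"""Run configuration: structured text files (JSON / TOML) -> validated objects.

An empty file reproduces the reference setup: balance-preset signaling
constants, the curated TF Hill constants, the standard 2500 um / 6000 min
grid. Sections ``[signaling]``, ``[tf]``, ``[grid]``, ``[classifier]`` and
``[perturbation]`` override individual fields by name; unknown keys and
out-of-range values fail fast with the offending field path.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Union

from .perturb import PerturbationKind, PerturbationSpec
from .regimes import ClassifierConfig
from .signaling import DomainGrid, SignalingParams
from .tfnet import TFParams

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration parse/validation failure, carrying the field path."""


@dataclass
class RunConfig:
    """Fully validated configuration of one run."""

    signaling: SignalingParams = field(default_factory=SignalingParams)
    tf: TFParams = field(default_factory=TFParams)
    grid: DomainGrid = field(default_factory=DomainGrid)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    perturbation: Optional[PerturbationSpec] = None
    seeds: List[int] = field(default_factory=lambda: [0])
    domain_threshold: float = 0.1
    output_dir: Path = Path("results")


_SECTIONS = {
    "signaling": SignalingParams,
    "tf": TFParams,
    "grid": DomainGrid,
    "classifier": ClassifierConfig,
    "perturbation": PerturbationSpec,
}
_TOP_LEVEL = {"seeds", "domain_threshold", "output_dir"}


def _build_section(name: str, cls, values: Dict[str, Any]):
    if not isinstance(values, dict):
        raise ConfigError(f"section [{name}] must be a table/object")
    known = {f.name for f in dataclasses.fields(cls)}
    for key in values:
        if key not in known:
            raise ConfigError(f"unknown key {name}.{key}")
    if cls is PerturbationSpec and "kind" in values:
        try:
            values = {**values, "kind": PerturbationKind(values["kind"])}
        except ValueError as exc:
            raise ConfigError(f"invalid value for perturbation.kind: {exc}") from exc
    try:
        return cls(**values)
    except (TypeError, ValueError) as exc:
        # name the first offending field if the message carries it
        culprit = next((k for k in values if k in str(exc)), None)
        where = f"{name}.{culprit}" if culprit else f"section [{name}]"
        raise ConfigError(f"invalid value for {where}: {exc}") from exc


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a JSON or TOML run configuration.

    An empty file (or empty object) yields all defaults. Raises
    :class:`ConfigError` naming the offending field for parse errors,
    unknown keys and out-of-range values.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        try:
            data = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a table/object")

    kwargs: Dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _build_section(key, _SECTIONS[key], value)
        elif key == "seeds":
            if not isinstance(value, list) or not all(isinstance(s, int) for s in value):
                raise ConfigError("seeds must be a list of integers")
            kwargs["seeds"] = value
        elif key == "domain_threshold":
            if not 0 < float(value) <= 1:
                raise ConfigError("domain_threshold must be in (0, 1]")
            kwargs["domain_threshold"] = float(value)
        elif key == "output_dir":
            kwargs["output_dir"] = Path(str(value))
        else:
            raise ConfigError(f"unknown key {key}")
    return RunConfig(**kwargs)
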