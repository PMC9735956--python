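"""Run configuration: one YAML document governs all pipeline stages.

Every physical and statistical parameter of the generator, signal
processing, feature extraction and classifier has a config key with the
package default; a stable SHA-256 hash of the resolved configuration is
embedded in every output file so any stage can be traced back to the
exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, is_dataclass
from typing import Any, List, Sequence

import yaml

from .classify import EvaluationConfig
from .processing import SlopeBand
from .simulate import CohortConfig

__all__ = [
    "ProcessingConfig",
    "FeatureConfig",
    "ClassifyConfig",
    "RunConfig",
    "default_run_config",
    "run_config_from_dict",
    "load_run_config",
    "save_run_config",
    "config_to_dict",
    "config_hash",
]

DEFAULT_PREDICTOR_SETS: List[List[str]] = [
    ["S_Start"],
    ["S_Elev"],
    ["S_Phys"],
    ["S_Elev", "S_Phys"],
]


@dataclass(frozen=True)
class ProcessingConfig:
    cutoff_thz: float = 0.1
    regularization: float = 1e-3
    band: SlopeBand = SlopeBand()


@dataclass(frozen=True)
class FeatureConfig:
    window_min: float = 30.0


@dataclass(frozen=True)
class ClassifyConfig:
    evaluation: EvaluationConfig = EvaluationConfig()
    predictor_sets: Sequence[Sequence[str]] = field(
        default_factory=lambda: [list(s) for s in DEFAULT_PREDICTOR_SETS]
    )


@dataclass(frozen=True)
class RunConfig:
    simulate: CohortConfig = CohortConfig()
    process: ProcessingConfig = ProcessingConfig()
    features: FeatureConfig = FeatureConfig()
    classify: ClassifyConfig = ClassifyConfig()
    seed: int = 0
    log_level: str = "INFO"


def default_run_config() -> RunConfig:
    return RunConfig()


def _merge_dataclass(obj: Any, overrides: dict) -> Any:
    """Recursively rebuild a (frozen) dataclass with override values."""
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(obj)}
    unknown = set(overrides) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys for {type(obj).__name__}: {sorted(unknown)}")
    for name, f in fields.items():
        current = getattr(obj, name)
        if name not in overrides:
            kwargs[name] = current
            continue
        value = overrides[name]
        if is_dataclass(current) and isinstance(value, dict):
            kwargs[name] = _merge_dataclass(current, value)
        elif name == "group_sizes" and isinstance(value, dict):
            kwargs[name] = {float(k): int(v) for k, v in value.items()}
        else:
            kwargs[name] = value
    return type(obj)(**kwargs)


def run_config_from_dict(overrides: dict) -> RunConfig:
    """Defaults overridden by a (possibly partial) nested dict."""
    return _merge_dataclass(default_run_config(), overrides or {})


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return run_config_from_dict(data or {})


def config_to_dict(cfg: Any) -> Any:
    """JSON/YAML-serialisable view of a config dataclass."""
    if is_dataclass(cfg) and not isinstance(cfg, type):
        return {f.name: config_to_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, dict):
        return {str(k): config_to_dict(v) for k, v in cfg.items()}
    if isinstance(cfg, (list, tuple)):
        return [config_to_dict(v) for v in cfg]
    if hasattr(cfg, "item"):  # numpy scalar
        return cfg.item()
    return cfg


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: Any) -> str:
    """SHA-256 over the canonical JSON form of a configuration."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
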