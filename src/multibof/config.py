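"""Run configuration: declarative file (JSON/YAML) with validated defaults."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class RunConfig(BaseModel):
    """Validated settings shared by all subcommands.

    Unknown keys are rejected rather than silently ignored.
    """

    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    model_path: str | None = None
    bof_paths: list[str] = Field(default_factory=list)
    measurement_set_path: str | None = None
    method: str = "fixed"
    environment: dict[str, float] = Field(default_factory=dict)
    environment_mode: str = "fixed"
    solver_tolerance: float = 1e-9
    epsilon: float = 1e-3
    k_max: int = 100
    clamp_fraction: float = 0.01
    unconstrained_value: float = 1000.0
    relative_acetate_cap: float = 10.0
    output_dir: str = "."
    seed: int = 0

    @field_validator("solver_tolerance", "epsilon")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator("k_max")
    @classmethod
    def _nonnegative_int(cls, v: int) -> int:
        if v < 0:
            raise ValueError(f"k_max must be >= 0, got {v}")
        return v

    @field_validator("clamp_fraction", "unconstrained_value", "relative_acetate_cap")
    @classmethod
    def _nonnegative(cls, v: float, info) -> float:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    @field_validator("environment_mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("fixed", "upper_bound"):
            raise ValueError(f"environment_mode must be fixed|upper_bound, got {v!r}")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a config file (JSON or YAML by extension); missing path means all
    defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text) or {}
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return RunConfig(**data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
    else:
        path.write_text(json.dumps(config.model_dump(), indent=1, sort_keys=True) + "\n")
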