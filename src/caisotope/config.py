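"""Run configuration: one YAML file driving the whole pipeline.

Every stochastic operation receives an explicit seed; a configuration
without a seed is rejected so that runs are reproducible by construction.
The config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .baseline import BaselineMode
from .cohort import BoneResponseParams, CohortParams
from .rayleigh import DEFAULT_ALPHA

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def _build(cls, payload: dict, where: str):
    if not isinstance(payload, dict):
        raise ConfigError(f"config section {where!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(payload) - known)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where!r}: {', '.join(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in {where!r}: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (generator + analysis parameters)."""

    seed: int
    n_subjects: int = 7
    cohort: CohortParams = field(default_factory=CohortParams)
    bone: BoneResponseParams = field(default_factory=BoneResponseParams)
    alpha: float = DEFAULT_ALPHA
    noise_se: float = 0.05
    include_ntx: bool = True
    confidence_level: float = 0.95
    alpha_level: float = 0.05
    baseline_mode: str = BaselineMode.SEMILOG_DELTA.value

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("an explicit integer 'seed' is required")
        if not isinstance(self.seed, int):
            raise ConfigError(f"'seed' must be an integer, got {self.seed!r}")
        if self.n_subjects < 0:
            raise ConfigError(f"'n_subjects' must be >= 0, got {self.n_subjects}")
        if self.noise_se < 0:
            raise ConfigError(f"'noise_se' must be >= 0, got {self.noise_se}")
        try:
            BaselineMode(self.baseline_mode)
        except ValueError as exc:
            raise ConfigError(
                f"'baseline_mode' must be one of "
                f"{[m.value for m in BaselineMode]}, got {self.baseline_mode!r}"
            ) from exc

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        if not isinstance(payload, dict):
            raise ConfigError("config must be a mapping")
        payload = dict(payload)
        if "seed" not in payload:
            raise ConfigError("config is missing the required 'seed' field")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        if "cohort" in payload:
            payload["cohort"] = _build(CohortParams, payload["cohort"], "cohort")
        if "bone" in payload:
            payload["bone"] = _build(BoneResponseParams, payload["bone"], "bone")
        try:
            return cls(**payload)
        except ConfigError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid config value: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path, encoding="utf-8") as fh:
                payload = yaml.safe_load(fh)
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
        if payload is None:
            raise ConfigError(f"config file {path} is empty")
        return cls.from_dict(payload)
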