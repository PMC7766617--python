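"""Declarative pipeline configuration (single YAML file, all keys optional)."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .feature_io import ValidationError

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    tol_ppm: float = 5.0
    rt_window_s: float = 5.0
    min_corr: float = 0.8
    seed: int = 0
    alpha: float = 0.05
    efsa_threshold_mg_day: float = 5.0
    min_rel_int: float = 0.01

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0 or self.rt_window_s <= 0:
            raise ValidationError("tolerances must be positive")
        if not -1.0 <= self.min_corr <= 1.0:
            raise ValidationError("min_corr must lie in [-1, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValidationError("config file must contain a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
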