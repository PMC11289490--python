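"""Run configuration: nested, schema-validated, round-trippable records.

Unknown keys are rejected; omitted keys take defaults; `to_dict` /
`from_dict` round-trip unchanged. YAML files map section names to key/value
tables, e.g.::

    training:
      cycles: 2
      batch_size: 4
    loss:
      alpha: 5.0
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["ExtractConfig", "FusionConfig", "LossConfig", "SemanticConfig",
           "TrainingConfig", "MetricsConfig", "RunConfig", "load_config",
           "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _from_dict(cls, data: dict):
    if data is None:
        data = {}
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class ExtractConfig:
    channels: list[int] = field(default_factory=lambda: [16, 32, 64, 128, 256])
    leaky_slope: float = 0.01
    share_weights: bool = False
    n_branches: int = 3
    n_scales: int = 5

    def __post_init__(self):
        if len(self.channels) < self.n_scales:
            raise ConfigError("extract.channels must cover every scale")
        if self.n_branches < 1 or self.n_scales < 1:
            raise ConfigError("branch and scale counts must be positive")


@dataclass
class FusionConfig:
    upsample: str = "bilinear"
    reduction_kernel: int = 1
    use_attention: bool = True

    def __post_init__(self):
        if self.upsample != "bilinear":
            raise ConfigError("only bilinear upsampling is implemented")
        if self.reduction_kernel % 2 != 1:
            raise ConfigError("reduction kernel must be odd")


@dataclass
class LossConfig:
    alpha: float = 5.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ConfigError("loss.alpha must be non-negative")


@dataclass
class SemanticConfig:
    K: int = 8
    feature_dim: int = 32
    hidden: int = 16
    jitter_brightness: float = 0.1
    jitter_contrast: float = 0.1
    jitter_gamma: float = 0.2
    use_geometric: bool = True
    enabled: bool = True

    def __post_init__(self):
        if self.K < 1:
            raise ConfigError("semantic.K must be at least 1")


@dataclass
class TrainingConfig:
    fusion_epochs_per_cycle: int = 20
    seg_epochs_per_cycle: int = 10
    cycles: int = 5
    batch_size: int = 4
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        for name in ("fusion_epochs_per_cycle", "seg_epochs_per_cycle",
                     "cycles", "batch_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"training.{name} must be at least 1")
        if self.learning_rate <= 0:
            raise ConfigError("training.learning_rate must be positive")


@dataclass
class MetricsConfig:
    aggregate: str = "mean"

    def __post_init__(self):
        if self.aggregate not in ("mean", "max"):
            raise ConfigError("metrics.aggregate must be 'mean' or 'max'")


@dataclass
class RunConfig:
    extract: ExtractConfig = field(default_factory=ExtractConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    semantic: SemanticConfig = field(default_factory=SemanticConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    @classmethod
    def from_dict(cls, data: dict | None) -> "RunConfig":
        data = dict(data or {})
        sections = {"extract": ExtractConfig, "fusion": FusionConfig,
                    "loss": LossConfig, "semantic": SemanticConfig,
                    "training": TrainingConfig, "metrics": MetricsConfig}
        unknown = set(data) - set(sections)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        return cls(**{name: _from_dict(section_cls, data.get(name))
                      for name, section_cls in sections.items()})

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def tiny(cls) -> "RunConfig":
        """Desk-scale preset: narrow channels and a faster learning rate for
        short overfit runs on small phantoms."""
        cfg = cls()
        cfg.extract.channels = [8, 12, 16, 24, 32]
        cfg.semantic.K = 4
        cfg.semantic.feature_dim = 16
        cfg.semantic.hidden = 8
        cfg.training.learning_rate = 1e-3
        return cfg


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; None gives all defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data)
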