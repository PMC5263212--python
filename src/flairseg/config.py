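"""Pipeline configuration: every tunable with its study default.

Configs load from YAML; unknown keys are rejected so typos fail loudly. The
effective config is persisted verbatim next to every output so any result
can be regenerated from its directory alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["SuperpixelConfig", "TextonConfig", "FeatureConfig", "SelectConfig",
           "ERTConfig", "PostprocessConfig", "PipelineConfig"]


@dataclass
class SuperpixelConfig:
    S: int = 6
    m: float = 0.2
    n_iter: int = 10


@dataclass
class TextonConfig:
    thetas: list = field(default_factory=lambda: [0.0, 30.0, 45.0, 60.0, 90.0, 120.0])
    sigmas: list = field(default_factory=lambda: [0.3, 0.6, 0.9, 1.2, 1.5])
    lambdas: list = field(default_factory=lambda: [0.8, 1.0, 1.2, 1.5])
    psi: float = 0.0
    gamma: float = 1.0
    k: int = 5
    max_pixels: int = 200_000


@dataclass
class FeatureConfig:
    n_t: int = 3
    scale_hi: float = 30.0
    curvature_sigma: float = 1.0


@dataclass
class SelectConfig:
    n_fea: int = 5
    n_bins: int = 10
    scheme: str = "MID"
    use_preset: bool = False  # skip selection; use the study's 5 named features


@dataclass
class ERTConfig:
    T: int = 20
    K: int = 5
    n_min: int = 2
    max_depth: int = 15
    criterion: str = "entropy"
    class_weight: str | None = None  # e.g. "balanced"; off by default


@dataclass
class PostprocessConfig:
    min_region_voxels: int = 100
    connectivity: int = 26
    threshold: float = 0.5


@dataclass
class PipelineConfig:
    superpixel: SuperpixelConfig = field(default_factory=SuperpixelConfig)
    texton: TextonConfig = field(default_factory=TextonConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    select: SelectConfig = field(default_factory=SelectConfig)
    ert: ERTConfig = field(default_factory=ERTConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    seed: int = 0
    reference_case: str | None = None  # histogram-matching reference; default first case

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        sections = {f.name: f for f in fields(cls)}
        for key, val in d.items():
            if key not in sections:
                raise ValueError(f"unknown config key: {key!r}")
            if isinstance(val, dict):
                sub = getattr(cfg, key)
                known = {f.name for f in fields(sub)}
                for sk, sv in val.items():
                    if sk not in known:
                        raise ValueError(f"unknown config key: {key}.{sk}")
                    setattr(sub, sk, sv)
            else:
                setattr(cfg, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
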