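"""Run configuration: every tunable of the pipeline with defaults.

Loaded from a YAML file and/or CLI flag overrides; unknown keys are
rejected.  The effective configuration is embedded verbatim in every run
report.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NormalizeConfig(_Strict):
    p_low: float = Field(0.01, ge=0, lt=0.5)
    p_high: float = Field(0.01, ge=0, lt=0.5)


class StainsConfig(_Strict):
    hematoxylin: tuple[float, float, float] = (0.650, 0.704, 0.286)
    eosin: tuple[float, float, float] = (0.072, 0.990, 0.105)


class FeatureConfig(_Strict):
    channel: str = "eosin"  # eosin | hematoxylin | luminance


class CoarseConfig(_Strict):
    model_class: str = "similarity"  # translation | rigid | similarity | affine
    ratio: float = Field(0.8, gt=0, le=1)
    inlier_tol: float = Field(3.0, gt=0)
    max_iters: int = Field(2000, ge=1)
    seed: int = 0


class ElasticConfig(_Strict):
    spacing_px: float = Field(16.0, gt=0)
    pyramid_levels: int = Field(3, ge=1)
    w_img: float = Field(1.0, gt=0)
    w_div: float = Field(0.1, ge=0)
    w_rot: float = Field(0.1, ge=0)
    w_cons: float = Field(1.0, ge=0)
    max_iters: int = Field(200, ge=1)
    tol: float = Field(1e-5, gt=0)
    cons_stride: int = Field(4, ge=1)
    img_stride: int = Field(2, ge=1)


class StackConfig(_Strict):
    reference: str = "middle"  # middle | first | index:k
    alpha: float = Field(50.0, ge=0)


class ValidateConfig(_Strict):
    scope: str = "total"  # total | elastic_only


class MetricConfig(_Strict):
    t: int = Field(200, ge=1, le=255)
    bg_tol: int = Field(0, ge=0, le=254)
    symmetric: bool = False


class RunConfig(_Strict):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    seed: int = 0
    verbosity: int = 1
    normalize: NormalizeConfig = NormalizeConfig()
    stains: StainsConfig = StainsConfig()
    feature: FeatureConfig = FeatureConfig()
    coarse: CoarseConfig = CoarseConfig()
    elastic: ElasticConfig = ElasticConfig()
    stack: StackConfig = StackConfig()
    validation: ValidateConfig = Field(ValidateConfig(), alias="validate")
    metric: MetricConfig = MetricConfig()

    def as_dict(self) -> dict:
        return self.model_dump(by_alias=True)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus dotted overrides.

    Overrides are {'stack.alpha': 0.0, ...}; flags win over the file.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data = loaded
    for key, value in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
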