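"""YAML configuration schema for the pipeline.

One flat document with blocks {simulate, preprocess, features, hcsae,
balstm, train, evaluate} plus a root seed; every field is validated
against its documented domain, and violations report the offending field
path. Defaults pin the reference training recipe (batch 64, learning rate
1e-3, decay 0.9 every 20 epochs, 200 epochs, 64 hidden LSTM units).
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .types import ConfigurationError


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateBlock(_Block):
    preset: Optional[Literal["repod-like", "nnci-like"]] = None
    n_subjects_per_group: int = Field(default=10, ge=1)
    duration_s: float = Field(default=60.0, gt=0)
    fs: float = Field(default=128.0, gt=0)
    montage_name: Literal["std19", "std16"] = "std16"
    band: Literal["delta", "theta", "alpha", "beta", "gamma"] = "alpha"
    power_ratio: float = Field(default=3.0, gt=0)
    corr_shift: float = Field(default=0.2, ge=-1.0, le=1.0)
    noise_sd: float = Field(default=1.0, ge=0)


class PreprocessBlock(_Block):
    low: float = Field(default=0.0, ge=0)
    high: float = Field(default=100.0, gt=0)
    win_s: float = Field(default=2.0, gt=0)
    stride_s: float = Field(default=1.0, gt=0)
    train_frac: float = Field(default=0.8, gt=0, lt=1)
    undersample_to: Optional[int] = Field(default=None, ge=1)
    harmonize: bool = True


class FeaturesBlock(_Block):
    mode: Literal["wpt", "cwt"] = "wpt"
    wavelet: str = "db4"
    depth: int = Field(default=3, ge=1, le=8)
    n_components: Optional[int] = Field(default=None, ge=1)
    ica_max_samples: int = Field(default=50_000, ge=1000)


class HCSAEBlock(_Block):
    abstract_channels: int = Field(default=32, ge=2)
    n_1x3_layers: int = Field(default=2, ge=0)
    dropout_q: float = Field(default=0.3, ge=0, lt=1)
    latent_channels: int = Field(default=64, ge=1)
    recon_weight: float = Field(default=0.1, ge=0)

    @model_validator(mode="after")
    def _even(self):
        if self.abstract_channels % 2:
            raise ValueError("abstract_channels must be even")
        return self


class BALSTMBlock(_Block):
    hidden: int = Field(default=64, ge=1)
    layers: int = Field(default=3, ge=2)


class TrainBlock(_Block):
    lr: float = Field(default=1e-3, gt=0)
    batch: int = Field(default=64, ge=1)
    epochs: int = Field(default=200, ge=1)
    decay: float = Field(default=0.9, gt=0, le=1)
    decay_every: int = Field(default=20, ge=1)
    seq_len: int = Field(default=32, ge=2)


class EvaluateBlock(_Block):
    subject_threshold: float = Field(default=0.95, ge=0, lt=1)


class PipelineConfig(_Block):
    seed: int = 0
    out_dir: str = "run"
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)
    preprocess: PreprocessBlock = Field(default_factory=PreprocessBlock)
    features: FeaturesBlock = Field(default_factory=FeaturesBlock)
    hcsae: HCSAEBlock = Field(default_factory=HCSAEBlock)
    balstm: BALSTMBlock = Field(default_factory=BALSTMBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    evaluate: EvaluateBlock = Field(default_factory=EvaluateBlock)


def load_config(path) -> PipelineConfig:
    """Parse + validate a YAML config; raises ConfigurationError with the
    offending field path on schema violations."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> PipelineConfig:
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigurationError("invalid config:\n  " + "\n  ".join(lines)) from exc


def default_recipe() -> PipelineConfig:
    """The shipped default recipe (data/defaults.yaml)."""
    with resources.files("mdefusion.data").joinpath("defaults.yaml").open() as fh:
        return validate_config(yaml.safe_load(fh) or {})
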