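"""Run configuration: nested, validated blocks mirroring each module's knobs.

YAML or JSON files load into :class:`RunConfig`; unknown keys are rejected
with the offending key named, and every block validates its invariants
before any work starts. A single global seed fans out deterministically to
per-module seeds (BLAKE2 hash of ``seed:module``), so each stage stays
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ClaheBlock(_Block):
    enabled: bool = True
    tile_rows: int = Field(8, ge=1)
    tile_cols: int = Field(8, ge=1)
    n_gray_levels: int = Field(256, ge=2)
    clip_factor: float = Field(40.0, ge=0)
    max_slope: float = Field(4.0, ge=1)


class AugmentationBlock(_Block):
    enabled: bool = True
    rotation_deg: tuple[float, float] = (-45.0, 45.0)
    zoom: tuple[float, float] = (-0.08, 0.08)
    horizontal_flip: bool = True
    width_shift_frac: float = Field(0.15, ge=0, le=1)
    height_shift_frac: float = Field(0.15, ge=0, le=1)
    shear: tuple[float, float] = (-0.03, 0.03)
    brightness: tuple[float, float] = (0.99, 1.07)

    @field_validator("rotation_deg", "zoom", "shear", "brightness")
    @classmethod
    def _ordered(cls, v):
        if v[0] > v[1]:
            raise ValueError("interval lower bound exceeds upper bound")
        return v


class ModelBlock(_Block):
    variant: str = "sharp_attention"
    depth: int = Field(4, ge=1)
    base_filters: int = Field(16, ge=1)
    activation: str = "swish"
    leaky_slope: float = 0.1
    dropout_encoder: float = Field(0.1, ge=0, lt=1)
    dropout_decoder: float = Field(0.5, ge=0, lt=1)
    input_side: int = Field(128, ge=1)


class TrainingBlock(_Block):
    epochs: int = Field(300, ge=1)
    batch_size: int = Field(32, ge=1)
    learning_rate: float = Field(0.001, gt=0)
    beta1: float = 0.9
    beta2: float = 0.9
    adam_epsilon: float = 1e-7
    early_stop_patience: int = Field(50, ge=1)
    threshold: float = Field(0.4, gt=0, lt=1)
    derive_threshold: bool = False
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)


class ComparisonBlock(_Block):
    alpha_family: float = Field(0.1, gt=0, lt=1)
    exact: bool = False


class SynthBlock(_Block):
    n_normal: int = Field(34, ge=0)
    n_benign: int = Field(112, ge=0)
    n_malignant: int = Field(54, ge=0)


class RunConfig(_Block):
    seed: int = 0
    log_level: str = "INFO"
    clahe: ClaheBlock = ClaheBlock()
    augmentation: AugmentationBlock = AugmentationBlock()
    model: ModelBlock = ModelBlock()
    training: TrainingBlock = TrainingBlock()
    comparison: ComparisonBlock = ComparisonBlock()
    synth: SynthBlock = SynthBlock()

    def module_seed(self, module: str) -> int:
        """Deterministic per-module seed derived from the global seed."""
        digest = hashlib.blake2s(f"{self.seed}:{module}".encode(),
                                 digest_size=4).digest()
        return int.from_bytes(digest, "big") % (2**31 - 1)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def load_config(path=None) -> RunConfig:
    """Load YAML/JSON into a validated RunConfig; missing file keys default."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    return RunConfig.model_validate(data or {})


def to_objects(cfg: RunConfig):
    """Instantiate the dataclass configs of the worker modules."""
    from .augmentation import AugmentationConfig
    from .architectures import ModelSpec
    from .enhancement import ClaheConfig
    from .training_eval import TrainingConfig

    clahe = ClaheConfig(tile_rows=cfg.clahe.tile_rows, tile_cols=cfg.clahe.tile_cols,
                        n_gray_levels=cfg.clahe.n_gray_levels,
                        clip_factor=cfg.clahe.clip_factor,
                        max_slope=cfg.clahe.max_slope) if cfg.clahe.enabled else None
    aug = AugmentationConfig(
        rotation_deg=cfg.augmentation.rotation_deg, zoom=cfg.augmentation.zoom,
        horizontal_flip=cfg.augmentation.horizontal_flip,
        width_shift_frac=cfg.augmentation.width_shift_frac,
        height_shift_frac=cfg.augmentation.height_shift_frac,
        shear=cfg.augmentation.shear, brightness=cfg.augmentation.brightness,
    ) if cfg.augmentation.enabled else None
    spec = ModelSpec(variant=cfg.model.variant, depth=cfg.model.depth,
                     base_filters=cfg.model.base_filters,
                     activation=cfg.model.activation,
                     dropout_encoder=cfg.model.dropout_encoder,
                     dropout_decoder=cfg.model.dropout_decoder,
                     input_side=cfg.model.input_side)
    tcfg = TrainingConfig(epochs=cfg.training.epochs,
                          batch_size=cfg.training.batch_size,
                          learning_rate=cfg.training.learning_rate,
                          beta1=cfg.training.beta1, beta2=cfg.training.beta2,
                          adam_epsilon=cfg.training.adam_epsilon,
                          early_stop_patience=cfg.training.early_stop_patience,
                          seed=cfg.module_seed("training"))
    return clahe, aug, spec, tcfg
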