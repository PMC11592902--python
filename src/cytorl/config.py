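"""Structured run configuration: one YAML file wiring every component.

Validation is strict (unknown keys rejected, every constraint checked before
any work starts) because most hyperparameters here are under-documented in
the literature this model family comes from — silent defaults would be
unauditable.  Errors name the offending key in dotted form (e.g.
``rl.gamma``).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .backbone import BackboneConfig, StageConfig as BackboneStage
from .data import AugmentConfig, PreprocConfig, SplitSpec
from .model import ModelConfig
from .pipeline import StageConfig
from .rl import RLConfig
from .supporter import SupporterConfig
from .vit import EncoderConfig, PatchConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataSection(_Strict):
    target_size: tuple[int, int] = (32, 32)
    grayscale: bool = True
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    kfold: int = 5
    augment: bool = True
    rotation_max_deg: float = 20.0
    hflip: bool = True
    vflip: bool = True
    zoom_range: tuple[float, float] = (0.9, 1.1)
    shift_fraction: float = 0.1


class BackboneStageSection(_Strict):
    block_type: str
    repeats: int = 1
    channels: int = 8
    stride: int = 2
    expansion: int = 2


class BackboneSection(_Strict):
    stages: list[BackboneStageSection] | None = None
    in_channels: int = 1
    supporter_insertion: list[bool] | None = None


class VitSection(_Strict):
    patch_size: int = 2
    embed_dim: int = 16
    depth: int = 2
    heads: int = 2
    ffn_dim: int = 32


class SupporterSection(_Strict):
    stack_depth: int = 3
    kernel: tuple[int, int, int] = (3, 3, 3)
    lstm_hidden: int = 8
    attention_dim: int = 8
    max_seq_hw: int = 4


class RLSection(_Strict):
    gamma: float = 0.9
    lr: float = 1e-2
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_steps: int = 100
    replay_capacity: int = 2048
    batch_size: int = 32
    target_sync_period: int = 100
    beta: float = 1.2
    w_min: float = 0.25
    w_max: float = 4.0
    minority_classes: list[int] | None = None  # default: frequency < 1/C
    delta: float = 0.1                         # correct-majority reward

    @field_validator("gamma")
    @classmethod
    def _gamma_range(cls, v):
        if not (0.0 <= v < 1.0):
            raise ValueError("gamma must be in [0, 1)")
        return v

    @field_validator("delta")
    @classmethod
    def _delta_range(cls, v):
        if not (0.0 < v < 1.0):
            raise ValueError("delta must be in (0, 1)")
        return v


class TrainingSection(_Strict):
    stage1_epochs: int = 8
    stage2_epochs: int = 20
    batch_size: int = 16
    stage1_lr: float = 3e-3
    stage2_lr: float = 2e-3


class RunConfig(_Strict):
    seed: int = 0
    n_classes: int = 2
    out_dir: str = "runs"
    data: DataSection = DataSection()
    backbone: BackboneSection = BackboneSection()
    vit: VitSection = VitSection()
    supporter: SupporterSection = SupporterSection()
    rl: RLSection = RLSection()
    training: TrainingSection = TrainingSection()

    # ------------------------------------------- dataclass materialisation
    def preproc_config(self) -> PreprocConfig:
        return PreprocConfig(tuple(self.data.target_size), True, self.data.grayscale)

    def augment_config(self) -> AugmentConfig | None:
        if not self.data.augment:
            return None
        return AugmentConfig(self.data.rotation_max_deg, self.data.hflip,
                             self.data.vflip, tuple(self.data.zoom_range),
                             self.data.shift_fraction, self.seed)

    def split_spec(self) -> SplitSpec:
        return SplitSpec(tuple(self.data.fractions), self.seed)

    def model_config_(self) -> ModelConfig:
        if self.backbone.stages is None:
            from .backbone import default_stages
            stages = default_stages()
        else:
            stages = tuple(BackboneStage(s.block_type, s.repeats, s.channels,
                                         s.stride, s.expansion)
                           for s in self.backbone.stages)
        bb = BackboneConfig(
            stages, self.backbone.in_channels, tuple(self.data.target_size),
            tuple(self.backbone.supporter_insertion)
            if self.backbone.supporter_insertion else None,
        )
        return ModelConfig(
            n_classes=self.n_classes, backbone=bb,
            patch=PatchConfig(self.vit.patch_size, self.vit.embed_dim),
            encoder=EncoderConfig(self.vit.depth, self.vit.heads, self.vit.ffn_dim),
            supporter=SupporterConfig(self.supporter.stack_depth,
                                      tuple(self.supporter.kernel),
                                      self.supporter.lstm_hidden,
                                      self.supporter.attention_dim,
                                      self.supporter.max_seq_hw),
            seed=self.seed,
        )

    def rl_config(self) -> RLConfig:
        r = self.rl
        return RLConfig(r.gamma, r.lr, r.epsilon_start, r.epsilon_end,
                        r.epsilon_decay_steps, r.replay_capacity, r.batch_size,
                        r.target_sync_period, r.beta, r.w_min, r.w_max)

    def stage_config(self, stage: str) -> StageConfig:
        t = self.training
        if stage == "stage1":
            return StageConfig(t.stage1_epochs, t.batch_size, t.stage1_lr,
                               self.seed, "stage1")
        return StageConfig(t.stage2_epochs, t.batch_size, t.stage2_lr,
                           self.seed + 1, "stage2")


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def load_config(path: Path | str | None = None, overrides: dict | None = None
                ) -> RunConfig:
    """Load and validate a YAML config; missing keys take defaults."""
    payload: dict = {}
    if path is not None:
        text = Path(path).read_text()
        payload = yaml.safe_load(text) or {}
    if overrides:
        payload.update(overrides)
    try:
        return RunConfig(**payload)
    except ValidationError as exc:
        raise ValueError(
            f"invalid configuration: {_format_validation_error(exc)}"
        ) from exc


def dump_config(cfg: RunConfig, path: Path | str) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
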