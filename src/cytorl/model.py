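"""The full classifier: conv backbone + ViT encoder + supporter + fusion head.

The backbone extracts a local feature map F_CNN; the ViT encoder turns it
into contextual patch tokens; the supporter pathway condenses multi-stage
maps into a context vector.  The fusion head classifies the concatenation
of a global CNN summary, the mean token and the context vector.  The ViT's
own concatenated-patch head remains available as an auxiliary output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .backbone import Backbone, BackboneConfig
from .supporter import FusionHead, Supporter, SupporterConfig
from .vit import EncoderConfig, PatchConfig, ViTEncoder

__all__ = ["ModelConfig", "CytologyClassifier"]


@dataclass(frozen=True)
class ModelConfig:
    n_classes: int = 2
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    patch: PatchConfig = field(default_factory=PatchConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    supporter: SupporterConfig = field(default_factory=SupporterConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


class CytologyClassifier(nn.Module):
    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        # derive each component's seed from the model seed so one integer
        # reproduces the whole parameterisation
        ss = np.random.SeedSequence(cfg.seed)
        s_bb, s_vit, s_sup, s_head = (int(c.generate_state(1)[0] % 2**31)
                                      for c in ss.spawn(4))
        self.backbone = Backbone(
            BackboneConfig(cfg.backbone.stages, cfg.backbone.in_channels,
                           cfg.backbone.input_size, cfg.backbone.supporter_insertion,
                           seed=s_bb)
        )
        fmap_hw = self.backbone.config.out_spatial()
        self.vit = ViTEncoder(
            self.backbone.config.out_channels, fmap_hw, cfg.patch,
            EncoderConfig(cfg.encoder.depth, cfg.encoder.heads,
                          cfg.encoder.ffn_dim, seed=s_vit),
            cfg.n_classes,
        )
        self.supporter = Supporter(
            SupporterConfig(cfg.supporter.stack_depth, cfg.supporter.kernel,
                            cfg.supporter.lstm_hidden, cfg.supporter.attention_dim,
                            cfg.supporter.max_seq_hw, seed=s_sup)
        )
        head_rng = np.random.default_rng(s_head)
        self.head = FusionHead(
            self.backbone.config.out_channels, cfg.patch.embed_dim,
            self.supporter.context_dim, cfg.n_classes, head_rng,
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_detail(x)["probs"]

    def forward_detail(self, x: Tensor) -> dict[str, Tensor]:
        f_cnn, stage_outputs = self.backbone.forward_with_stages(x)
        tokens = self.vit.encode(f_cnn)
        alpha, context = self.supporter(stage_outputs)
        probs = self.head(f_cnn, tokens, context)
        return {
            "probs": probs,
            "logits": self.head.logits(f_cnn, tokens, context),
            "tokens": tokens,
            "f_cnn": f_cnn,
            "attention": alpha,
            "context": context,
        }

    def aux_vit_probs(self, x: Tensor) -> Tensor:
        """The transformer's own concatenated-patch classification head."""
        f_cnn = self.backbone(x)
        return self.vit(f_cnn)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        probs = self.forward(Tensor(np.asarray(batch))).data
        return probs.argmax(axis=1)

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(np.asarray(batch))).data
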