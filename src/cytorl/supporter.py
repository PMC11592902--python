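"""Supporter pathway: Conv3D aggregation, BiLSTM encoding, attention pooling.

Feature maps from different network stages are channel-averaged, pooled to a
common spatial size and stacked along a depth axis (depth = provenance, not
a volumetric z-stack).  A same-padded 3-D convolution mixes information
across depth and space; the result is read out as a row-major raster
sequence of depth-dimensional vectors and encoded by a bidirectional LSTM.
Additive attention (e_t = v^T tanh(W_h h_t + b_h)) pools the BiLSTM outputs
into a context vector c = sum_t alpha_t h_t, which the fusion head
concatenates with global summaries of the CNN map and transformer tokens
before the final softmax.  A 1x1 projection is available to send a
recalibrated map back onto a residual stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat, stack
from .nn.functional import avg_pool2d, conv3d_same

__all__ = [
    "SupporterConfig", "stack_feature_maps", "conv3d_aggregate", "BiLSTM",
    "AttentionPool", "project_residual", "Conv1x1Projection", "FusionHead",
    "Supporter",
]


@dataclass(frozen=True)
class SupporterConfig:
    stack_depth: int = 3            # how many trailing stage outputs to stack
    kernel: tuple[int, int, int] = (3, 3, 3)
    lstm_hidden: int = 8
    attention_dim: int = 8
    max_seq_hw: int = 4             # raster side length cap before the BiLSTM
    seed: int = 0

    def __post_init__(self):
        if min(self.stack_depth, self.lstm_hidden, self.attention_dim,
               self.max_seq_hw) <= 0:
            raise ValueError("supporter dimensions must be positive")
        if any(k % 2 == 0 or k <= 0 for k in self.kernel):
            raise ValueError("conv3d kernel sides must be odd and positive")


def stack_feature_maps(stage_outputs: list[Tensor], cfg: SupporterConfig) -> Tensor:
    """Build the (N, D, H, W) volume from the last ``stack_depth`` stage maps.

    Each map is channel-averaged to a single plane and average-pooled to the
    smallest (coarsest) spatial size among the selected stages, capped at
    ``max_seq_hw`` to bound the raster sequence the BiLSTM consumes.
    """
    if not stage_outputs:
        raise ValueError("no stage outputs to stack")
    chosen = stage_outputs[-cfg.stack_depth:]
    target_h = min(min(t.shape[2] for t in chosen), cfg.max_seq_hw)
    target_w = min(min(t.shape[3] for t in chosen), cfg.max_seq_hw)
    planes = []
    for t in chosen:
        plane = t.mean(axis=1, keepdims=True)  # (N, 1, H, W)
        h, w = plane.shape[2], plane.shape[3]
        if h % target_h or w % target_w:
            raise ValueError(
                f"stage map {h}x{w} not reducible to {target_h}x{target_w}"
            )
        if (h, w) != (target_h, target_w):
            plane = avg_pool2d(plane, h // target_h)
        planes.append(plane)
    return concat(planes, axis=1)  # (N, D, H, W)


def conv3d_aggregate(volume: Tensor, conv: nn.Conv3dSame) -> Tensor:
    """Same-padded linear 3-D convolution plus bias over the stacked volume."""
    return conv(volume)


class BiLSTM(nn.Module):
    """Encode a (N, T, F) sequence to (N, T, 2*hidden), forward ⊕ backward."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.fwd = nn.LSTMCell(in_dim, hidden, rng)
        self.bwd = nn.LSTMCell(in_dim, hidden, rng)

    def forward(self, seq: Tensor) -> Tensor:
        n, t, f = seq.shape
        if t < 1:
            raise ValueError("empty sequence")
        h = Tensor(np.zeros((n, self.hidden)))
        c = Tensor(np.zeros((n, self.hidden)))
        fwd_states = []
        for step in range(t):
            h, c = self.fwd(seq[:, step, :], h, c)
            fwd_states.append(h)
        h = Tensor(np.zeros((n, self.hidden)))
        c = Tensor(np.zeros((n, self.hidden)))
        bwd_states: list[Tensor] = [None] * t  # type: ignore[list-item]
        for step in reversed(range(t)):
            h, c = self.bwd(seq[:, step, :], h, c)
            bwd_states[step] = h
        both = [concat([f_, b_], axis=-1) for f_, b_ in zip(fwd_states, bwd_states)]
        return stack(both, axis=1)  # (N, T, 2*hidden)


class AttentionPool(nn.Module):
    """Additive attention over time: alpha = softmax(v^T tanh(W h + b))."""

    def __init__(self, in_dim: int, attn_dim: int, rng: np.random.Generator):
        self.wh = nn.Linear(in_dim, attn_dim, rng)
        self.v = nn.Parameter(rng.normal(0.0, 1.0 / np.sqrt(attn_dim),
                                         size=(attn_dim, 1)))

    def forward(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """h: (N, T, F) -> (weights (N, T), context (N, F))."""
        scores = (self.wh(h).tanh() @ self.v).reshape(h.shape[0], h.shape[1])
        alpha = scores.softmax(axis=-1)
        n, t = alpha.shape
        context = (h * alpha.reshape(n, t, 1)).sum(axis=1)
        return alpha, context


class Conv1x1Projection(nn.Module):
    """Channel-mixing 1x1 convolution used on the residual return path."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv = nn.Conv2d(channels, channels, 1, rng, pad=0)

    def forward(self, fmap: Tensor) -> Tensor:
        return self.conv(fmap)


def project_residual(fmap: Tensor, projection: Conv1x1Projection,
                     residual: Tensor) -> Tensor:
    """1x1-project ``fmap`` and add it onto ``residual`` (same shapes)."""
    out = projection(fmap)
    if out.shape != residual.shape:
        raise ValueError(f"shape mismatch {out.shape} vs {residual.shape}")
    return residual + out


class FusionHead(nn.Module):
    """softmax(W_fc . concat(GAP(F_CNN), mean tokens, c) + b_fc)."""

    def __init__(self, cnn_channels: int, token_dim: int, context_dim: int,
                 n_classes: int, rng: np.random.Generator):
        self.fc = nn.Linear(cnn_channels + token_dim + context_dim, n_classes, rng)

    def forward(self, f_cnn: Tensor, tokens: Tensor, context: Tensor) -> Tensor:
        pooled_cnn = f_cnn.mean(axis=(2, 3))    # (N, C)
        pooled_tok = tokens.mean(axis=1)        # (N, d)
        fused = concat([pooled_cnn, pooled_tok, context], axis=-1)
        return self.fc(fused).softmax(axis=-1)

    def logits(self, f_cnn: Tensor, tokens: Tensor, context: Tensor) -> Tensor:
        pooled_cnn = f_cnn.mean(axis=(2, 3))
        pooled_tok = tokens.mean(axis=1)
        fused = concat([pooled_cnn, pooled_tok, context], axis=-1)
        return self.fc(fused)


class Supporter(nn.Module):
    """Conv3D -> raster sequence -> BiLSTM -> attention pool."""

    def __init__(self, cfg: SupporterConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.conv3d = nn.Conv3dSame(cfg.kernel, rng)
        self.bilstm = BiLSTM(cfg.stack_depth, cfg.lstm_hidden, rng)
        self.pool = AttentionPool(2 * cfg.lstm_hidden, cfg.attention_dim, rng)

    @property
    def context_dim(self) -> int:
        return 2 * self.cfg.lstm_hidden

    def forward(self, stage_outputs: list[Tensor]) -> tuple[Tensor, Tensor]:
        """Return (attention weights, context vector) for the batch."""
        volume = stack_feature_maps(stage_outputs, self.cfg)
        f_conv = conv3d_aggregate(volume, self.conv3d)
        n, d, h, w = f_conv.shape
        seq = f_conv.reshape(n, d, h * w).transpose(0, 2, 1)  # (N, T=H*W, D)
        encoded = self.bilstm(seq)
        return self.pool(encoded)
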