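"""Vision-transformer encoder over backbone feature maps.

The feature map is cut into non-overlapping P x P patches in row-major
raster order, each flattened and affinely projected to the embedding
dimension; learned position embeddings are added.  Encoder blocks are
post-norm: z <- LayerNorm(z + MHSA(z)) then z <- LayerNorm(z + FFN(z)) with
FFN(z) = ReLU(z W1 + b1) W2 + b2.  There is no class token — the
classification head acts on the concatenation of all N patch outputs.

Scaled dot-product attention is Softmax(Q K^T / sqrt(d_k)) V with
max-subtracted softmax for stability; multi-head attention concatenates the
per-head outputs and projects by W_o.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat

__all__ = [
    "PatchConfig", "EncoderConfig", "scaled_dot_attention", "PatchEmbed",
    "MultiHeadSelfAttention", "EncoderBlock", "ViTEncoder", "add_positions",
]


@dataclass(frozen=True)
class PatchConfig:
    patch_size: int = 2
    embed_dim: int = 16

    def __post_init__(self):
        if self.patch_size <= 0 or self.embed_dim <= 0:
            raise ValueError("patch_size and embed_dim must be positive")

    def n_patches(self, h: int, w: int) -> int:
        p = self.patch_size
        if h % p or w % p:
            raise ValueError(f"patch size {p} does not divide feature map {h}x{w}")
        return (h // p) * (w // p)


@dataclass(frozen=True)
class EncoderConfig:
    depth: int = 2
    heads: int = 2
    ffn_dim: int = 32
    seed: int = 0

    def __post_init__(self):
        if min(self.depth, self.heads, self.ffn_dim) <= 0:
            raise ValueError("depth, heads and ffn_dim must be positive")


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
    """Softmax(Q K^T / sqrt(d_k)) V; returns (output, attention weights).

    Q: (..., Tq, d_k), K: (..., Tk, d_k), V: (..., Tk, d_v).
    """
    if q.shape[-1] != k.shape[-1]:
        raise ValueError("Q and K must share the key dimension")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("K and V must share the sequence length")
    d_k = q.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) \
        * (1.0 / np.sqrt(d_k))
    weights = scores.softmax(axis=-1)
    return weights @ v, weights


class PatchEmbed(nn.Module):
    """Flatten P x P patches (row-major) and project affinely to embed_dim."""

    def __init__(self, in_channels: int, cfg: PatchConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.in_channels = in_channels
        in_dim = in_channels * cfg.patch_size**2
        self.proj = nn.Linear(in_dim, cfg.embed_dim, rng)

    def forward(self, fmap: Tensor) -> Tensor:
        n, c, h, w = fmap.shape
        p = self.cfg.patch_size
        if h % p or w % p:
            raise ValueError(f"patch size {p} does not divide feature map {h}x{w}")
        gh, gw = h // p, w // p
        # (N, C, gh, p, gw, p) -> (N, gh, gw, C, p, p) -> (N, Npatch, C*p*p)
        patches = (
            fmap.reshape(n, c, gh, p, gw, p)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(n, gh * gw, c * p * p)
        )
        return self.proj(patches)


def add_positions(z: Tensor, e: Tensor) -> Tensor:
    """Element-wise z[p] + E[p]; E must match the sequence layout."""
    if z.shape[-2:] != e.shape[-2:]:
        raise ValueError(f"position embedding shape {e.shape} does not match {z.shape}")
    return z + e


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"embed dim {dim} not divisible by {heads} heads")
        self.heads = heads
        self.d_k = dim // heads
        self.wq = nn.Linear(dim, dim, rng)
        self.wk = nn.Linear(dim, dim, rng)
        self.wv = nn.Linear(dim, dim, rng)
        self.wo = nn.Linear(dim, dim, rng)

    def forward(self, z: Tensor) -> Tensor:
        n, t, d = z.shape
        h, dk = self.heads, self.d_k
        def split(x):  # (N, T, D) -> (N, h, T, d_k)
            return x.reshape(n, t, h, dk).transpose(0, 2, 1, 3)
        q, k, v = split(self.wq(z)), split(self.wk(z)), split(self.wv(z))
        out, _ = scaled_dot_attention(q, k, v)
        merged = out.transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.wo(merged)


class FeedForward(nn.Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, z: Tensor) -> Tensor:
        return self.fc2(self.fc1(z).relu())


class EncoderBlock(nn.Module):
    """Post-norm residual block: LN(z + MHSA(z)), then LN(z + FFN(z))."""

    def __init__(self, dim: int, heads: int, ffn_dim: int, rng: np.random.Generator):
        self.mhsa = MultiHeadSelfAttention(dim, heads, rng)
        self.ln1 = nn.LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_dim, rng)
        self.ln2 = nn.LayerNorm(dim)

    def forward(self, z: Tensor) -> Tensor:
        z = self.ln1(z + self.mhsa(z))
        z = self.ln2(z + self.ffn(z))
        return z


class ViTEncoder(nn.Module):
    """Patch embedding + position embeddings + L encoder blocks + head.

    The head concatenates all patch outputs; because that dimension grows
    with N, it is sized at construction from the known feature-map geometry.
    """

    def __init__(self, in_channels: int, fmap_hw: tuple[int, int],
                 patch_cfg: PatchConfig, enc_cfg: EncoderConfig, n_classes: int):
        rng = np.random.default_rng(enc_cfg.seed)
        self.patch_cfg = patch_cfg
        self.n_patches = patch_cfg.n_patches(*fmap_hw)
        self.embed = PatchEmbed(in_channels, patch_cfg, rng)
        self.pos = nn.Parameter(
            rng.normal(0.0, 0.02, size=(self.n_patches, patch_cfg.embed_dim))
        )
        self.blocks = [
            EncoderBlock(patch_cfg.embed_dim, enc_cfg.heads, enc_cfg.ffn_dim, rng)
            for _ in range(enc_cfg.depth)
        ]
        self.head = nn.Linear(self.n_patches * patch_cfg.embed_dim, n_classes, rng)

    def encode(self, fmap: Tensor) -> Tensor:
        z = add_positions(self.embed(fmap), self.pos)
        for blk in self.blocks:
            z = blk(z)
        return z

    def classify(self, tokens: Tensor) -> Tensor:
        n, t, d = tokens.shape
        logits = self.head(tokens.reshape(n, t * d))
        return logits.softmax(axis=-1)

    def forward(self, fmap: Tensor) -> Tensor:
        return self.classify(self.encode(fmap))
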