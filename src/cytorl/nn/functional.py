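"""Convolution primitives with hand-written gradients.

2-D convolution is computed by im2col + matmul; its gradient uses the
transpose (col2im) scatter.  The depthwise variant applies one k x k kernel
per channel.  The 3-D convolution operates on single-channel volumes
(depth x height x width) with same-padding, which is how stacked feature
maps from different network stages are aggregated.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "depthwise_conv2d", "conv3d_same", "avg_pool2d"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, oh, ow, kh, kw),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    # (N, OH*OW, C*kh*kw)
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    out = np.zeros((n, c, hp, wp))
    cols = cols.reshape(n, oh, ow, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """x: (N,C,H,W), weight: (Cout,Cin,kh,kw), bias: (Cout,) or None."""
    cout, cin, kh, kw = weight.shape
    n, c, h, w = x.shape
    if c != cin:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(cout, -1)
    out = cols @ wmat.T  # (N, OH*OW, Cout)
    if bias is not None:
        out = out + bias.data
    out = out.transpose(0, 2, 1).reshape(n, cout, oh, ow)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.reshape(n, cout, oh * ow).transpose(0, 2, 1)  # (N, OH*OW, Cout)
        gw = np.einsum("npk,npc->kc", gmat, cols).reshape(weight.shape)
        gcols = gmat @ wmat  # (N, OH*OW, C*kh*kw)
        gx = _col2im(gcols, x.data.shape, kh, kw, stride, pad)
        pairs = [(x, gx), (weight, gw)]
        if bias is not None:
            pairs.append((bias, gmat.sum(axis=(0, 1))))
        return tuple(pairs)

    return Tensor._make(out, parents, backward)


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
                     stride: int = 1, pad: int = 0) -> Tensor:
    """Per-channel convolution. weight: (C, kh, kw)."""
    c, kh, kw = weight.shape
    n, cx, h, w = x.shape
    if cx != c:
        raise ValueError(f"depthwise channel mismatch: input {cx}, weight {c}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, oh, ow, kh, kw),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3), writeable=False)
    out = np.einsum("nchwij,cij->nchw", windows, weight.data)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gw = np.einsum("nchwij,nchw->cij", windows, g)
        gcols = np.einsum("nchw,cij->nchwij", g, weight.data)
        # scatter windows back
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                    gcols[:, :, :, :, i, j]
                )
        gx = gxp[:, :, pad : pad + h, pad : pad + w] if pad else gxp
        pairs = [(x, gx), (weight, gw)]
        if bias is not None:
            pairs.append((bias, g.sum(axis=(0, 2, 3))))
        return tuple(pairs)

    return Tensor._make(out, parents, backward)


def conv3d_same(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Single-channel 3-D convolution with same-padding.

    x: (N, D, H, W); weight: (kd, kh, kw) with odd sides; bias: scalar Tensor
    or None.  Output shape equals input shape (cross-correlation convention).
    """
    kd, kh, kw = weight.shape
    if kd % 2 == 0 or kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv3d_same requires odd kernel sides")
    n, d, h, w = x.shape
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(n, d, h, w, kd, kh, kw),
        strides=(s0, s1, s2, s3, s1, s2, s3), writeable=False)
    out = np.einsum("ndhwijk,ijk->ndhw", windows, weight.data)
    if bias is not None:
        out = out + bias.data

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gw = np.einsum("ndhwijk,ndhw->ijk", windows, g)
        gxp = np.zeros_like(xp)
        gcols = np.einsum("ndhw,ijk->ndhwijk", g, weight.data)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    gxp[:, i : i + d, j : j + h, k : k + w] += gcols[:, :, :, :, i, j, k]
        gx = gxp[:, pd : pd + d, ph : ph + h, pw : pw + w]
        pairs = [(x, gx), (weight, gw)]
        if bias is not None:
            pairs.append((bias, np.asarray(g.sum())))
        return tuple(pairs)

    return Tensor._make(out, parents, backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling; spatial dims must divide by k."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: {h}x{w} not divisible by {k}")
    r = x.reshape(n, c, h // k, k, w // k, k)
    return r.mean(axis=(3, 5))
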