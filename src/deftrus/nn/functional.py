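"""Image-specific differentiable primitives: padding, convolution,
nearest-neighbour upsampling and instance normalization.

Convolution is implemented as a strided ``sliding_window_view`` followed by a
``tensordot`` (im2col), which routes the heavy lifting through BLAS.  The
input gradient is the usual transposed convolution: the output gradient is
zero-stuffed by the stride, zero-padded by ``k-1`` and correlated with the
spatially flipped kernel.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["pad2d", "conv2d", "upsample_nearest2d", "instance_norm2d"]


def _windows(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    if stride > 1:
        v = v[:, :, ::stride, ::stride]
    return v


def _reflect_index(n: int, pad: int) -> np.ndarray:
    """Index map of length n+2*pad implementing 'reflect' (no edge repeat)."""
    idx = np.arange(-pad, n + pad)
    period = 2 * (n - 1) if n > 1 else 1
    idx = np.abs(idx) % period
    return np.where(idx >= n, period - idx, idx)


def pad2d(x: Tensor, pad: int, mode: str = "zeros") -> Tensor:
    """Pad the two trailing spatial axes of an (N, C, H, W) tensor."""
    if pad == 0:
        return x
    n, c, h, w = x.data.shape
    if mode == "zeros":
        y = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        out = Tensor._make(y, (x,), None)
        out._backward = lambda g: x._accum(g[:, :, pad:-pad, pad:-pad])
        return out
    if mode == "reflect":
        ih = _reflect_index(h, pad)
        iw = _reflect_index(w, pad)
        y = x.data[:, :, ih][:, :, :, iw]
        out = Tensor._make(y, (x,), None)

        def bw(g):
            gh = np.zeros((n, c, h, w + 2 * pad), dtype=g.dtype)
            np.add.at(gh, (slice(None), slice(None), ih), g)
            gx = np.zeros((n, c, h, w), dtype=g.dtype)
            np.add.at(gx, (slice(None), slice(None), slice(None), iw), gh)
            x._accum(gx)

        out._backward = bw
        return out
    raise ValueError(f"unknown pad mode: {mode!r}")


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Valid cross-correlation of (N, C, H, W) with (O, C, kh, kw)."""
    kh, kw = w.data.shape[2:]
    cols = _windows(x.data, kh, kw, stride)  # (N, C, Ho, Wo, kh, kw)
    y = np.tensordot(cols, w.data, axes=([1, 4, 5], [1, 2, 3]))  # (N, Ho, Wo, O)
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(y, parents, None)

    def bw(g):
        if w.requires_grad:
            gw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 2, 3]))
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            n, _, h, wd = x.data.shape
            gd = np.zeros((g.shape[0], g.shape[1], h - kh + 1, wd - kw + 1), dtype=g.dtype)
            gd[:, :, ::stride, ::stride] = g
            gp = np.pad(gd, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
            wf = w.data[:, :, ::-1, ::-1]
            colsg = np.lib.stride_tricks.sliding_window_view(gp, (kh, kw), axis=(2, 3))
            gx = np.tensordot(colsg, wf, axes=([1, 4, 5], [0, 2, 3]))  # (N, H, W, C)
            x._accum(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))

    out._backward = bw
    return out


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    y = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    out = Tensor._make(y, (x,), None)

    def bw(g):
        x._accum(g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    out._backward = bw
    return out


def instance_norm2d(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel standardization over the spatial axes."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xm = x.data - mu
    var = (xm * xm).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xm * inv
    out = Tensor._make(xhat, (x,), None)

    def bw(g):
        gm = g.mean(axis=(2, 3), keepdims=True)
        gx = (g - gm - xhat * (g * xhat).mean(axis=(2, 3), keepdims=True)) * inv
        x._accum(gx)

    out._backward = bw
    return out
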