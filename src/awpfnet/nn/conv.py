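"""Convolution, pooling and interpolation primitives (im2col based)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import DEFAULT_DTYPE, Tensor


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int,
            pad_value: float = 0.0) -> np.ndarray:
    """(B,C,H,W) -> (B, C*kh*kw, Ho*Wo) patch matrix."""
    B, C, H, W = x.shape
    Ho, Wo = _out_size(H, kh, sh, ph), _out_size(W, kw, sw, pw)
    if ph or pw:
        xp = np.full((B, C, H + 2 * ph, W + 2 * pw), pad_value, dtype=x.dtype)
        xp[:, :, ph:ph + H, pw:pw + W] = x
    else:
        xp = x
    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    v = v.transpose(0, 1, 4, 5, 2, 3)  # (B, C, kh, kw, Ho, Wo)
    return np.ascontiguousarray(v).reshape(B, C * kh * kw, Ho * Wo)


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, sh: int, sw: int,
            ph: int, pw: int) -> np.ndarray:
    B, C, H, W = x_shape
    Ho, Wo = _out_size(H, kh, sh, ph), _out_size(W, kw, sw, pw)
    cols = cols.reshape(B, C, kh, kw, Ho, Wo)
    xp = np.zeros((B, C, H + 2 * ph, W + 2 * pw), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += cols[:, :, i, j]
    return xp[:, :, ph:ph + H, pw:pw + W]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation; weight shape (out, in, kh, kw)."""
    O, C, kh, kw = weight.shape
    B = x.shape[0]
    Ho = _out_size(x.shape[2], kh, stride, padding)
    Wo = _out_size(x.shape[3], kw, stride, padding)
    cols = _im2col(x.data, kh, kw, stride, stride, padding, padding)
    wmat = weight.data.reshape(O, -1)
    out = np.matmul(wmat, cols)  # (B, O, Ho*Wo)
    if bias is not None:
        out += bias.data.reshape(1, O, 1)
    out = out.reshape(B, O, Ho, Wo)

    def backward(g):
        gm = g.reshape(B, O, Ho * Wo)
        gw = np.einsum("bol,bkl->ok", gm, cols, optimize=True)
        weight._accum(gw.reshape(weight.shape).astype(DEFAULT_DTYPE))
        if bias is not None:
            bias._accum(gm.sum(axis=(0, 2)))
        gcols = np.matmul(wmat.T, gm)
        x._accum(_col2im(gcols, x.shape, kh, kw, stride, stride, padding, padding))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    B, C, H, W = x.shape
    Ho, Wo = _out_size(H, kernel, stride, padding), _out_size(W, kernel, stride, padding)
    cols = _im2col(x.data, kernel, kernel, stride, stride, padding, padding,
                   pad_value=-np.inf)
    cols = cols.reshape(B, C, kernel * kernel, Ho * Wo)
    idx = cols.argmax(axis=2)
    out = np.take_along_axis(cols, idx[:, :, None, :], axis=2)[:, :, 0, :]
    out = out.reshape(B, C, Ho, Wo)

    def backward(g):
        gcols = np.zeros((B, C, kernel * kernel, Ho * Wo), dtype=DEFAULT_DTYPE)
        np.put_along_axis(gcols, idx[:, :, None, :], g.reshape(B, C, 1, Ho * Wo), axis=2)
        x._accum(_col2im(gcols.reshape(B, C * kernel * kernel, Ho * Wo), x.shape,
                         kernel, kernel, stride, stride, padding, padding))

    return Tensor._make(out, (x,), backward)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (align_corners=False)."""
    W = np.zeros((n_out, n_in), dtype=DEFAULT_DTYPE)
    for o in range(n_out):
        c = (o + 0.5) * n_in / n_out - 0.5
        c0 = int(np.floor(c))
        t = c - c0
        i0 = min(max(c0, 0), n_in - 1)
        i1 = min(max(c0 + 1, 0), n_in - 1)
        W[o, i0] += 1.0 - t
        W[o, i1] += t
    return W


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Resize the last two axes of a (B,C,H,W) tensor by bilinear interpolation."""
    Ho, Wo = size
    if Ho < 1 or Wo < 1:
        raise ValueError(f"target size must be at least (1, 1), got {size}")
    H, W = x.shape[-2:]
    if (H, W) == (Ho, Wo):
        return x
    Rh = _interp_matrix(H, Ho)
    Rw = _interp_matrix(W, Wo)
    out = np.einsum("oh,bchw,pw->bcop", Rh, x.data, Rw, optimize=True)

    def backward(g):
        x._accum(np.einsum("oh,bcop,pw->bchw", Rh, g, Rw, optimize=True))

    return Tensor._make(out.astype(DEFAULT_DTYPE), (x,), backward)


def batch_norm(x: Tensor, weight: Tensor, bias: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (B,H,W) per channel of a (B,C,H,W) tensor.

    Updates ``running_mean``/``running_var`` in place when training.
    """
    axes = (0, 2, 3)
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    if training:
        mean = x.data.mean(axis=axes)
        var = np.einsum("bchw,bchw->c", x.data, x.data, optimize=True) / n - mean * mean
        np.maximum(var, 0.0, out=var)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        unbiased = var * (n / max(n - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(DEFAULT_DTYPE)
    scale = (weight.data * inv_std).reshape(1, -1, 1, 1)
    shift = (bias.data - weight.data * inv_std * mean).reshape(1, -1, 1, 1)
    out = x.data * scale + shift

    def backward(g):
        # xhat recomputed lazily to keep the forward pass lean
        xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv_std.reshape(1, -1, 1, 1)
        weight._accum((g * xhat).sum(axis=axes))
        bias._accum(g.sum(axis=axes))
        gy = g * weight.data.reshape(1, -1, 1, 1)
        if training:
            gmean = gy.mean(axis=axes, keepdims=True)
            gdot = (gy * xhat).mean(axis=axes, keepdims=True)
            gx = (gy - gmean - xhat * gdot) * inv_std.reshape(1, -1, 1, 1)
        else:
            gx = gy * inv_std.reshape(1, -1, 1, 1)
        x._accum(gx.astype(DEFAULT_DTYPE))

    return Tensor._make(out.astype(DEFAULT_DTYPE), (x, weight, bias), backward)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mean = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out = xhat * weight.data + bias.data

    def backward(g):
        red = tuple(range(g.ndim - 1))
        weight._accum((g * xhat).sum(axis=red))
        bias._accum(g.sum(axis=red))
        gy = g * weight.data
        gmean = gy.mean(axis=-1, keepdims=True)
        gdot = (gy * xhat).mean(axis=-1, keepdims=True)
        x._accum(((gy - gmean - xhat * gdot) * inv_std).astype(DEFAULT_DTYPE))

    return Tensor._make(out.astype(DEFAULT_DTYPE), (x, weight, bias), backward)
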