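"""Differentiable primitives over :class:`~renalseg.nn.tensor.Tensor`.

Convolutions are realised as ``k^3`` shifted GEMMs rather than an im2col
buffer, which keeps peak memory proportional to one activation map.  Under
:func:`~renalseg.nn.tensor.no_grad` every primitive returns a detached
tensor, so inference never retains the graph.  All tensors are
``(N, C, D, H, W)`` float32.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, grad_enabled

__all__ = [
    "scale",
    "add",
    "relu",
    "concat",
    "conv3d",
    "conv_transpose3d",
    "max_pool3d",
    "batch_norm",
    "dropout",
    "softmax_channel",
    "weighted_bce_from_probs",
]


def scale(x: Tensor, c: float) -> Tensor:
    """Multiplication by a constant (e.g. fixed input normalisation)."""
    if not grad_enabled():
        return Tensor(x.data * c)
    out = Tensor(x.data * c, parents=(x,))

    def _backward(g):
        x.accumulate(g * c)

    out._backward = _backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not grad_enabled():
        return Tensor(a.data + b.data)
    out = Tensor(a.data + b.data, parents=(a, b))

    def _backward(g):
        a.accumulate(g)
        b.accumulate(g)

    out._backward = _backward
    return out


def relu(x: Tensor) -> Tensor:
    if not grad_enabled():
        return Tensor(np.maximum(x.data, 0))
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def _backward(g):
        x.accumulate(g * mask)

    out._backward = _backward
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    if not grad_enabled():
        return Tensor(data)
    out = Tensor(data, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate(g[tuple(idx)])

    out._backward = _backward
    return out


def _pad_spatial(a: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return a
    return np.pad(a, ((0, 0), (0, 0)) + ((pad, pad),) * 3)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int | None = None) -> Tensor:
    """3D convolution, stride 1.  ``w`` is ``(Cout, Cin, k, k, k)``; ``pad``
    defaults to ``k // 2`` (shape-preserving for odd kernels)."""
    N, Ci, D, H, W = x.data.shape
    Co, Ci2, k, _, _ = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"conv3d channel mismatch: input {Ci}, weight {Ci2}")
    if pad is None:
        pad = k // 2
    xp = _pad_spatial(x.data, pad)
    Do, Ho, Wo = (D + 2 * pad - k + 1, H + 2 * pad - k + 1, W + 2 * pad - k + 1)
    S = Do * Ho * Wo
    out = np.zeros((N, Co, S), np.float32)
    for kd in range(k):
        for kh in range(k):
            for kw in range(k):
                xs = xp[:, :, kd : kd + Do, kh : kh + Ho, kw : kw + Wo].reshape(N, Ci, S)
                out += np.matmul(w.data[:, :, kd, kh, kw], xs)
    out = out.reshape(N, Co, Do, Ho, Wo)
    if b is not None:
        out += b.data.reshape(1, Co, 1, 1, 1)
    del xp  # re-padded on demand in the backward pass
    if not grad_enabled():
        return Tensor(out)
    parents = (x, w) if b is None else (x, w, b)
    res = Tensor(out, parents=parents)

    def _backward(g):
        go = g.reshape(N, Co, S)
        if b is not None:
            b.accumulate(go.sum(axis=(0, 2)))
        xp = _pad_spatial(x.data, pad)
        gxp = np.zeros_like(xp) if x.needs_grad else None
        gw = np.zeros_like(w.data) if w.needs_grad else None
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    sl = (
                        slice(None),
                        slice(None),
                        slice(kd, kd + Do),
                        slice(kh, kh + Ho),
                        slice(kw, kw + Wo),
                    )
                    if gw is not None:
                        xs = xp[sl].reshape(N, Ci, S)
                        gw[:, :, kd, kh, kw] = np.matmul(go, xs.transpose(0, 2, 1)).sum(axis=0)
                    if gxp is not None:
                        gxp[sl] += np.matmul(
                            w.data[:, :, kd, kh, kw].T, go
                        ).reshape(N, Ci, Do, Ho, Wo)
        if gw is not None:
            w.accumulate(gw)
        if gxp is not None:
            gx = gxp[:, :, pad : pad + D, pad : pad + H, pad : pad + W] if pad > 0 else gxp
            x.accumulate(gx)

    res._backward = _backward
    return res


def conv_transpose3d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 2,
    pad: int = 0,
    output_padding: int = 0,
) -> Tensor:
    """Transposed 3D convolution.  ``w`` is ``(Cin, Cout, k, k, k)``.

    Output spatial size is ``(n - 1) * stride - 2 * pad + k + output_padding``
    per axis; kernel 2 / stride 2 and kernel 3 / stride 2 / pad 1 /
    output_padding 1 both exactly double the resolution.
    """
    N, Ci, D, H, W = x.data.shape
    Ci2, Co, k, _, _ = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"conv_transpose3d channel mismatch: input {Ci}, weight {Ci2}")
    full = tuple((n - 1) * stride + k for n in (D, H, W))
    out_shape = tuple(f - 2 * pad + output_padding for f in full)
    S = D * H * W
    x2 = x.data.reshape(N, Ci, S)

    def _scatter_slices(kd, kh, kw):
        return (
            slice(None),
            slice(None),
            slice(kd, kd + stride * (D - 1) + 1, stride),
            slice(kh, kh + stride * (H - 1) + 1, stride),
            slice(kw, kw + stride * (W - 1) + 1, stride),
        )

    buf = np.zeros((N, Co) + full, np.float32)
    for kd in range(k):
        for kh in range(k):
            for kw in range(k):
                contrib = np.matmul(w.data[:, :, kd, kh, kw].T, x2).reshape(N, Co, D, H, W)
                buf[_scatter_slices(kd, kh, kw)] += contrib
    crop = tuple(slice(pad, pad + o) for o in out_shape)
    out = np.ascontiguousarray(buf[(slice(None), slice(None)) + crop])
    del buf
    if b is not None:
        out += b.data.reshape(1, Co, 1, 1, 1)
    if not grad_enabled():
        return Tensor(out)
    parents = (x, w) if b is None else (x, w, b)
    res = Tensor(out, parents=parents)

    def _backward(g):
        if b is not None:
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))
        gfull = np.zeros((N, Co) + full, np.float32)
        gfull[(slice(None), slice(None)) + crop] = g
        gx = np.zeros((N, Ci, S), np.float32) if x.needs_grad else None
        gw = np.zeros_like(w.data) if w.needs_grad else None
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    gof = np.ascontiguousarray(
                        gfull[_scatter_slices(kd, kh, kw)]
                    ).reshape(N, Co, S)
                    if gx is not None:
                        gx += np.matmul(w.data[:, :, kd, kh, kw], gof)
                    if gw is not None:
                        gw[:, :, kd, kh, kw] = np.matmul(x2, gof.transpose(0, 2, 1)).sum(axis=0)
        if gx is not None:
            x.accumulate(gx.reshape(N, Ci, D, H, W))
        if gw is not None:
            w.accumulate(gw)

    res._backward = _backward
    return res


def max_pool3d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must divide by ``size``.
    Gradient is split evenly among tied maxima (deterministic)."""
    N, C, D, H, W = x.data.shape
    if D % size or H % size or W % size:
        raise ValueError(f"spatial size {(D, H, W)} not divisible by pool size {size}")
    xr = x.data.reshape(N, C, D // size, size, H // size, size, W // size, size)
    m = xr.max(axis=(3, 5, 7))
    if not grad_enabled():
        return Tensor(m)
    out = Tensor(m, parents=(x,))

    def _backward(g):
        me = m[:, :, :, None, :, None, :, None]
        mask = xr == me
        cnt = mask.sum(axis=(3, 5, 7), keepdims=True)
        ge = g[:, :, :, None, :, None, :, None] / cnt
        x.accumulate((mask * ge).reshape(x.data.shape))

    out._backward = _backward
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.9,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over ``(N, D, H, W)``.

    In training mode batch statistics are used and the running buffers are
    updated in place with ``momentum`` on the old value.
    """
    C = x.data.shape[1]
    cshape = (1, C, 1, 1, 1)
    if training:
        axes = (0, 2, 3, 4)
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= momentum
        running_mean += (1 - momentum) * mu
        running_var *= momentum
        running_var += (1 - momentum) * var
        ivstd = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(cshape)) * ivstd.reshape(cshape)
        data = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)
        if not grad_enabled():
            return Tensor(data)
        out = Tensor(data, parents=(x, gamma, beta))
        m = x.data.size // C

        def _backward(g):
            gamma.accumulate((g * xhat).sum(axis=axes))
            beta.accumulate(g.sum(axis=axes))
            if x.needs_grad:
                dxhat = g * gamma.data.reshape(cshape)
                sum_dxhat = dxhat.sum(axis=axes).reshape(cshape)
                sum_dxhat_xhat = (dxhat * xhat).sum(axis=axes).reshape(cshape)
                gx = (
                    (dxhat - sum_dxhat / m - xhat * sum_dxhat_xhat / m)
                    * ivstd.reshape(cshape)
                )
                x.accumulate(gx.astype(np.float32))

        out._backward = _backward
        return out
    ivstd = 1.0 / np.sqrt(running_var + eps)
    scale = (gamma.data * ivstd).reshape(cshape)
    data = scale * (x.data - running_mean.reshape(cshape)) + beta.data.reshape(cshape)
    if not grad_enabled():
        return Tensor(data)
    out = Tensor(data, parents=(x, gamma, beta))
    xhat_eval = (x.data - running_mean.reshape(cshape)) * ivstd.reshape(cshape)

    def _backward_eval(g):
        gamma.accumulate((g * xhat_eval).sum(axis=(0, 2, 3, 4)))
        beta.accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.needs_grad:
            x.accumulate(g * scale)

    out._backward = _backward_eval
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    if not grad_enabled():
        return Tensor(x.data * mask)
    out = Tensor(x.data * mask, parents=(x,))

    def _backward(g):
        x.accumulate(g * mask)

    out._backward = _backward
    return out


def softmax_channel(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    if not grad_enabled():
        return Tensor(p)
    out = Tensor(p, parents=(x,))

    def _backward(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        x.accumulate(p * (g - dot))

    out._backward = _backward
    return out


def weighted_bce_from_probs(
    probs: Tensor,
    truth_onehot: np.ndarray,
    voxel_weights: np.ndarray,
    eps: float = 1e-7,
) -> Tensor:
    """Class-weighted binary cross-entropy summed over voxels and channels.

    ``loss = -(1/N) sum_i w_i [ yhat_i log p_i + (1 - yhat_i) log(1 - p_i) ]``
    with ``N`` the number of voxels per volume (times the batch size), every
    channel of voxel ``i`` weighted by that voxel's class weight ``w_i``.
    Probabilities are clamped to ``[eps, 1 - eps]`` before the logarithm.
    """
    y = np.asarray(truth_onehot, np.float32)
    wv = np.asarray(voxel_weights, np.float32)
    p = np.clip(probs.data, eps, 1.0 - eps)
    n_vox = float(np.prod(probs.data.shape) / probs.data.shape[1])
    terms = wv * (y * np.log(p) + (1.0 - y) * np.log1p(-p))
    data = np.float32(-terms.sum() / n_vox)
    if not grad_enabled():
        return Tensor(data)
    loss = Tensor(data, parents=(probs,))

    def _backward(g):
        # gradient through the clamped probabilities: the clamp bounds the
        # denominators but must not silence saturated voxels, or training
        # could never leave a confidently-wrong initialisation
        scale = float(g) / n_vox
        dp = -scale * wv * (y / p - (1.0 - y) / (1.0 - p))
        probs.accumulate(dp.astype(np.float32))

    loss._backward = _backward
    return loss
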