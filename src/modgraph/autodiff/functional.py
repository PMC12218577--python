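"""Neural-network primitives built on :class:`~modgraph.autodiff.tensor.Tensor`.

Convolution is implemented with im2col and a single matrix product; pooling
and nearest-neighbour upsampling are pure reshapes. Everything here is
stride-1/same-padding by design — downsampling in the model zoo is done with
explicit average pooling so every primitive stays simple and exactly
differentiable.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _unbroadcast


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,C,Ho,Wo,kh,kw
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, pad: int) -> np.ndarray:
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = hp - kh + 1, wp - kw + 1
    dxp = np.zeros((b, c, hp, wp))
    d6 = dcols.reshape(b, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + ho, j:j + wo] += d6[:, :, :, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor], pad: int = 1) -> Tensor:
    """Stride-1 2D convolution. x: (B,C,H,W), weight: (F,C,kh,kw), bias: (F,)."""
    b, c, h, w = x.shape
    f, c_w, kh, kw = weight.shape
    if c != c_w:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c_w}")
    ho, wo = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    cols = _im2col(x.data, kh, kw, pad)                       # (B*Ho*Wo, C*kh*kw)
    w2 = weight.data.reshape(f, -1)
    out = cols @ w2.T                                          # (B*Ho*Wo, F)
    if bias is not None:
        out = out + bias.data
    out = out.reshape(b, ho, wo, f).transpose(0, 3, 1, 2)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g: np.ndarray) -> None:
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, f)            # (B*Ho*Wo, F)
        if weight.requires_grad:
            weight._accumulate((g2.T @ cols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcols = g2 @ w2                                    # (B*Ho*Wo, C*kh*kw)
            x._accumulate(_col2im(dcols, x.shape, kh, kw, pad))

    return Tensor._make(out, parents, backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    b, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: spatial dims {h}x{w} not divisible by {k}")
    out = x.data.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accumulate(gg)

    return Tensor._make(out, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            b, c, h2, w2 = g.shape
            x._accumulate(g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C)."""
    return x.mean(axis=(2, 3))


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(logits.data.max(axis=axis, keepdims=True))  # constant, no grad
    z = logits - shift
    lse = z.exp().sum(axis=axis, keepdims=True).log()
    return z - lse


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(logits, axis=axis).exp()


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  weights: Optional[np.ndarray] = None) -> Tensor:
    """Mean (optionally per-class weighted) cross-entropy from logits.

    targets: int array (B,); weights: per-class array, normalised so the
    weighted mean reduces to the plain mean when weights are uniform.
    """
    targets = np.asarray(targets, dtype=int)
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(targets.shape[0]), targets]
    if weights is None:
        return -picked.mean()
    w = np.asarray(weights, dtype=float)[targets]
    return -(picked * Tensor(w)).sum() / float(w.sum())


def mse(a: Tensor, b: Tensor) -> Tensor:
    return ((a - b) ** 2).mean()


def l1(a: Tensor, b: Tensor) -> Tensor:
    return (a - b).abs().mean()


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    return x * Tensor(mask)


def instance_norm2d(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel spatial standardisation (no affine)."""
    mu = x.mean(axis=(2, 3), keepdims=True)
    xc = x - mu
    var = (xc ** 2).mean(axis=(2, 3), keepdims=True)
    return xc / (var + eps).sqrt()
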