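"""Module system: parameter containers, layers, and a bias tape for
full-gradient attribution.

Layers take an explicit ``numpy.random.Generator`` at construction so every
initialisation is reproducible from a single experiment seed.
"""

from __future__ import annotations

import contextlib
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from . import functional as F
from .tensor import Tensor

# --------------------------------------------------------------------------
# Bias tape: when active, Linear/Conv2d layers add a zero "virtual bias"
# tensor at full output resolution whose gradient after backward() is the
# per-position pre-activation gradient — exactly what full-gradient saliency
# needs (the gradient w.r.t. a broadcast bias at every spatial location).
# --------------------------------------------------------------------------
_BIAS_TAPE: Optional[List[Tuple["Module", np.ndarray, Tensor]]] = None


@contextlib.contextmanager
def bias_tape():
    """Context manager collecting (layer, broadcast_bias, virtual_bias) triples."""
    global _BIAS_TAPE
    prev, _BIAS_TAPE = _BIAS_TAPE, []
    try:
        yield _BIAS_TAPE
    finally:
        _BIAS_TAPE = prev


def _tape_bias(layer: "Module", out: Tensor, bias: Optional[Tensor]) -> Tensor:
    if _BIAS_TAPE is None or bias is None:
        return out
    virtual = Tensor(np.zeros_like(out.data), requires_grad=True)
    if out.ndim == 4:  # conv: bias (F,) broadcast over (B,F,H,W)
        broadcast = np.broadcast_to(bias.data[None, :, None, None], out.shape)
    else:              # linear: bias (F,) broadcast over (B,F)
        broadcast = np.broadcast_to(bias.data, out.shape)
    _BIAS_TAPE.append((layer, broadcast.copy(), virtual))
    return out + virtual


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # ------------------------------------------------------------ parameters
    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # ----------------------------------------------------------- persistence
    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch, differing keys: {sorted(missing)}")
        for name, arr in state.items():
            if own[name].data.shape != arr.shape:
                raise ValueError(
                    f"parameter {name}: shape {arr.shape} != expected {own[name].data.shape}")
            own[name].data = np.asarray(arr, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return _tape_bias(self, out, self.bias)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Tensor(rng.normal(0.0, scale, (c_out, c_in, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.pad = k // 2

    def forward(self, x: Tensor) -> Tensor:
        out = F.conv2d(x, self.weight, self.bias, pad=self.pad)
        # with an active tape a virtual zero bias rides on top of the real
        # one and collects the per-position pre-activation gradient
        return _tape_bias(self, out, self.bias)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Dropout(Module):
    """Seeded dropout; the mask stream advances only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.rate, self.rng, self.training)


class ResidualBlock2d(Module):
    """conv-relu-conv plus identity (1x1-projected when widths change)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, rng)
        self.conv2 = Conv2d(c_out, c_out, rng)
        self.proj = Conv2d(c_in, c_out, rng, k=1) if c_in != c_out else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu())
        skip = self.proj(x) if self.proj is not None else x
        return (h + skip).relu()


class SelfAttention2d(Module):
    """Single-head dot-product attention over spatial positions."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.q = Conv2d(channels, channels, rng, k=1)
        self.k = Conv2d(channels, channels, rng, k=1)
        self.v = Conv2d(channels, channels, rng, k=1)
        self.out = Conv2d(channels, channels, rng, k=1)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        n = h * w
        q = self.q(x).reshape(b, c, n).transpose(0, 2, 1)   # (B,N,C)
        k = self.k(x).reshape(b, c, n)                       # (B,C,N)
        v = self.v(x).reshape(b, c, n).transpose(0, 2, 1)   # (B,N,C)
        att = F.softmax((q @ k) * (1.0 / np.sqrt(c)), axis=-1)  # (B,N,N)
        mixed = (att @ v).transpose(0, 2, 1).reshape(b, c, h, w)
        return x + self.out(mixed)
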