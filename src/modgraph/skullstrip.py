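"""Learned skull-stripping as direct image regression.

An encoder–decoder network with skip connections maps a raw head slice to
the skull-stripped brain slice directly — no intermediate binary mask — so
the edge stays differentiable end-to-end. Trained with mean squared error;
the final sigmoid makes the [0,1] output bound architectural.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from .autodiff import Tensor, concat
from .autodiff import functional as F
from .autodiff import nn
from .autodiff.optim import Adam
from .metrics import mask_iou, threshold_mask
from .slices import SliceStack

IOU_THRESHOLD_FRACTION = 0.05  # of max output intensity, to score regression as a mask


class SkullStripNet(nn.Module):
    """Miniature U-Net: two down stages, bottleneck, two up stages with skips."""

    def __init__(self, rng: np.random.Generator, base_channels: int = 8):
        super().__init__()
        c = base_channels
        self.enc1a = nn.Conv2d(1, c, rng)
        self.enc1b = nn.Conv2d(c, c, rng)
        self.enc2 = nn.Conv2d(c, 2 * c, rng)
        self.bottleneck = nn.Conv2d(2 * c, 4 * c, rng)
        self.dec2 = nn.Conv2d(6 * c, 2 * c, rng)
        self.dec1 = nn.Conv2d(3 * c, c, rng)
        self.out = nn.Conv2d(c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        e1 = self.enc1b(self.enc1a(x).relu()).relu()
        e2 = self.enc2(F.avg_pool2d(e1)).relu()
        b = self.bottleneck(F.avg_pool2d(e2)).relu()
        d2 = self.dec2(concat([F.upsample2x(b), e2], axis=1)).relu()
        d1 = self.dec1(concat([F.upsample2x(d2), e1], axis=1)).relu()
        # saturating clamp keeps the [0,1] bound architectural without the
        # vanishing gradients a sigmoid shows on mostly-zero targets
        return self.out(d1).clip01()


def _as_slice_batch(arr: np.ndarray) -> Tensor:
    """(N,S,S) -> Tensor (N,1,S,S)."""
    a = np.asarray(arr, dtype=float)
    return Tensor(a[:, None, :, :])


def strip_stack(model: SkullStripNet, stack: SliceStack) -> SliceStack:
    model.eval()
    out = model(_as_slice_batch(stack.data)).data[:, 0]
    return SliceStack(out, plane=stack.plane)


def train_skullstrip(model: SkullStripNet,
                     pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
                     epochs: int = 20, seed: int = 0, lr: float = 3e-3,
                     batch_size: int = 16, val_fraction: float = 0.2) -> Dict:
    """Train raw->brain regression with MSE; deterministic under `seed`.

    `pairs` is a sequence of (raw_slice, brain_slice) 2D arrays. Returns a
    report with the loss trajectory and untrained/trained validation MSE.
    """
    if len(pairs) < 10:
        raise ValueError(f"need at least 10 training slices, got {len(pairs)}")
    for raw, brain in pairs:
        if np.shape(raw) != np.shape(brain):
            raise ValueError("mismatched raw/brain slice shapes")
    raw = np.stack([np.asarray(p[0], dtype=float) for p in pairs])
    brain = np.stack([np.asarray(p[1], dtype=float) for p in pairs])

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(raw))
    n_val = max(1, int(len(raw) * val_fraction))
    val_idx, train_idx = order[:n_val], order[n_val:]

    def val_mse() -> float:
        model.eval()
        pred = model(_as_slice_batch(raw[val_idx])).data[:, 0]
        return float(np.mean((pred - brain[val_idx]) ** 2))

    mse_before = val_mse()
    opt = Adam(model.parameters(), lr=lr)
    losses: List[float] = []
    model.train()
    for _ in range(epochs):
        perm = rng.permutation(train_idx)
        total, count = 0.0, 0
        for start in range(0, len(perm), batch_size):
            idx = perm[start:start + batch_size]
            opt.zero_grad()
            pred = model(_as_slice_batch(raw[idx]))
            loss = F.mse(pred, _as_slice_batch(brain[idx]))
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            count += len(idx)
        losses.append(total / count)
    mse_after = val_mse()
    return {"losses": losses, "val_mse_untrained": mse_before,
            "val_mse_trained": mse_after, "n_train": len(train_idx),
            "n_val": len(val_idx)}


def strip_and_iou(model: SkullStripNet, raw: SliceStack,
                  truth_mask: np.ndarray,
                  threshold: float | None = None) -> float:
    """Strip a volume and score the thresholded output against the truth mask.

    threshold defaults to IOU_THRESHOLD_FRACTION of the output's max
    intensity; IoU is computed per volume.
    """
    truth = np.asarray(truth_mask, dtype=bool)
    if truth.shape != raw.data.shape:
        raise ValueError(f"truth mask shape {truth.shape} != stack shape {raw.data.shape}")
    stripped = strip_stack(model, raw).data
    if threshold is None:
        threshold = IOU_THRESHOLD_FRACTION * float(stripped.max())
    return mask_iou(threshold_mask(stripped, threshold), truth)
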