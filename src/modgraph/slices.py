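"""Slice stacks and slice-count normalisation.

Subjects arrive with varying numbers of coronal slices; classifiers need a
fixed count. Normalisation interpolates linearly along the slice axis with
endpoints preserved, so a stack already at the target count passes through
bit-exactly and constant stacks stay constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SliceStack:
    """A slice-major 3D intensity array in [0, 1]."""

    data: np.ndarray
    plane: str = "coronal"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"slice stack must be 3D, got shape {self.data.shape}")
        if self.n_slices < 2:
            raise ValueError("slice stack needs at least 2 slices")
        if not np.isfinite(self.data).all():
            raise ValueError("slice stack contains non-finite intensities")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def normalize_slices(stack: SliceStack, target: int) -> SliceStack:
    """Resample a stack to exactly `target` slices.

    Linear interpolation along the slice axis with endpoints preserved;
    identity (bit-exact) when the count already matches.
    """
    if target < 2:
        raise ValueError(f"target slice count must be >= 2, got {target}")
    n = stack.n_slices
    if n < 2:
        raise ValueError("degenerate stack: need at least 2 slices")
    if n == target:
        return SliceStack(stack.data.copy(), plane=stack.plane)
    old_pos = np.linspace(0.0, 1.0, n)
    new_pos = np.linspace(0.0, 1.0, target)
    idx = np.searchsorted(old_pos, new_pos, side="right") - 1
    idx = np.clip(idx, 0, n - 2)
    frac = (new_pos - old_pos[idx]) / (old_pos[idx + 1] - old_pos[idx])
    out = (1.0 - frac)[:, None, None] * stack.data[idx] + \
        frac[:, None, None] * stack.data[idx + 1]
    return SliceStack(out, plane=stack.plane)
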