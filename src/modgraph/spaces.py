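"""Typed data spaces attached to graph nodes.

A space declares what kind of datum lives at a node (an image volume, a 2D
slice, a named feature vector, or an AD/CN probability pair) and its exact
shape. Edges declare their input/output spaces and the graph refuses any
wiring whose spaces do not match exactly — adaptation must itself be an edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

KINDS = ("image_volume", "image_slice", "feature_vector", "probability_pair")

Shape = Union[Tuple[int, ...], Tuple[str, ...]]


@dataclass(frozen=True)
class DataSpace:
    """A node's data representation: kind + fully specified shape.

    For feature vectors the shape may be a tuple of feature names; its
    length then fixes the dimensionality. Probability pairs always have
    length 2, elements in [0,1] summing to 1.
    """

    name: str
    kind: str
    shape: Shape
    range: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"space {self.name!r}: unknown kind {self.kind!r}")
        if not self.shape:
            raise ValueError(f"space {self.name!r}: shape must be fully specified")
        object.__setattr__(self, "shape", tuple(self.shape))
        if self.kind == "probability_pair" and self.numeric_shape != (2,):
            raise ValueError(f"space {self.name!r}: probability_pair must have length 2")

    @property
    def numeric_shape(self) -> Tuple[int, ...]:
        if all(isinstance(s, str) for s in self.shape):
            return (len(self.shape),)
        return tuple(int(s) for s in self.shape)

    @property
    def feature_names(self) -> Optional[Tuple[str, ...]]:
        if all(isinstance(s, str) for s in self.shape):
            return tuple(self.shape)
        return None

    def validate(self, x: np.ndarray, atol: float = 1e-6) -> None:
        """Raise ValueError if the datum does not belong to this space."""
        x = np.asarray(x)
        if x.shape != self.numeric_shape:
            raise ValueError(
                f"datum shape {x.shape} does not belong to space {self.name!r} "
                f"with shape {self.numeric_shape}")
        if self.range is not None:
            lo, hi = self.range
            if x.min() < lo - atol or x.max() > hi + atol:
                raise ValueError(
                    f"datum values outside [{lo}, {hi}] for space {self.name!r}")
        if self.kind == "probability_pair":
            if np.any(x < -atol) or np.any(x > 1 + atol) or abs(float(x.sum()) - 1.0) > atol:
                raise ValueError(
                    f"datum is not a probability pair for space {self.name!r}")

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "shape": list(self.shape)}
        if self.range is not None:
            d["range"] = list(self.range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DataSpace":
        rng = tuple(d["range"]) if d.get("range") else None
        return cls(name=d["name"], kind=d["kind"], shape=tuple(d["shape"]), range=rng)
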