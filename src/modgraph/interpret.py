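"""Attribution: full-gradient saliency along graph paths, first-layer weight
importance by modality group, and exact Shapley values over the seven
modality groups of the fusion MLP.

Full-gradient saliency decomposes a network's output into an input-gradient
term plus per-layer bias terms; for rectified-linear networks the raw
decomposition is complete (it reconstructs the output exactly). Saliency
maps apply a post-processing psi (absolute value, per-layer max
normalisation) to each term, align deeper layers' bias maps to the input
resolution by linear upsampling, and rescale the sum to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .autodiff import Tensor
from .autodiff import nn
from .cohort import MODALITIES, SubjectRecord
from .fusion import MASK_FILL, N_GROUPS, FusionMLP, ScoreVector
from .graph import ContractViolationError, ModelGraph, PathPredictor, compose_path


@dataclass
class AttributionMap:
    """Importance keyed by node id or modality group."""

    values: Dict[str, np.ndarray]
    method: str  # fullgrad | layer1_weights | shapley
    normalization: str = ""


class UntrainedEdgeError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Full-gradient decomposition and saliency
# ---------------------------------------------------------------------------
def _psi(arr: np.ndarray) -> np.ndarray:
    a = np.abs(arr)
    peak = a.max()
    return a / peak if peak > 0 else a


def fullgrad_decomposition(forward: Callable[[Tensor], Tensor], x: np.ndarray
                           ) -> Tuple[float, float, Dict[int, float]]:
    """Raw (un-normalised) full-gradient decomposition of a scalar output.

    Returns (f(x), input term x·∇x, {layer index: bias term b·∇b}). For a
    rectified-linear network the input term plus all bias terms equals f(x).
    """
    xt = Tensor(np.asarray(x, dtype=float).copy(), requires_grad=True)
    with nn.bias_tape() as tape:
        out = forward(xt)
        scalar = out.sum()
        scalar.backward()
    input_term = float(np.sum(xt.data * xt.grad))
    bias_terms = {}
    for i, (_, broadcast, virtual) in enumerate(tape):
        grad = np.zeros_like(broadcast) if virtual.grad is None else virtual.grad
        bias_terms[i] = float(np.sum(broadcast * grad))
    return float(scalar.data), input_term, bias_terms


def fullgrad_saliency(path: PathPredictor, x: np.ndarray,
                      target_class: int = 1) -> AttributionMap:
    """Full-gradient saliency at the path's input node.

    map = psi(x ⊙ ∇x) + sum over layers of psi(b ⊙ ∇b), bias maps of conv
    layers summed over channels and linearly upsampled to the input's
    spatial resolution; the result is rescaled to [0, 1]. Paths containing
    sampling edges are refused.
    """
    for edge in path.edges:
        if not edge.transform.differentiable:
            raise ContractViolationError(
                f"edge {edge.id!r} samples; full-gradient saliency is undefined")
    x = np.asarray(x, dtype=float)
    xt = Tensor(x.copy(), requires_grad=True)
    with nn.bias_tape() as tape:
        out = path.forward_tensor(xt)
        scalar = out.reshape(-1)[int(target_class)].sum()
        scalar.backward()

    grad_in = np.zeros_like(x) if xt.grad is None else xt.grad
    smap = _psi(x * grad_in).astype(float)
    spatial = x.ndim >= 2
    target_shape = x.shape[-2:] if spatial else None

    for _, broadcast, virtual in tape:
        if virtual.grad is None:
            continue
        contrib = broadcast * virtual.grad
        if spatial and contrib.ndim == 4:
            # conv layer (B,F,h,w): sum channels, align each plane to the input
            planes = np.abs(contrib).sum(axis=1)  # (B,h,w)
            zoom_y = target_shape[0] / planes.shape[1]
            zoom_x = target_shape[1] / planes.shape[2]
            aligned = np.stack([ndimage.zoom(p, (zoom_y, zoom_x), order=1)
                                for p in planes])
            if smap.ndim == 2:
                aligned = aligned.sum(axis=0)
            elif aligned.shape[0] != smap.shape[0]:
                aligned = np.broadcast_to(aligned.sum(axis=0), smap.shape)
            smap = smap + _psi(aligned)
        else:
            # dense layer: spatially (or feature-wise) uniform contribution
            smap = smap + _psi(np.full(smap.shape, np.abs(contrib).sum()))
    peak = smap.max()
    if peak > 0:
        smap = smap / peak
    node = path.node_sequence[0]
    return AttributionMap(values={node: smap}, method="fullgrad",
                          normalization="per-layer max, final rescale to [0,1]")


_PATH_INPUT_FIELDS = {
    "mri_raw": "mri_volume", "pet_raw": "pet_volume",
    "mri_stripped": "mri_brain", "pet_stripped": "pet_brain",
    "roi_volume": "roi_volume", "roi_thickness": "roi_thickness",
    "roi_surface": "roi_surface", "cognitive": "cognitive",
}


def saliency_all_nodes(graph: ModelGraph, subject: SubjectRecord,
                       target_class: int = 1, n_slices: int = 8
                       ) -> AttributionMap:
    """Saliency at every node along each diagnosis path.

    For each node on paths 1-7 (excluding the label sink) the map is the
    full-gradient saliency of the sub-path from that node to the label.
    Every edge on a sub-path must be trained.
    """
    from .slices import SliceStack, normalize_slices

    values: Dict[str, np.ndarray] = {}
    for name, node_seq in graph.enumerate_paths().items():
        if node_seq[-1] != "label":
            continue
        for start in range(len(node_seq) - 1):
            sub_nodes = node_seq[start:]
            sub = compose_path(graph, sub_nodes)
            for edge in sub.edges:
                if not getattr(edge.transform, "trained", False):
                    raise UntrainedEdgeError(
                        f"edge {edge.id!r} on path {name!r} is untrained")
            datum = _node_datum(subject, sub_nodes[0], graph, n_slices)
            if datum is None:
                continue
            amap = fullgrad_saliency(sub, datum, target_class=target_class)
            values[sub_nodes[0]] = amap.values[sub_nodes[0]]
    return AttributionMap(values=values, method="fullgrad",
                          normalization="per-layer max, final rescale to [0,1]")


def _node_datum(subject: SubjectRecord, node_id: str, graph: ModelGraph,
                n_slices: int) -> Optional[np.ndarray]:
    from .slices import SliceStack, normalize_slices

    fieldname = _PATH_INPUT_FIELDS.get(node_id)
    if fieldname is None:
        return None
    raw = getattr(subject, fieldname)
    if raw is None:
        return None
    if fieldname == "gene":
        return np.array([float(raw)])
    arr = np.asarray(raw, dtype=float)
    if node_id == "gene":
        return np.array([float(raw)])
    if arr.ndim == 3:
        return normalize_slices(SliceStack(arr), n_slices).data
    return arr


# ---------------------------------------------------------------------------
# Fusion-MLP attribution
# ---------------------------------------------------------------------------
def layer1_importance(mlp: FusionMLP,
                      groups: Sequence[str] = MODALITIES) -> AttributionMap:
    """Mean |weight| of first-layer connections incident to each group's
    two input columns."""
    w = np.abs(mlp.fc1.weight.data)  # (14, width)
    values: Dict[str, np.ndarray] = {}
    for g, name in enumerate(groups):
        cols = (2 * g, 2 * g + 1)
        if max(cols) >= w.shape[0]:
            raise ValueError(f"group {name!r} columns {cols} out of range")
        values[name] = np.array(w[list(cols), :].mean())
    return AttributionMap(values=values, method="layer1_weights")


def _coalition_values(mlp: FusionMLP, sv: ScoreVector) -> Dict[frozenset, float]:
    """Model AD-probability for every coalition (out-of-coalition groups
    masked to the fill value); one batched forward over all 2^7 coalitions."""
    full = sv.flat()
    coalitions = []
    batch = np.empty((2 ** N_GROUPS, 14))
    for i in range(2 ** N_GROUPS):
        members = frozenset(g for g in range(N_GROUPS) if i >> g & 1)
        coalitions.append(members)
        row = np.full(14, MASK_FILL)
        for g in members:
            row[2 * g:2 * g + 2] = full[2 * g:2 * g + 2]
        batch[i] = row
    probs = mlp.predict_proba(batch)[:, 1]
    return dict(zip(coalitions, probs))


def shapley_modalities(mlp: FusionMLP, sv: ScoreVector) -> AttributionMap:
    """Exact Shapley value per modality group by enumerating all 2^7
    coalitions; the coalition value is the fused AD-probability with
    out-of-coalition groups masked to the fill baseline."""
    v = _coalition_values(mlp, sv)
    n = N_GROUPS
    values: Dict[str, np.ndarray] = {}
    for g in range(n):
        others = [j for j in range(n) if j != g]
        total = 0.0
        for size in range(n):
            weight = factorial(size) * factorial(n - size - 1) / factorial(n)
            for subset in combinations(others, size):
                s = frozenset(subset)
                total += weight * (v[s | {g}] - v[s])
        values[MODALITIES[g]] = np.array(total)
    return AttributionMap(values=values, method="shapley",
                          normalization="baseline = mask fill (0,0)")


def shapley_modalities_sampled(mlp: FusionMLP, sv: ScoreVector,
                               n_permutations: int = 2000,
                               seed: int = 0) -> AttributionMap:
    """Monte-Carlo permutation-sampling estimate of the Shapley values."""
    v = _coalition_values(mlp, sv)
    rng = np.random.default_rng(seed)
    totals = np.zeros(N_GROUPS)
    for _ in range(n_permutations):
        perm = rng.permutation(N_GROUPS)
        members: frozenset = frozenset()
        prev = v[members]
        for g in perm:
            members = members | {int(g)}
            cur = v[members]
            totals[g] += cur - prev
            prev = cur
    totals /= n_permutations
    return AttributionMap(values={m: np.array(t) for m, t in zip(MODALITIES, totals)},
                          method="shapley",
                          normalization=f"permutation sampling n={n_permutations}")
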