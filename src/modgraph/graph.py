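"""Typed directed graph of data nodes and differentiable model edges.

A node holds a :class:`~modgraph.spaces.DataSpace`; an edge holds a model
mapping its source space to its target space. Any directed path composes
into a :class:`PathPredictor` — a single differentiable map supporting
forward evaluation, input gradients, and fine-tuning with frozen subsets.
Edges are opaque registered objects exposing only (input_space,
output_space, apply, parameters); the graph never inspects their internals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .autodiff import Tensor
from .autodiff.optim import Adam
from .autodiff import functional as F
from .spaces import DataSpace


class GraphConfigError(ValueError):
    """Graph construction rejected (missing space, duplicate id, ...)."""


class SpaceMismatchError(GraphConfigError):
    """Edge's declared spaces do not equal its endpoints' spaces."""


class PathError(ValueError):
    """Requested path cannot be assembled (gap between consecutive nodes)."""


class AmbiguousEdgeError(PathError):
    """Parallel edges between a node pair and no edge id given."""


class ContractViolationError(RuntimeError):
    """A non-differentiable edge inside an operation that needs gradients."""


# ---------------------------------------------------------------------------
# Edge models
# ---------------------------------------------------------------------------
class EdgeModel:
    """Base class for the differentiable map carried by an edge.

    Subclasses must set `input_space` / `output_space` and implement
    `apply(x: Tensor) -> Tensor`. `differentiable` is False only for
    sampling edges (e.g. ancestral diffusion sampling), which support
    forward evaluation but refuse gradient-based operations.
    """

    input_space: DataSpace
    output_space: DataSpace
    differentiable: bool = True
    model_type: str = "custom"
    trained: bool = False

    def apply(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def parameters(self) -> List[Tensor]:
        return []

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        if state:
            raise ValueError("stateless edge cannot load parameters")

    def train(self, mode: bool = True) -> None:
        pass


class LinearMapEdge(EdgeModel):
    """y = A x (+ b). The workhorse of the analytic oracle tests."""

    model_type = "linear_map"

    def __init__(self, input_space: DataSpace, output_space: DataSpace,
                 matrix: np.ndarray, bias: Optional[np.ndarray] = None,
                 trainable: bool = True):
        self.input_space = input_space
        self.output_space = output_space
        self.matrix = Tensor(np.asarray(matrix, dtype=float), requires_grad=trainable)
        n_out = self.matrix.shape[0]
        b = np.zeros(n_out) if bias is None else np.asarray(bias, dtype=float)
        self.bias = Tensor(b, requires_grad=trainable)

    def apply(self, x: Tensor) -> Tensor:
        if x.ndim != 1:
            raise ValueError("LinearMapEdge expects a 1-D feature vector")
        return self.matrix @ x + self.bias

    def parameters(self) -> List[Tensor]:
        return [self.matrix, self.bias]

    def state_dict(self):
        return {"matrix": self.matrix.data.copy(), "bias": self.bias.data.copy()}

    def load_state_dict(self, state):
        self.matrix.data = state["matrix"].copy()
        self.bias.data = state["bias"].copy()


class FunctionEdge(EdgeModel):
    """Stateless edge wrapping a Tensor->Tensor function."""

    model_type = "function"

    def __init__(self, input_space: DataSpace, output_space: DataSpace,
                 fn: Callable[[Tensor], Tensor], differentiable: bool = True):
        self.input_space = input_space
        self.output_space = output_space
        self.fn = fn
        self.differentiable = differentiable

    def apply(self, x: Tensor) -> Tensor:
        return self.fn(x)


class ModuleEdge(EdgeModel):
    """Edge wrapping an autodiff nn.Module between two declared spaces."""

    def __init__(self, input_space: DataSpace, output_space: DataSpace,
                 module, model_type: str = "module",
                 apply_fn: Optional[Callable] = None):
        self.input_space = input_space
        self.output_space = output_space
        self.module = module
        self.model_type = model_type
        self._apply_fn = apply_fn

    def apply(self, x: Tensor) -> Tensor:
        if self._apply_fn is not None:
            return self._apply_fn(self.module, x)
        return self.module(x)

    def parameters(self) -> List[Tensor]:
        return list(self.module.parameters())

    def state_dict(self):
        return self.module.state_dict()

    def load_state_dict(self, state):
        self.module.load_state_dict(state)

    def train(self, mode: bool = True) -> None:
        self.module.train(mode)


# ---------------------------------------------------------------------------
# Graph structure
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class GraphNode:
    id: str
    space: DataSpace


@dataclass
class GraphEdge:
    id: str
    source: str
    target: str
    transform: EdgeModel
    trainable: bool = True


class ModelGraph:
    """Directed multigraph; parallel edges allowed with distinct ids."""

    def __init__(self):
        self.nodes: Dict[str, GraphNode] = {}
        self.edges: Dict[str, GraphEdge] = {}
        # declared source->sink path specifications (ordered node id lists)
        self.declared_paths: Dict[str, List[str]] = {}
        # metadata: which edges feed a collector node (e.g. the fusion input)
        self.feeder_edges: Dict[str, List[str]] = {}

    # ------------------------------------------------------------- building
    def add_node(self, node_id: str, space: DataSpace) -> GraphNode:
        if node_id in self.nodes:
            raise GraphConfigError(f"duplicate node id {node_id!r}")
        node = GraphNode(node_id, space)
        self.nodes[node_id] = node
        return node

    def add_edge(self, edge_id: str, source: str, target: str,
                 transform: EdgeModel, trainable: bool = True) -> GraphEdge:
        if edge_id in self.edges:
            raise GraphConfigError(f"duplicate edge id {edge_id!r}")
        for endpoint in (source, target):
            if endpoint not in self.nodes:
                raise GraphConfigError(f"edge {edge_id!r}: unknown node {endpoint!r}")
        src_space = self.nodes[source].space
        tgt_space = self.nodes[target].space
        if transform.input_space.numeric_shape != src_space.numeric_shape or \
           transform.input_space.kind != src_space.kind:
            raise SpaceMismatchError(
                f"edge {edge_id!r}: declared input space "
                f"{transform.input_space.name!r} {transform.input_space.numeric_shape} "
                f"!= source node space {src_space.name!r} {src_space.numeric_shape}")
        if transform.output_space.numeric_shape != tgt_space.numeric_shape or \
           transform.output_space.kind != tgt_space.kind:
            raise SpaceMismatchError(
                f"edge {edge_id!r}: declared output space "
                f"{transform.output_space.name!r} {transform.output_space.numeric_shape} "
                f"!= target node space {tgt_space.name!r} {tgt_space.numeric_shape}")
        edge = GraphEdge(edge_id, source, target, transform, trainable)
        self.edges[edge_id] = edge
        return edge

    def declare_path(self, name: str, node_ids: Sequence[str]) -> None:
        for nid in node_ids:
            if nid not in self.nodes:
                raise GraphConfigError(f"path {name!r}: unknown node {nid!r}")
        self.declared_paths[name] = list(node_ids)

    # ------------------------------------------------------------- querying
    def edges_between(self, source: str, target: str) -> List[GraphEdge]:
        return [e for e in self.edges.values()
                if e.source == source and e.target == target]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def enumerate_paths(self) -> Dict[str, List[str]]:
        """The declared source->sink paths (the graph has generative cycles,
        so free topological enumeration is not meaningful)."""
        return dict(self.declared_paths)

    # -------------------------------------------------------- serialisation
    def topology_dict(self) -> dict:
        return {
            "nodes": [{"id": n.id, **n.space.to_dict()} for n in self.nodes.values()],
            "edges": [{"id": e.id, "source": e.source, "target": e.target,
                       "model_type": e.transform.model_type,
                       "trainable": e.trainable}
                      for e in self.edges.values()],
            "paths": {k: list(v) for k, v in self.declared_paths.items()},
            "feeders": {k: list(v) for k, v in self.feeder_edges.items()},
        }

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.topology_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, edge_factory: Callable[[dict, DataSpace, DataSpace], EdgeModel]) -> "ModelGraph":
        """Rebuild a graph from a topology document.

        `edge_factory(edge_dict, input_space, output_space)` must return a
        fresh EdgeModel of the recorded model_type.
        """
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        g = cls()
        for nd in doc["nodes"]:
            g.add_node(nd["id"], DataSpace.from_dict(nd))
        for ed in doc["edges"]:
            src = g.nodes[ed["source"]].space
            tgt = g.nodes[ed["target"]].space
            g.add_edge(ed["id"], ed["source"], ed["target"],
                       edge_factory(ed, src, tgt), trainable=ed.get("trainable", True))
        for name, seq in doc.get("paths", {}).items():
            g.declare_path(name, seq)
        g.feeder_edges = {k: list(v) for k, v in doc.get("feeders", {}).items()}
        return g


# ---------------------------------------------------------------------------
# Path composition (the composite predictor F_P)
# ---------------------------------------------------------------------------
@dataclass
class PathPredictor:
    """Composite predictor along a node sequence n_1 ... n_k.

    The composite applies the listed edges in order:
    F(x) = f_{k-1,k} ∘ ... ∘ f_{1,2}(x); a single-node path is the identity.
    """

    node_sequence: List[str]
    edge_sequence: List[str]
    edges: List[GraphEdge]
    input_space: DataSpace
    output_space: DataSpace

    def forward_tensor(self, x: Tensor) -> Tensor:
        h = x
        for edge in self.edges:
            h = edge.transform.apply(h)
        return h

    def __call__(self, x: np.ndarray) -> np.ndarray:
        self.input_space.validate(np.asarray(x, dtype=float))
        return self.forward_tensor(Tensor(np.asarray(x, dtype=float))).data

    @property
    def differentiable(self) -> bool:
        return all(e.transform.differentiable for e in self.edges)


def compose_path(graph: ModelGraph, node_ids: Sequence[str],
                 edge_ids: Optional[Sequence[str]] = None) -> PathPredictor:
    """Compose the edges along `node_ids` into a PathPredictor.

    Consecutive node pairs must be connected by exactly one edge, or
    `edge_ids` must name the edge for every hop (disambiguating parallels).
    A single-node path yields the identity predictor.
    """
    node_ids = list(node_ids)
    if not node_ids:
        raise PathError("empty node sequence")
    for nid in node_ids:
        if nid not in graph.nodes:
            raise PathError(f"unknown node {nid!r}")
    hops = list(zip(node_ids[:-1], node_ids[1:]))
    chosen: List[GraphEdge] = []
    if edge_ids is not None:
        if len(edge_ids) != len(hops):
            raise PathError(f"need {len(hops)} edge ids, got {len(edge_ids)}")
        for (src, tgt), eid in zip(hops, edge_ids):
            edge = graph.edges.get(eid)
            if edge is None or edge.source != src or edge.target != tgt:
                raise PathError(f"edge {eid!r} does not connect {src!r} -> {tgt!r}")
            chosen.append(edge)
    else:
        for src, tgt in hops:
            candidates = graph.edges_between(src, tgt)
            if not candidates:
                raise PathError(f"no edge connects {src!r} -> {tgt!r}")
            if len(candidates) > 1:
                raise AmbiguousEdgeError(
                    f"parallel edges {sorted(e.id for e in candidates)} between "
                    f"{src!r} and {tgt!r}; pass edge_ids to disambiguate")
            chosen.append(candidates[0])
    return PathPredictor(
        node_sequence=node_ids,
        edge_sequence=[e.id for e in chosen],
        edges=chosen,
        input_space=graph.nodes[node_ids[0]].space,
        output_space=graph.nodes[node_ids[-1]].space,
    )


ReductionSpec = Union[str, int, Tuple[str, int], Callable[[Tensor], Tensor]]


def _reduce_output(out: Tensor, spec: ReductionSpec) -> Tensor:
    if callable(spec):
        return spec(out)
    if spec == "sum":
        return out.sum()
    if isinstance(spec, int):
        return out.reshape(-1)[spec].sum() if out.ndim else out
    if isinstance(spec, tuple) and spec[0] == "logit":
        return out.reshape(-1)[spec[1]].sum()
    raise ValueError(f"unknown reduction spec {spec!r}")


def path_gradient(path: PathPredictor, x: np.ndarray,
                  target_scalar: ReductionSpec = ("logit", 1)) -> np.ndarray:
    """Gradient of the reduced scalar output w.r.t. every element of x.

    The default reduction selects the AD logit/probability (index 1),
    matching saliency usage. Returns an array with the shape of x.
    """
    for edge in path.edges:
        if not edge.transform.differentiable:
            raise ContractViolationError(
                f"edge {edge.id!r} is not differentiable; path gradient undefined")
    xt = Tensor(np.asarray(x, dtype=float).copy(), requires_grad=True)
    out = path.forward_tensor(xt)
    scalar = _reduce_output(out, target_scalar)
    scalar.backward()
    return np.zeros_like(xt.data) if xt.grad is None else xt.grad


def finetune_path(path: PathPredictor, data: Sequence[Tuple[np.ndarray, np.ndarray]],
                  loss: Union[str, Callable[[Tensor, np.ndarray], Tensor]] = "mse",
                  frozen: Iterable[str] = (), epochs: int = 50,
                  lr: float = 1e-2) -> dict:
    """Fine-tune the non-frozen edges of a path on paired samples.

    loss: "mse", "cross_entropy", or a callable (prediction, target)->Tensor.
    Returns a report with the per-epoch loss trajectory and the set of edges
    actually updated. If every edge is frozen the call is a warned no-op.
    """
    frozen = set(frozen)
    unknown = frozen - set(path.edge_sequence)
    if unknown:
        raise ValueError(f"frozen edge ids not on path: {sorted(unknown)}")
    params: List[Tensor] = []
    updated: List[str] = []
    for edge in path.edges:
        if edge.id in frozen or not edge.trainable:
            continue
        ps = edge.transform.parameters()
        if ps:
            params.extend(ps)
            updated.append(edge.id)
    if not params:
        warnings.warn("all edges frozen or parameter-free; finetune_path is a no-op")
        return {"updated_edges": [], "losses": [], "no_op": True}

    if loss == "mse":
        loss_fn = lambda pred, y: F.mse(pred, Tensor(np.asarray(y, dtype=float)))
    elif loss == "cross_entropy":
        loss_fn = lambda pred, y: -(Tensor(np.asarray(y, dtype=float)) *
                                    (pred + 1e-12).log()).sum()
    elif callable(loss):
        loss_fn = loss
    else:
        raise ValueError(f"unknown loss spec {loss!r}")

    for edge in path.edges:
        edge.transform.train(True)
    opt = Adam(params, lr=lr)
    losses: List[float] = []
    for _ in range(epochs):
        total = 0.0
        for x, y in data:
            opt.zero_grad()
            pred = path.forward_tensor(Tensor(np.asarray(x, dtype=float)))
            lval = loss_fn(pred, y)
            lval.backward()
            opt.step()
            total += float(lval.data)
        losses.append(total / max(len(data), 1))
    for edge in path.edges:
        edge.transform.train(False)
    return {"updated_edges": updated, "losses": losses, "no_op": False}
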