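"""The default AD-diagnosis graph: 11 data nodes, 14 model edges, 11
declared source-to-sink paths.

Nodes: raw MRI/PET volumes, their skull-stripped counterparts, three ROI
feature vectors (volume/thickness/surface), the APOE4 carrier flag, the
cognitive-score vector, the fusion-input score block, and the AD/CN label.
Edges: two skull-strippers, seven diagnosis classifiers ending at the label
node, two MRI<->PET translators, two label-conditioned diffusion samplers,
and the fusion MLP from the score block to the label. The seven classifier
outputs are wired to the fusion-input node as recorded feeder metadata (the
score block is assembled from their probability pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Union

import numpy as np

from .autodiff import Tensor
from .autodiff import functional as F
from .classify import FeatureClassifier, SliceClassifier
from .cohort import COGNITIVE_NAMES
from .fusion import FusionMLP
from .generative import DiffusionBundle, DiffusionNet, NoiseSchedule, StyleTranslator
from .graph import EdgeModel, GraphConfigError, ModelGraph, ModuleEdge
from .skullstrip import SkullStripNet
from .spaces import DataSpace

_REQUIRED_DIMS = {
    "image_side": ("mri_raw", "pet_raw", "mri_stripped", "pet_stripped"),
    "n_slices": ("mri_raw", "pet_raw", "mri_stripped", "pet_stripped"),
    "n_roi": ("roi_volume", "roi_thickness", "roi_surface"),
}


@dataclass
class GraphConfig:
    """Desk-scale dimensions for every data space in the default graph."""

    image_side: int = 32
    n_slices: int = 8
    n_roi: int = 8
    seed: int = 0
    diffusion_T: int = 200

    @classmethod
    def from_mapping(cls, mapping: Dict) -> "GraphConfig":
        missing = [key for key in ("image_side", "n_slices", "n_roi")
                   if key not in mapping]
        if missing:
            nodes = sorted({n for key in missing for n in _REQUIRED_DIMS[key]})
            raise GraphConfigError(
                f"graph config missing {missing}; required for node spaces {nodes}")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(mapping) - known
        if unknown:
            raise GraphConfigError(f"unknown graph config keys: {sorted(unknown)}")
        return cls(**mapping)


# ---------------------------------------------------------------------------
# Edge wrappers
# ---------------------------------------------------------------------------
def _slicewise(module, x: Tensor) -> Tensor:
    """(n,S,S) volume -> (n,1,S,S) batch -> module -> (n,S,S)."""
    n, s, _ = x.shape
    out = module(x.reshape(n, 1, s, s))
    return out.reshape(n, s, s)


def _image_classifier_apply(module: SliceClassifier, x: Tensor) -> Tensor:
    n, s, _ = x.shape
    logits = module(x.reshape(n, 1, s, s))
    return F.softmax(logits, axis=-1).mean(axis=0)


def _feature_classifier_apply(module, x: Tensor) -> Tensor:
    logits = module(x.reshape(1, -1))
    return F.softmax(logits, axis=-1).reshape(2)


def _translator_apply(module: StyleTranslator, x: Tensor) -> Tensor:
    n, s, _ = x.shape
    z = Tensor(np.zeros((n, module.z_dim)))  # deterministic edge: z = 0
    return module(x.reshape(n, 1, s, s), z).reshape(n, s, s)


def _fusion_apply(module: FusionMLP, x: Tensor) -> Tensor:
    logits = module(x.reshape(1, -1))
    return F.softmax(logits, axis=-1).reshape(2)


class DiffusionSamplerEdge(EdgeModel):
    """Label -> image-volume sampling edge (stochastic, non-differentiable).

    Forward evaluation draws `n_slices` slices by ancestral sampling with
    the label mask set from the argmax of the incoming probability pair.
    Gradient-based operations refuse this edge.
    """

    differentiable = False
    model_type = "label2image_diffusion"

    def __init__(self, input_space: DataSpace, output_space: DataSpace,
                 bundle: DiffusionBundle, n_slices: int, side: int,
                 sample_seed: int = 0):
        self.input_space = input_space
        self.output_space = output_space
        self.bundle = bundle
        self.n_slices = n_slices
        self.side = side
        self.sample_seed = sample_seed

    def apply(self, x: Tensor) -> Tensor:
        from .generative import sample_label2image

        label = int(np.argmax(x.data))
        images = sample_label2image(self.bundle, label, self.n_slices,
                                    self.sample_seed, side=self.side)
        return Tensor(images)

    def parameters(self):
        return list(self.bundle.eps_net.parameters())

    def state_dict(self):
        return self.bundle.eps_net.state_dict()

    def load_state_dict(self, state):
        self.bundle.eps_net.load_state_dict(state)
        self.bundle.trained = True


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------
def build_default_ad_graph(config: Union[GraphConfig, Dict, None] = None
                           ) -> ModelGraph:
    """Build the full default topology with freshly initialised models.

    All parameter initialisation flows from ``config.seed``.
    """
    if config is None:
        config = GraphConfig()
    elif isinstance(config, dict):
        config = GraphConfig.from_mapping(config)

    s, k, r = config.image_side, config.n_slices, config.n_roi
    rng = np.random.default_rng(config.seed)

    vol = lambda name: DataSpace(name, "image_volume", (k, s, s), range=(0.0, 1.0))
    g = ModelGraph()
    g.add_node("mri_raw", vol("mri_raw"))
    g.add_node("pet_raw", vol("pet_raw"))
    g.add_node("mri_stripped", vol("mri_stripped"))
    g.add_node("pet_stripped", vol("pet_stripped"))
    g.add_node("roi_volume", DataSpace("roi_volume", "feature_vector", (r,)))
    g.add_node("roi_thickness", DataSpace("roi_thickness", "feature_vector", (r,)))
    g.add_node("roi_surface", DataSpace("roi_surface", "feature_vector", (r,)))
    g.add_node("gene", DataSpace("gene", "feature_vector", (1,)))
    g.add_node("cognitive", DataSpace("cognitive", "feature_vector", COGNITIVE_NAMES))
    g.add_node("scores", DataSpace("scores", "feature_vector", (14,)))
    g.add_node("label", DataSpace("label", "probability_pair", (2,)))

    def child_rng():
        return np.random.default_rng(rng.integers(2 ** 31))

    space = lambda nid: g.nodes[nid].space

    # skull-stripping edges (direct image regression)
    for mod in ("mri", "pet"):
        g.add_edge(f"strip_{mod}", f"{mod}_raw", f"{mod}_stripped",
                   ModuleEdge(space(f"{mod}_raw"), space(f"{mod}_stripped"),
                              SkullStripNet(child_rng()), model_type="unet_strip",
                              apply_fn=_slicewise))

    # image classifier edges (slice scores averaged to a subject pair)
    for mod in ("mri", "pet"):
        g.add_edge(f"classify_{mod}", f"{mod}_stripped", "label",
                   ModuleEdge(space(f"{mod}_stripped"), space("label"),
                              SliceClassifier(child_rng(), n_slices_expected=k),
                              model_type="resnet_classifier",
                              apply_fn=_image_classifier_apply))

    # feature classifier edges
    for node in ("roi_volume", "roi_thickness", "roi_surface", "gene", "cognitive"):
        n_features = space(node).numeric_shape[0]
        g.add_edge(f"classify_{node}", node, "label",
                   ModuleEdge(space(node), space("label"),
                              FeatureClassifier(n_features, child_rng()),
                              model_type="feature_mlp",
                              apply_fn=_feature_classifier_apply))

    # image-to-image translation edges
    g.add_edge("mri2pet", "mri_stripped", "pet_stripped",
               ModuleEdge(space("mri_stripped"), space("pet_stripped"),
                          StyleTranslator(child_rng()), model_type="style_translator",
                          apply_fn=_translator_apply))
    g.add_edge("pet2mri", "pet_stripped", "mri_stripped",
               ModuleEdge(space("pet_stripped"), space("mri_stripped"),
                          StyleTranslator(child_rng()), model_type="style_translator",
                          apply_fn=_translator_apply))

    # label-conditioned diffusion sampling edges
    for mod in ("mri", "pet"):
        bundle = DiffusionBundle(eps_net=DiffusionNet(child_rng()),
                                 schedule=NoiseSchedule(T=config.diffusion_T))
        g.add_edge(f"label2{mod}", "label", f"{mod}_stripped",
                   DiffusionSamplerEdge(space("label"), space(f"{mod}_stripped"),
                                        bundle, n_slices=k, side=s))

    # fusion edge
    g.add_edge("fuse", "scores", "label",
               ModuleEdge(space("scores"), space("label"), FusionMLP(child_rng()),
                          model_type="fusion_mlp", apply_fn=_fusion_apply))

    g.feeder_edges["scores"] = ["classify_mri", "classify_pet",
                                "classify_roi_volume", "classify_roi_thickness",
                                "classify_roi_surface", "classify_gene",
                                "classify_cognitive"]

    g.declare_path("path_01_mri", ["mri_raw", "mri_stripped", "label"])
    g.declare_path("path_02_pet", ["pet_raw", "pet_stripped", "label"])
    g.declare_path("path_03_roi_volume", ["roi_volume", "label"])
    g.declare_path("path_04_roi_thickness", ["roi_thickness", "label"])
    g.declare_path("path_05_roi_surface", ["roi_surface", "label"])
    g.declare_path("path_06_gene", ["gene", "label"])
    g.declare_path("path_07_cognitive", ["cognitive", "label"])
    g.declare_path("path_08_mri2pet", ["mri_stripped", "pet_stripped"])
    g.declare_path("path_09_pet2mri", ["pet_stripped", "mri_stripped"])
    g.declare_path("path_10_label2mri", ["label", "mri_stripped"])
    g.declare_path("path_11_label2pet", ["label", "pet_stripped"])
    return g
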