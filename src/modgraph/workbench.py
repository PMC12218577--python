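"""Experiment configuration, checkpointing, and the end-to-end runner.

One experiment = one directory; nothing is written outside it. Every stage
draws its randomness from the single experiment seed and logs structured
lines (stage, seed, metric, value) so downstream tooling parses logs rather
than scraping stdout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .cohort import CohortConfig, generate_cohort
from .default_graph import GraphConfig
from .fusion import FusionMLP, MissingProtocol, evaluate_missing, train_fusion
from .graph import GraphEdge
from .interpret import layer1_importance, shapley_modalities
from .metrics import balanced_accuracy
from .scoring import score_table
from .skullstrip import SkullStripNet, strip_and_iou, train_skullstrip
from .slices import SliceStack

logger = logging.getLogger("modgraph.workbench")


@dataclass
class TrainingConfig:
    folds: int = 3
    n_slices: int = 4
    image_epochs: int = 2
    feature_epochs: int = 40
    fusion_epochs: int = 120
    skullstrip_epochs: int = 4


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(
        n_subjects=60, image_side=24, n_slices_range=(4, 6)))
    graph: GraphConfig = field(default_factory=lambda: GraphConfig(
        image_side=24, n_slices=4))
    training: TrainingConfig = field(default_factory=TrainingConfig)
    protocols: List[MissingProtocol] = field(default_factory=lambda: [
        MissingProtocol(mode="random_k", k=0, repetitions=1),
        MissingProtocol(mode="random_k", k=5, repetitions=20)])
    seed: int = 0
    output_dir: str = "experiment_out"

    # -------------------------------------------------------- serialisation
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["n_slices_range"] = list(self.cohort.n_slices_range)
        for p in d["protocols"]:
            p["features"] = list(p["features"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        def build(klass, sub: dict):
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(
                    f"unknown keys in {klass.__name__}: {sorted(unknown)}")
            return klass(**sub)

        known_top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: Dict = {}
        if "cohort" in doc:
            sub = dict(doc["cohort"])
            if "n_slices_range" in sub:
                sub["n_slices_range"] = tuple(sub["n_slices_range"])
            kwargs["cohort"] = build(CohortConfig, sub)
        if "graph" in doc:
            kwargs["graph"] = build(GraphConfig, dict(doc["graph"]))
        if "training" in doc:
            kwargs["training"] = build(TrainingConfig, dict(doc["training"]))
        if "protocols" in doc:
            protos = []
            for p in doc["protocols"]:
                sub = dict(p)
                if "features" in sub:
                    sub["features"] = tuple(sub["features"])
                protos.append(build(MissingProtocol, sub))
            kwargs["protocols"] = protos
        for key in ("seed", "output_dir"):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------
def save_checkpoint(edge: GraphEdge, path) -> None:
    """One file per edge: parameters plus the declared spaces."""
    meta = {
        "edge_id": edge.id,
        "model_type": edge.transform.model_type,
        "input_space": edge.transform.input_space.to_dict(),
        "output_space": edge.transform.output_space.to_dict(),
    }
    state = edge.transform.state_dict()
    np.savez(path, __meta__=json.dumps(meta),
             **{f"param/{k}": v for k, v in state.items()})


def load_checkpoint(edge: GraphEdge, path) -> None:
    """Refuse to load when spaces or model type mismatch; never resize."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    for side in ("input_space", "output_space"):
        stored = meta[side]
        declared = getattr(edge.transform, side).to_dict()
        if stored["kind"] != declared["kind"] or \
                list(stored["shape"]) != list(declared["shape"]):
            raise ValueError(
                f"checkpoint refuses to load into edge {edge.id!r}: stored "
                f"{side} {stored} != declared {declared}")
    if meta["model_type"] != edge.transform.model_type:
        raise ValueError(
            f"checkpoint model type {meta['model_type']!r} != edge "
            f"{edge.transform.model_type!r}")
    edge.transform.load_state_dict(state)
    edge.transform.trained = True


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------
def _log_metric(stage: str, seed: int, metric: str, value) -> None:
    logger.info("stage=%s seed=%d metric=%s value=%s", stage, seed, metric, value)


def run_experiment(config: ExperimentConfig) -> dict:
    """simulate -> train edges -> score -> fuse -> protocols -> explain.

    Returns (and writes) a manifest with the config hash, per-stage seeds,
    metrics and output file paths. Re-running the same config reproduces
    every metric bit-exactly; only the timestamp differs.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "files": {},
        "completed": [],
        "failed_stage": None,
    }
    seed = config.seed
    tr = config.training

    def finish() -> dict:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        manifest["files"]["manifest"] = str(out_dir / "manifest.json")
        return manifest

    stage = "simulate"
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=seed)
        cohort = generate_cohort(cohort_cfg)
        n_ad = sum(r.y for r in cohort)
        manifest["stages"][stage] = {"n_subjects": len(cohort), "n_ad": n_ad,
                                     "seed": seed}
        _log_metric(stage, seed, "n_subjects", len(cohort))
        manifest["completed"].append(stage)

        stage = "skullstrip"
        with_mri = [r for r in cohort if r.mri_volume is not None]
        split = max(len(with_mri) // 2, 5)
        pairs = [(s, b) for rec in with_mri[:split]
                 for s, b in zip(rec.mri_volume, rec.mri_brain)]
        net = SkullStripNet(np.random.default_rng(seed + 1))
        report = train_skullstrip(net, pairs, epochs=tr.skullstrip_epochs,
                                  seed=seed + 1)
        ious = [strip_and_iou(net, SliceStack(rec.mri_volume),
                              rec.mri_brain > 0)
                for rec in with_mri[split:split + 10]]
        manifest["stages"][stage] = {
            "val_mse_untrained": report["val_mse_untrained"],
            "val_mse_trained": report["val_mse_trained"],
            "mean_iou": float(np.mean(ious)), "seed": seed + 1}
        _log_metric(stage, seed + 1, "mean_iou", float(np.mean(ious)))
        manifest["completed"].append(stage)

        stage = "score"
        frame, results = score_table(
            cohort, folds=tr.folds, seed=seed + 2, n_slices=tr.n_slices,
            image_epochs=tr.image_epochs, feature_epochs=tr.feature_epochs)
        frame.to_csv(out_dir / "scores.csv", index=False, float_format="%.17g")
        manifest["files"]["scores"] = str(out_dir / "scores.csv")
        manifest["stages"][stage] = {
            "per_modality_bac": {m: r.mean_bac for m, r in results.items()},
            "seed": seed + 2}
        for m, r in results.items():
            _log_metric(stage, seed + 2, f"bac_{m}", r.mean_bac)
        manifest["completed"].append(stage)

        stage = "fuse"
        mlp = FusionMLP(np.random.default_rng(seed + 3))
        train_fusion(mlp, frame, epochs=tr.fusion_epochs, seed=seed + 3)
        protocol_metrics = {}
        for i, protocol in enumerate(config.protocols):
            mlp_bac, mlp_se = evaluate_missing(mlp, frame, protocol, seed=seed + 4 + i)
            vote_bac, vote_se = evaluate_missing("vote", frame, protocol,
                                                 seed=seed + 4 + i)
            key = f"{protocol.mode}_k{protocol.k}" if protocol.mode == "random_k" \
                else f"{protocol.mode}_{'_'.join(protocol.features)}"
            protocol_metrics[key] = {"mlp_bac": mlp_bac, "mlp_se": mlp_se,
                                     "vote_bac": vote_bac, "vote_se": vote_se}
            _log_metric(stage, seed + 4 + i, f"{key}_mlp", mlp_bac)
            _log_metric(stage, seed + 4 + i, f"{key}_vote", vote_bac)
        manifest["stages"][stage] = {"protocols": protocol_metrics,
                                     "seed": seed + 3}
        manifest["completed"].append(stage)

        stage = "explain"
        from .fusion import frame_to_scores
        weights_map = layer1_importance(mlp)
        vectors = frame_to_scores(frame)[:20]
        shap_abs = {m: 0.0 for m in weights_map.values}
        for sv in vectors:
            smap = shapley_modalities(mlp, sv)
            for m, v in smap.values.items():
                shap_abs[m] += abs(float(v)) / len(vectors)
        explain = {"layer1": {m: float(v) for m, v in weights_map.values.items()},
                   "mean_abs_shapley": shap_abs, "seed": seed + 3}
        with open(out_dir / "attribution.json", "w") as fh:
            json.dump(explain, fh, indent=2, sort_keys=True)
        manifest["files"]["attribution"] = str(out_dir / "attribution.json")
        manifest["stages"][stage] = explain
        manifest["completed"].append(stage)
    except Exception as exc:  # record partial completion
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        logger.error("stage=%s failed: %s", stage, exc)
    return finish()
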