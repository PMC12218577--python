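"""Desk-scale experiment protocols.

Each function runs one of the framework's headline experiments end-to-end on
a freshly generated synthetic cohort and returns its metrics: fusion-layer
robustness to missing modalities (with the majority-vote ensemble baseline
and the synthetic-PET substitution), classifier-guidance ablations for the
translation GAN and the label-conditioned diffusion model, the
skull-stripping ablation, and lesion localisation of path saliency.

Problem sizes default to values a single CPU handles in minutes; every
source of randomness derives from the `seed` argument.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .autodiff import functional as F
from .classify import (SliceClassifier, classify_subject, subject_score,
                       train_feature_classifier, train_image_classifier)
from .cohort import MODALITIES, CohortConfig, SubjectRecord, generate_cohort
from .fusion import (FusionMLP, MissingProtocol, evaluate_missing,
                     scores_to_frame, substitute_synthetic_pet, train_fusion,
                     ScoreVector)
from .generative import (DiffusionBundle, DiffusionNet, FrozenConvEmbedder,
                         GanBundle, GanLossConfig, NoiseSchedule,
                         PatchDiscriminator, StyleTranslator,
                         class_relevance_accuracy, sample_label2image,
                         train_diffusion, train_img2img)
from .metrics import balanced_accuracy
from .slices import SliceStack, normalize_slices


def _softmax_handle(clf: SliceClassifier):
    return lambda imgs: F.softmax(clf(imgs), axis=-1)


def split_cohort(cohort: Sequence[SubjectRecord], test_fraction: float,
                 seed: int) -> Tuple[List[SubjectRecord], List[SubjectRecord]]:
    """Stratified subject-level train/test split."""
    rng = np.random.default_rng(seed)
    idx_ad = [i for i, r in enumerate(cohort) if r.y == 1]
    idx_cn = [i for i, r in enumerate(cohort) if r.y == 0]
    rng.shuffle(idx_ad)
    rng.shuffle(idx_cn)
    n_ad = int(round(len(idx_ad) * test_fraction))
    n_cn = int(round(len(idx_cn) * test_fraction))
    test = set(idx_ad[:n_ad] + idx_cn[:n_cn])
    return ([cohort[i] for i in range(len(cohort)) if i not in test],
            [cohort[i] for i in sorted(test)])


def train_modality_models(train_recs: Sequence[SubjectRecord], seed: int,
                          n_slices: int = 4, image_epochs: int = 8,
                          feature_epochs: int = 40) -> Dict[str, object]:
    """One classifier per modality, trained on the training subjects."""
    models: Dict[str, object] = {}
    for j, modality in enumerate(MODALITIES):
        rng = np.random.default_rng(seed * 100 + j)
        usable = [r for r in train_recs if r.available.get(modality, False)]
        if modality in ("mri", "pet"):
            models[modality] = train_image_classifier(
                usable, modality, rng, n_slices=n_slices, epochs=image_epochs)
        else:
            models[modality] = train_feature_classifier(
                usable, modality, rng, epochs=feature_epochs)
    return models


def score_with_models(models: Dict[str, object],
                      records: Sequence[SubjectRecord],
                      n_slices: int = 4) -> pd.DataFrame:
    """Score every record with the trained models -> fusion score table."""
    vectors = []
    for rec in records:
        scores = np.zeros((7, 2))
        avail = np.zeros(7, bool)
        for g, modality in enumerate(MODALITIES):
            pair = subject_score(models[modality], rec, modality,
                                 n_slices=n_slices)
            if pair is not None:
                scores[g] = pair
                avail[g] = True
        vectors.append(ScoreVector(scores=scores, available=avail,
                                   label=rec.label, subject=rec.id))
    return scores_to_frame(vectors)


# ---------------------------------------------------------------------------
# Fusion robustness + synthetic-PET substitution
# ---------------------------------------------------------------------------
def fusion_robustness_experiment(seed: int, n_subjects: int = 200,
                                 image_side: int = 16, n_slices: int = 4,
                                 image_epochs: int = 8,
                                 fusion_epochs: int = 250,
                                 repetitions: int = 40,
                                 ks: Sequence[int] = (0, 1, 2, 3, 4, 5),
                                 with_substitution: bool = True) -> Dict:
    """Missing-modality robustness of the masked-trained fusion MLP against
    the majority-vote ensemble, plus the synthetic-PET substitution.

    Returns mlp_k{k} / vote_k{k} balanced accuracies on held-out subjects
    and the real/masked/synthetic PET fusion BACs.
    """
    cfg = CohortConfig(n_subjects=n_subjects, image_side=image_side,
                       n_slices_range=(4, 6), missing_rates={"pet": 0.15},
                       seed=seed)
    cohort = generate_cohort(cfg)
    train_recs, test_recs = split_cohort(cohort, test_fraction=0.4,
                                         seed=seed + 11)
    models = train_modality_models(train_recs, seed, n_slices=n_slices,
                                   image_epochs=image_epochs)
    frame_train = score_with_models(models, train_recs, n_slices=n_slices)
    frame_test = score_with_models(models, test_recs, n_slices=n_slices)

    mlp = FusionMLP(np.random.default_rng(seed + 21))
    train_fusion(mlp, frame_train, epochs=fusion_epochs, seed=seed + 21)

    out: Dict[str, float] = {}
    for k in ks:
        proto = MissingProtocol(mode="random_k", k=k, repetitions=repetitions)
        out[f"mlp_k{k}"], out[f"mlp_k{k}_se"] = evaluate_missing(
            mlp, frame_test, proto, seed=seed + 31)
        out[f"vote_k{k}"], out[f"vote_k{k}_se"] = evaluate_missing(
            "vote", frame_test, proto, seed=seed + 31)

    if with_substitution:
        pairs = []
        for rec in train_recs:
            if rec.pet_brain is None or rec.mri_brain is None:
                continue
            sm = normalize_slices(SliceStack(rec.mri_brain), n_slices).data
            sp = normalize_slices(SliceStack(rec.pet_brain), n_slices).data
            pairs.extend((a, b, rec.y) for a, b in zip(sm, sp))
        rng = np.random.default_rng(seed + 51)
        bundle = GanBundle(G=StyleTranslator(rng), D=PatchDiscriminator(rng),
                           C=_softmax_handle(models["pet"]),
                           phi=FrozenConvEmbedder(seed=123))
        train_img2img(bundle, pairs, weights=GanLossConfig(), epochs=5,
                      seed=seed + 51, lr=3e-3, track_frechet=False)
        out.update(substitute_synthetic_pet(
            frame_test, cohort, bundle.G, models["pet"], mlp,
            n_slices=n_slices, seed=seed + 61))
    return out


# ---------------------------------------------------------------------------
# Classifier-guidance ablations
# ---------------------------------------------------------------------------
def gan_guidance_experiment(seed: int, n_subjects: int = 80,
                            image_side: int = 16, n_slices: int = 4,
                            epochs: int = 5) -> Dict[str, float]:
    """Class-relevance accuracy of MRI->PET translation with and without the
    frozen-classifier loss term (lambda_C = 50 vs 0)."""
    cfg = CohortConfig(n_subjects=n_subjects, image_side=image_side,
                       n_slices_range=(4, 5), missing_rates={}, seed=seed)
    cohort = generate_cohort(cfg)
    train_recs, test_recs = cohort[:3 * n_subjects // 4], cohort[3 * n_subjects // 4:]
    clf = train_image_classifier(train_recs, "pet",
                                 np.random.default_rng(seed + 50),
                                 n_slices=n_slices, epochs=6)
    pairs = []
    for rec in train_recs:
        sm = normalize_slices(SliceStack(rec.mri_brain), n_slices).data
        sp = normalize_slices(SliceStack(rec.pet_brain), n_slices).data
        pairs.extend((a, b, rec.y) for a, b in zip(sm, sp))

    out = {}
    for tag, lam in (("guided", 50.0), ("unguided", 0.0)):
        rng = np.random.default_rng(seed)
        bundle = GanBundle(G=StyleTranslator(rng), D=PatchDiscriminator(rng),
                           C=_softmax_handle(clf), phi=FrozenConvEmbedder(seed=123))
        train_img2img(bundle, pairs, weights=GanLossConfig(lambda_c=lam),
                      epochs=epochs, seed=seed, lr=3e-3, track_frechet=False)
        hits = total = 0
        for rec in test_recs:
            sm = normalize_slices(SliceStack(rec.mri_brain), n_slices).data
            z = np.zeros((len(sm), bundle.G.z_dim))
            probs = _softmax_handle(clf)(bundle.G(Tensor(sm[:, None]),
                                                  Tensor(z))).data
            hits += int((np.argmax(probs, axis=1) == rec.y).sum())
            total += len(sm)
        out[tag] = hits / total
    return out


def diffusion_guidance_experiment(seed: int, n_subjects: int = 80,
                                  image_side: int = 16, n_slices: int = 4,
                                  T: int = 60, epochs: int = 6,
                                  n_per_label: int = 40) -> Dict[str, float]:
    """Class-relevance accuracy of label-conditioned diffusion samples with
    and without the classifier loss term."""
    cfg = CohortConfig(n_subjects=n_subjects, image_side=image_side,
                       n_slices_range=(4, 5), missing_rates={}, seed=seed)
    cohort = generate_cohort(cfg)
    train_recs = cohort[:3 * n_subjects // 4]
    clf = train_image_classifier(train_recs, "mri",
                                 np.random.default_rng(seed + 60),
                                 n_slices=n_slices, epochs=6)
    imgs, labels = [], []
    for rec in train_recs:
        sm = normalize_slices(SliceStack(rec.mri_brain), n_slices).data
        imgs.extend(sm)
        labels.extend([rec.y] * len(sm))
    clf_np = lambda im: F.softmax(clf(Tensor(im[:, None])), axis=-1).data

    out = {}
    for tag, weight in (("guided", 1.0), ("unguided", 0.0)):
        bundle = DiffusionBundle(DiffusionNet(np.random.default_rng(seed)),
                                 NoiseSchedule(T=T), C=_softmax_handle(clf))
        train_diffusion(bundle, np.stack(imgs), np.array(labels),
                        epochs=epochs, seed=seed, classifier_weight=weight)
        gen = lambda label, n, s: sample_label2image(bundle, label, n, s,
                                                     side=image_side)
        out[tag] = class_relevance_accuracy(gen, clf_np,
                                            n_per_label=n_per_label,
                                            seed=seed + 7)
    return out


# ---------------------------------------------------------------------------
# Skull-stripping ablation
# ---------------------------------------------------------------------------
def skullstrip_ablation_experiment(seed: int, n_subjects: int = 80,
                                   image_side: int = 16, n_slices: int = 4,
                                   epochs: int = 6,
                                   modality: str = "pet") -> Dict[str, float]:
    """Image-classifier balanced accuracy trained on skull-stripped versus
    raw (skull-bearing) volumes; same subjects, same seeds."""
    cfg = CohortConfig(n_subjects=n_subjects, image_side=image_side,
                       n_slices_range=(4, 5), missing_rates={}, seed=seed)
    cohort = generate_cohort(cfg)
    train_recs, test_recs = cohort[:3 * n_subjects // 4], cohort[3 * n_subjects // 4:]
    out = {}
    for tag, use_stripped in (("stripped", True), ("raw", False)):
        model = train_image_classifier(train_recs, modality,
                                       np.random.default_rng(seed + 3),
                                       n_slices=n_slices, epochs=epochs,
                                       use_stripped=use_stripped)
        preds, truths = [], []
        for rec in test_recs:
            vol = (rec.pet_brain if modality == "pet" else rec.mri_brain) \
                if use_stripped else \
                (rec.pet_volume if modality == "pet" else rec.mri_volume)
            stack = normalize_slices(SliceStack(vol), n_slices)
            preds.append(int(np.argmax(classify_subject(model, stack))))
            truths.append(rec.y)
        out[tag] = balanced_accuracy(preds, truths)
    return out


# ---------------------------------------------------------------------------
# Saliency localisation
# ---------------------------------------------------------------------------
def lesion_mask(rec: SubjectRecord) -> np.ndarray:
    """The implanted dark (atrophy-proxy) region: dim pixels inside the brain."""
    brain = rec.mri_brain > 0
    return brain & (rec.mri_brain < 0.32)


def saliency_localization_experiment(seed: int, n_subjects: int = 80,
                                     image_side: int = 16, n_slices: int = 4,
                                     epochs: int = 6) -> Dict[str, float]:
    """Mean full-gradient saliency inside vs outside the implanted atrophy
    region, for AD subjects, on the MRI classifier path."""
    from .graph import FunctionEdge, ModelGraph
    from .interpret import fullgrad_saliency
    from .graph import compose_path
    from .spaces import DataSpace

    cfg = CohortConfig(n_subjects=n_subjects, image_side=image_side,
                       n_slices_range=(4, 5), missing_rates={}, seed=seed)
    cohort = generate_cohort(cfg)
    train_recs, test_recs = cohort[:3 * n_subjects // 4], cohort[3 * n_subjects // 4:]
    clf = train_image_classifier(train_recs, "mri",
                                 np.random.default_rng(seed + 70),
                                 n_slices=n_slices, epochs=epochs)

    vol_space = DataSpace("mri_stripped", "image_volume",
                          (n_slices, image_side, image_side), range=(0.0, 1.0))
    pair_space = DataSpace("label", "probability_pair", (2,))
    g = ModelGraph()
    g.add_node("mri_stripped", vol_space)
    g.add_node("label", pair_space)

    def apply_clf(x):
        n, s, _ = x.shape
        return F.softmax(clf(x.reshape(n, 1, s, s)), axis=-1).mean(axis=0)

    g.add_edge("classify_mri", "mri_stripped", "label",
               FunctionEdge(vol_space, pair_space, apply_clf))
    path = compose_path(g, ["mri_stripped", "label"])

    inside, outside = [], []
    for rec in test_recs:
        if rec.y != 1:
            continue
        stack = normalize_slices(SliceStack(rec.mri_brain), n_slices)
        amap = fullgrad_saliency(path, stack.data, target_class=1)
        smap = amap.values["mri_stripped"]
        mask = normalize_slices(SliceStack(lesion_mask(rec).astype(float)),
                                n_slices).data > 0.5
        brain = normalize_slices(SliceStack((rec.mri_brain > 0).astype(float)),
                                 n_slices).data > 0.5
        out_region = brain & ~mask
        if mask.sum() == 0 or out_region.sum() == 0:
            continue
        inside.append(float(smap[mask].mean()))
        outside.append(float(smap[out_region].mean()))
    return {"saliency_inside_lesion": float(np.mean(inside)),
            "saliency_outside_lesion": float(np.mean(outside)),
            "n_subjects": len(inside)}
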