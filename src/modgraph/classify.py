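"""Diagnosis classifier edges.

Image paths use a miniature residual CNN on individual 2D slices with
subject-level score averaging; feature paths use per-modality MLPs sized to
their feature set. Training is subject-level stratified k-fold with
inverse-frequency class weighting; evaluation reports balanced accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .autodiff import functional as F
from .autodiff import nn
from .autodiff.optim import Adam
from .cohort import MODALITIES, SubjectRecord
from .metrics import balanced_accuracy
from .slices import SliceStack, normalize_slices


class StratificationError(ValueError):
    pass


class ContractError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------
class SliceClassifier(nn.Module):
    """Residual CNN mapping one 2D slice to 2 class logits.

    Desk-scale miniature of an 18-layer residual net: a stem plus four
    residual blocks at widths 8/16/32/64 with pooling between stages.
    Requires spatial side divisible by 8.
    """

    def __init__(self, rng: np.random.Generator, n_slices_expected: int = 8):
        super().__init__()
        self.stem = nn.Conv2d(1, 8, rng)
        self.block1 = nn.ResidualBlock2d(8, 8, rng)
        self.block2 = nn.ResidualBlock2d(8, 16, rng)
        self.block3 = nn.ResidualBlock2d(16, 32, rng)
        self.block4 = nn.ResidualBlock2d(32, 64, rng)
        self.head = nn.Linear(64, 2, rng)
        self.n_slices_expected = n_slices_expected

    def embed(self, x: Tensor) -> Tensor:
        h = self.stem(x).relu()
        h = self.block1(h)
        h = F.avg_pool2d(self.block2(h))
        h = F.avg_pool2d(self.block3(h))
        h = F.avg_pool2d(self.block4(h))
        return F.global_avg_pool(h)  # (B, 64)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.embed(x))

    def probabilities(self, slices: np.ndarray) -> np.ndarray:
        """(N,S,S) -> per-slice probability pairs (N,2)."""
        self.eval()
        logits = self(Tensor(np.asarray(slices, dtype=float)[:, None]))
        return F.softmax(logits, axis=-1).data


class FeatureClassifier(nn.Module):
    """MLP sized to its feature set: two hidden layers of width max(16, 4d)."""

    def __init__(self, n_features: int, rng: np.random.Generator):
        super().__init__()
        width = max(16, 4 * n_features)
        self.fc1 = nn.Linear(n_features, width, rng)
        self.fc2 = nn.Linear(width, width, rng)
        self.fc3 = nn.Linear(width, 2, rng)
        self.n_features = n_features

    def forward(self, x: Tensor) -> Tensor:
        h = self.fc1(x).relu()
        h = self.fc2(h).relu()
        return self.fc3(h)

    def probabilities(self, features: np.ndarray) -> np.ndarray:
        self.eval()
        logits = self(Tensor(np.atleast_2d(np.asarray(features, dtype=float))))
        return F.softmax(logits, axis=-1).data


def classify_subject(model: SliceClassifier, stack: SliceStack) -> np.ndarray:
    """Subject score = arithmetic mean of per-slice probability pairs.

    The stack must already be normalised to the classifier's expected slice
    count; an un-normalised stack is a contract error.
    """
    if stack.n_slices != model.n_slices_expected:
        raise ContractError(
            f"stack has {stack.n_slices} slices but the classifier expects "
            f"{model.n_slices_expected}; run normalize_slices(stack, "
            f"{model.n_slices_expected}) first")
    return model.probabilities(stack.data).mean(axis=0)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------
def _class_weights(labels: np.ndarray) -> np.ndarray:
    counts = np.bincount(labels, minlength=2).astype(float)
    weights = counts.sum() / np.maximum(counts, 1.0) / 2.0
    return weights


def _modality_volume(rec: SubjectRecord, modality: str, use_stripped: bool):
    if modality == "mri":
        return rec.mri_brain if use_stripped else rec.mri_volume
    return rec.pet_brain if use_stripped else rec.pet_volume


def train_image_classifier(records: Sequence[SubjectRecord], modality: str,
                           rng: np.random.Generator, n_slices: int = 8,
                           epochs: int = 3, batch_size: int = 32,
                           lr: float = 1e-3, use_stripped: bool = True
                           ) -> SliceClassifier:
    """Train a slice classifier on all slices of the given subjects.

    Slices inherit their subject's label; the loss is inverse-frequency
    weighted cross-entropy.
    """
    slices, labels = [], []
    for rec in records:
        vol = _modality_volume(rec, modality, use_stripped)
        if vol is None:
            continue
        stack = normalize_slices(SliceStack(vol), n_slices)
        for s in stack.data:
            slices.append(s)
            labels.append(rec.y)
    x = np.stack(slices)
    y = np.array(labels, dtype=int)
    weights = _class_weights(y)

    model = SliceClassifier(rng, n_slices_expected=n_slices)
    opt = Adam(model.parameters(), lr=lr)
    model.train()
    for _ in range(epochs):
        perm = rng.permutation(len(x))
        for start in range(0, len(perm), batch_size):
            idx = perm[start:start + batch_size]
            opt.zero_grad()
            logits = model(Tensor(x[idx][:, None]))
            loss = F.cross_entropy(logits, y[idx], weights=weights)
            loss.backward()
            opt.step()
    model.eval()
    return model


def _feature_vector(rec: SubjectRecord, modality: str) -> Optional[np.ndarray]:
    if modality == "gene":
        return None if rec.apoe4 is None else np.array([float(rec.apoe4)])
    if modality == "cognitive":
        return rec.cognitive
    return getattr(rec, modality)


def train_feature_classifier(records: Sequence[SubjectRecord], modality: str,
                             rng: np.random.Generator, epochs: int = 60,
                             batch_size: int = 32, lr: float = 1e-3
                             ) -> FeatureClassifier:
    xs, ys = [], []
    for rec in records:
        vec = _feature_vector(rec, modality)
        if vec is not None:
            xs.append(vec)
            ys.append(rec.y)
    x = np.stack(xs)
    y = np.array(ys, dtype=int)
    weights = _class_weights(y)
    model = FeatureClassifier(x.shape[1], rng)
    opt = Adam(model.parameters(), lr=lr)
    model.train()
    for _ in range(epochs):
        perm = rng.permutation(len(x))
        for start in range(0, len(perm), batch_size):
            idx = perm[start:start + batch_size]
            opt.zero_grad()
            loss = F.cross_entropy(model(Tensor(x[idx])), y[idx], weights=weights)
            loss.backward()
            opt.step()
    model.eval()
    return model


def subject_score(model, rec: SubjectRecord, modality: str, n_slices: int = 8,
                  use_stripped: bool = True) -> Optional[np.ndarray]:
    """Probability pair for one subject, or None if the modality is absent."""
    if modality in ("mri", "pet"):
        vol = _modality_volume(rec, modality, use_stripped)
        if vol is None:
            return None
        stack = normalize_slices(SliceStack(vol), n_slices)
        return classify_subject(model, stack)
    vec = _feature_vector(rec, modality)
    if vec is None:
        return None
    return model.probabilities(vec)[0]


@dataclass
class CrossValResult:
    modality: str
    fold_bacs: List[float]
    models: List[object]
    scores: pd.DataFrame  # columns: subject, fold, p_cn, p_ad, label

    @property
    def mean_bac(self) -> float:
        return float(np.mean(self.fold_bacs))

    @property
    def stderr_bac(self) -> float:
        return float(np.std(self.fold_bacs, ddof=1) / np.sqrt(len(self.fold_bacs)))


def train_classifier(cohort: Sequence[SubjectRecord], modality: str,
                     epochs: int = 3, folds: int = 5, seed: int = 0,
                     n_slices: int = 8, use_stripped: bool = True,
                     feature_epochs: int = 60) -> CrossValResult:
    """Subject-level stratified k-fold cross-validation for one modality.

    All slices of a subject stay in one fold; returns per-fold balanced
    accuracies and out-of-fold subject scores.
    """
    from sklearn.model_selection import StratifiedKFold

    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    usable = [r for r in cohort if r.available.get(modality, False)]
    y = np.array([r.y for r in usable])
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise StratificationError(
            f"modality {modality!r}: a class would be absent from some fold "
            f"(class counts {counts.tolist()}, folds={folds})")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_bacs, models, rows = [], [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        rng = np.random.default_rng(seed * 1000 + fold)
        train_recs = [usable[i] for i in train_idx]
        test_recs = [usable[i] for i in test_idx]
        if modality in ("mri", "pet"):
            model = train_image_classifier(train_recs, modality, rng,
                                           n_slices=n_slices, epochs=epochs,
                                           use_stripped=use_stripped)
        else:
            model = train_feature_classifier(train_recs, modality, rng,
                                             epochs=feature_epochs)
        preds, truths = [], []
        for rec in test_recs:
            score = subject_score(model, rec, modality, n_slices=n_slices,
                                  use_stripped=use_stripped)
            preds.append(int(np.argmax(score)))
            truths.append(rec.y)
            rows.append({"subject": rec.id, "fold": fold, "modality": modality,
                         "p_cn": score[0], "p_ad": score[1], "label": rec.label})
        fold_bacs.append(balanced_accuracy(preds, truths))
        models.append(model)
    return CrossValResult(modality=modality, fold_bacs=fold_bacs, models=models,
                          scores=pd.DataFrame(rows))
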