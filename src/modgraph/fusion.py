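"""Late fusion of the seven modality classifiers.

Two aggregators over the 7x2 block of AD/CN probability pairs: a
majority-vote ensemble (each available modality casts its argmax label) and
a fusion MLP (14 inputs, layers 256/128/64/2, dropout 0.5 after the second
and third layers) trained with 0-5 modality groups randomly masked at every
step so it stays accurate when modalities go missing. Masked groups are
filled with (0, 0) — distinguishable from any valid probability pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .autodiff import functional as F
from .autodiff import nn
from .autodiff.optim import Adam
from .cohort import MODALITIES
from .metrics import balanced_accuracy

MASK_FILL = 0.0
N_GROUPS = len(MODALITIES)  # 7


class ProtocolError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ScoreVector
# ---------------------------------------------------------------------------
@dataclass
class ScoreVector:
    """7 ordered modality probability pairs plus availability flags."""

    scores: np.ndarray  # (7, 2)
    available: np.ndarray  # (7,) bool
    label: Optional[str] = None
    subject: Optional[str] = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float).reshape(N_GROUPS, 2)
        self.available = np.asarray(self.available, dtype=bool).reshape(N_GROUPS)
        for g in range(N_GROUPS):
            if self.available[g]:
                pair = self.scores[g]
                if not (pair.min() >= -1e-6 and abs(pair.sum() - 1.0) < 1e-6):
                    raise ValueError(
                        f"group {MODALITIES[g]}: available pair {pair} is not a "
                        "probability pair")
            else:
                self.scores[g] = MASK_FILL

    def flat(self) -> np.ndarray:
        """Length-14 input to the fusion MLP (mask fill already applied)."""
        return self.scores.reshape(-1).copy()

    def to_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {}
        if self.subject is not None:
            row["subject"] = self.subject
        if self.label is not None:
            row["label"] = self.label
        for g, m in enumerate(MODALITIES):
            row[f"p_cn_{m}"] = self.scores[g, 0]
            row[f"p_ad_{m}"] = self.scores[g, 1]
            row[f"avail_{m}"] = int(self.available[g])
        return row

    @classmethod
    def from_row(cls, row) -> "ScoreVector":
        scores = np.array([[row[f"p_cn_{m}"], row[f"p_ad_{m}"]] for m in MODALITIES])
        avail = np.array([bool(row[f"avail_{m}"]) for m in MODALITIES])
        return cls(scores=scores, available=avail,
                   label=row.get("label") if hasattr(row, "get") else row["label"],
                   subject=row.get("subject") if hasattr(row, "get") else row["subject"])


def scores_to_frame(vectors: Sequence[ScoreVector]) -> pd.DataFrame:
    return pd.DataFrame([v.to_row() for v in vectors])


def frame_to_scores(frame: pd.DataFrame) -> List[ScoreVector]:
    return [ScoreVector.from_row(row) for _, row in frame.iterrows()]


# ---------------------------------------------------------------------------
# Majority vote
# ---------------------------------------------------------------------------
def majority_vote(sv: ScoreVector, tie_break: str = "conservative") -> str:
    """Plurality over available modalities' argmax votes.

    tie_break:
      "conservative" (default) — an even split returns CN (no majority, no
      disease call), keeping the ensemble a literal hard-label vote;
      "mean_probability" — ties go to the label favoured by the mean
      AD-probability across available modalities, residual exact ties to CN.
    The conservative rule is the baseline used in the missing-modality
    protocols: breaking ties with mean probabilities turns the two-voter
    case into soft score averaging, which is no longer majority voting.
    """
    idx = np.where(sv.available)[0]
    if idx.size == 0:
        raise ValueError("majority_vote needs at least one available modality")
    votes = np.argmax(sv.scores[idx], axis=1)  # 1 = AD
    n_ad = int(votes.sum())
    n_cn = votes.size - n_ad
    if n_ad != n_cn:
        return "AD" if n_ad > n_cn else "CN"
    if tie_break == "mean_probability":
        return "AD" if float(sv.scores[idx, 1].mean()) > 0.5 else "CN"
    if tie_break == "conservative":
        return "CN"
    raise ValueError(f"unknown tie_break {tie_break!r}")


def mask_scores(sv: ScoreVector, to_mask: Sequence[str]) -> ScoreVector:
    """Return a copy with the named groups unavailable and fill-valued."""
    unknown = set(to_mask) - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown modality groups: {sorted(unknown)}")
    avail = sv.available.copy()
    scores = sv.scores.copy()
    for m in to_mask:
        g = MODALITIES.index(m)
        avail[g] = False
        scores[g] = MASK_FILL
    return ScoreVector(scores=scores, available=avail, label=sv.label,
                       subject=sv.subject)


# ---------------------------------------------------------------------------
# Fusion MLP
# ---------------------------------------------------------------------------
class FusionMLP(nn.Module):
    """14 -> 256 -> 128 -> 64 -> 2 with dropout 0.5 after layers 2 and 3."""

    def __init__(self, rng: np.random.Generator, dropout: float = 0.5):
        super().__init__()
        self.fc1 = nn.Linear(14, 256, rng)
        self.fc2 = nn.Linear(256, 128, rng)
        self.drop2 = nn.Dropout(dropout, rng)
        self.fc3 = nn.Linear(128, 64, rng)
        self.drop3 = nn.Dropout(dropout, rng)
        self.fc4 = nn.Linear(64, 2, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.fc1(x).relu()
        h = self.drop2(self.fc2(h).relu())
        h = self.drop3(self.fc3(h).relu())
        return self.fc4(h)

    def predict_proba(self, flat: np.ndarray) -> np.ndarray:
        self.eval()
        logits = self(Tensor(np.atleast_2d(np.asarray(flat, dtype=float))))
        return F.softmax(logits, axis=-1).data

    def predict_label(self, sv: ScoreVector) -> str:
        p = self.predict_proba(sv.flat())[0]
        return "AD" if int(np.argmax(p)) == 1 else "CN"


@dataclass
class MissingProtocol:
    """random_k (k groups masked per subject, re-drawn every repetition),
    single (one named group removed), or subset (several removed)."""

    mode: str
    k: Optional[int] = None
    features: Tuple[str, ...] = ()
    repetitions: int = 100

    def __post_init__(self):
        if self.mode not in ("random_k", "single", "subset"):
            raise ProtocolError(f"unknown protocol mode {self.mode!r}")
        if self.mode == "random_k":
            if self.k is None or not 0 <= self.k <= 5:
                raise ProtocolError("random_k requires 0 <= k <= 5")
        else:
            unknown = set(self.features) - set(MODALITIES)
            if unknown:
                raise ProtocolError(f"unknown feature groups: {sorted(unknown)}")
            if self.mode == "single" and len(self.features) != 1:
                raise ProtocolError("single-removal requires exactly one feature")
            if len(self.features) >= N_GROUPS:
                raise ProtocolError("cannot remove all 7 groups")


def _random_masks(n_subjects: int, k: int, rng: np.random.Generator) -> List[List[str]]:
    masks = []
    for _ in range(n_subjects):
        chosen = rng.choice(N_GROUPS, size=k, replace=False) if k else []
        masks.append([MODALITIES[int(g)] for g in chosen])
    return masks


def train_fusion(mlp: FusionMLP, score_frame: pd.DataFrame,
                 mask_range: Tuple[int, int] = (0, 5), epochs: int = 200,
                 seed: int = 0, lr: float = 1e-3, batch_size: int = 32,
                 val_fraction: float = 0.2, weight_decay: float = 0.0) -> Dict:
    """Train the fusion MLP with k ~ uniform{mask_range} groups masked per
    sample at every step (a fresh uniformly chosen k-subset each time)."""
    lo, hi = mask_range
    if not (0 <= lo <= hi):
        raise ValueError("invalid mask_range")
    if hi > 6:
        raise ValueError("mask_range max must leave at least one modality (<= 6)")
    vectors = frame_to_scores(score_frame)
    x = np.stack([v.flat() for v in vectors])
    y = np.array([1 if v.label == "AD" else 0 for v in vectors], dtype=int)
    # inverse-frequency class weights keep the minority (AD) class from
    # being sacrificed when heavy masking makes inputs uninformative
    counts = np.bincount(y, minlength=2).astype(float)
    class_w = counts.sum() / np.maximum(counts, 1.0) / 2.0

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x))
    n_val = max(1, int(len(x) * val_fraction))
    val_idx, train_idx = order[:n_val], order[n_val:]

    def val_loss() -> float:
        mlp.eval()
        loss = F.cross_entropy(mlp(Tensor(x[val_idx])), y[val_idx],
                               weights=class_w)
        return float(loss.data)

    loss_before = val_loss()
    opt = Adam(list(mlp.parameters()), lr=lr, weight_decay=weight_decay)
    losses = []
    for _ in range(epochs):
        mlp.train()
        perm = rng.permutation(train_idx)
        total = 0.0
        for start in range(0, len(perm), batch_size):
            idx = perm[start:start + batch_size]
            xb = x[idx].copy()
            for row_pos in range(len(idx)):
                k = int(rng.integers(lo, hi + 1))
                if k:
                    groups = rng.choice(N_GROUPS, size=k, replace=False)
                    for g in groups:
                        xb[row_pos, 2 * g:2 * g + 2] = MASK_FILL
            opt.zero_grad()
            loss = F.cross_entropy(mlp(Tensor(xb)), y[idx], weights=class_w)
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        losses.append(total / len(perm))
    mlp.eval()
    return {"losses": losses, "val_loss_untrained": loss_before,
            "val_loss_trained": val_loss()}


PredictorSpec = Union[FusionMLP, str]


def _predict(predictor: PredictorSpec, sv: ScoreVector) -> str:
    if isinstance(predictor, FusionMLP):
        return predictor.predict_label(sv)
    if predictor == "vote":
        return majority_vote(sv)
    raise ValueError(f"unknown predictor {predictor!r}")


def evaluate_missing(predictor: PredictorSpec, score_frame: pd.DataFrame,
                     protocol: MissingProtocol, seed: int = 0
                     ) -> Tuple[float, float]:
    """Balanced-accuracy mean ± s.e. under a missing-modality protocol.

    random_k: per repetition, an independent k-subset is masked per subject;
    single/subset: deterministic removal of the named group(s).
    """
    vectors = frame_to_scores(score_frame)
    truth = [v.label for v in vectors]

    def bac_with(masks: Sequence[Sequence[str]]) -> float:
        preds = [_predict(predictor, mask_scores(v, m))
                 for v, m in zip(vectors, masks)]
        return balanced_accuracy([p == "AD" for p in preds],
                                 [t == "AD" for t in truth])

    if protocol.mode == "random_k":
        rng = np.random.default_rng(seed)
        bacs = [bac_with(_random_masks(len(vectors), protocol.k, rng))
                for _ in range(protocol.repetitions)]
        mean = float(np.mean(bacs))
        se = float(np.std(bacs, ddof=1) / np.sqrt(len(bacs))) if len(bacs) > 1 else 0.0
        return mean, se
    masks = [list(protocol.features)] * len(vectors)
    return bac_with(masks), 0.0


def substitute_synthetic_pet(score_frame: pd.DataFrame, cohort, translator,
                             pet_classifier, fusion_mlp: FusionMLP,
                             n_slices: int = 8, seed: int = 0) -> Dict[str, float]:
    """Substitution experiment: treat every test subject's PET as missing,
    regenerate it from MRI through the translation edge, score it with the
    PET classifier, and fuse.

    Returns BAC with real PET scores, with PET masked, and with synthetic-PET
    scores substituted for the mask fill. Subjects lacking MRI are skipped.
    """
    import logging

    from .classify import classify_subject
    from .slices import SliceStack, normalize_slices

    logger = logging.getLogger(__name__)
    by_id = {rec.id: rec for rec in cohort}
    vectors = frame_to_scores(score_frame)
    rng = np.random.default_rng(seed)

    kept, preds_real, preds_masked, preds_synth = [], [], [], []
    for v in vectors:
        rec = by_id.get(v.subject)
        if rec is None or rec.mri_brain is None:
            logger.info("substitute_synthetic_pet: subject %s lacks MRI, skipped",
                        v.subject)
            continue
        stack = normalize_slices(SliceStack(rec.mri_brain), n_slices)
        z = rng.standard_normal((stack.n_slices, translator.z_dim))
        synth = translator(Tensor(stack.data[:, None]), Tensor(z)).data[:, 0]
        pair = classify_subject(pet_classifier, SliceStack(synth))

        masked = mask_scores(v, ["pet"])
        scores_syn = masked.scores.copy()
        avail_syn = masked.available.copy()
        g = MODALITIES.index("pet")
        scores_syn[g] = pair
        avail_syn[g] = True
        synth_sv = ScoreVector(scores=scores_syn, available=avail_syn,
                               label=v.label, subject=v.subject)
        kept.append(v.label == "AD")
        preds_real.append(fusion_mlp.predict_label(v) == "AD")
        preds_masked.append(fusion_mlp.predict_label(masked) == "AD")
        preds_synth.append(fusion_mlp.predict_label(synth_sv) == "AD")

    return {
        "bac_real_pet": balanced_accuracy(preds_real, kept),
        "bac_masked_pet": balanced_accuracy(preds_masked, kept),
        "bac_synthetic_pet": balanced_accuracy(preds_synth, kept),
        "n_subjects": len(kept),
    }
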