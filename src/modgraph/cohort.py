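"""Synthetic multimodal AD/CN cohort generator.

Emulates the statistical structure the framework's experiments need, with no
claim to MRI physics: each subject gets a stack of 2D "coronal" slices with
a bright removable skull annulus and an elliptical brain interior; disease
severity (a shared latent, shifted for AD subjects) enlarges a dark interior
region — an atrophy proxy — expressed in MRI and, through a tunable
cross-modality correlation, in PET; ROI metrics (volume/thickness/surface),
an APOE4 carrier flag and eight cognitive scores carry class-conditional
signal of decreasing/greater strength; modalities go missing completely at
random at per-modality rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

COGNITIVE_NAMES = ("CDRSB", "ADAS11", "ADAS13", "ADASQ4", "MMSE",
                   "RAVLT_immediate", "RAVLT_learning", "RAVLT_forgetting")
# direction of the AD shift for each cognitive score (impairment raises
# CDRSB/ADAS/forgetting, lowers MMSE/RAVLT recall)
COGNITIVE_SIGNS = np.array([+1, +1, +1, +1, -1, -1, -1, +1], dtype=float)

MODALITIES = ("mri", "pet", "roi_volume", "roi_thickness", "roi_surface",
              "gene", "cognitive")


class InsufficientCohortError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Desk-scale defaults; every size is configurable up to realistic scales."""

    n_subjects: int = 200
    ad_fraction: float = 0.35
    image_side: int = 32
    n_slices_range: Tuple[int, int] = (5, 12)
    skull_thickness: int = 2
    atrophy_effect: float = 2.0
    mri_pet_correlation: float = 0.7
    n_roi: int = 8
    roi_effects: Dict[str, float] = field(default_factory=lambda: {
        "volume": 0.62, "thickness": 0.45, "surface": 0.32})
    gene_ad_prob: float = 0.40
    gene_cn_prob: float = 0.30
    cognitive_effect: float = 1.2
    missing_rates: Dict[str, float] = field(default_factory=lambda: {
        "mri": 0.0, "pet": 0.2, "roi_volume": 0.05, "roi_thickness": 0.05,
        "roi_surface": 0.05, "gene": 0.1, "cognitive": 0.1})
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.ad_fraction < 1.0:
            raise ValueError("ad_fraction must be in (0, 1)")
        n_ad = int(round(self.n_subjects * self.ad_fraction))
        if n_ad < 2 or self.n_subjects - n_ad < 2:
            raise InsufficientCohortError(
                f"need at least 2 subjects per class; got {n_ad} AD / "
                f"{self.n_subjects - n_ad} CN")
        lo, hi = self.n_slices_range
        if not (2 <= lo <= hi <= 512):
            raise ValueError("n_slices_range must lie within [2, 512]")
        for k, v in self.missing_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missing rate for {k} outside [0, 1]")
        if not 0.0 <= self.mri_pet_correlation <= 1.0:
            raise ValueError("mri_pet_correlation must be in [0, 1]")
        for eff in (self.atrophy_effect, self.cognitive_effect,
                    *self.roi_effects.values()):
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")


@dataclass
class SubjectRecord:
    """One synthetic subject; unavailable modalities hold None, never zeros."""

    id: str
    label: str  # "AD" or "CN"
    mri_volume: Optional[np.ndarray]
    mri_brain: Optional[np.ndarray]
    mri_skull_mask: Optional[np.ndarray]
    pet_volume: Optional[np.ndarray]
    pet_brain: Optional[np.ndarray]
    pet_skull_mask: Optional[np.ndarray]
    roi_volume: Optional[np.ndarray]
    roi_thickness: Optional[np.ndarray]
    roi_surface: Optional[np.ndarray]
    apoe4: Optional[int]
    cognitive: Optional[np.ndarray]
    available: Dict[str, bool] = field(default_factory=dict)

    @property
    def y(self) -> int:
        return 1 if self.label == "AD" else 0


def _volume(side: int, n_slices: int, skull_thickness: int, severity: float,
            base_shift: float, rng: np.random.Generator
            ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (raw, brain, skull_mask) stacks for one subject/modality.

    severity drives the dark interior region's radius (atrophy proxy);
    base_shift shifts the interior base intensity (shared texture latent).
    """
    yy, xx = np.mgrid[0:side, 0:side]
    cy = cx = (side - 1) / 2.0
    raw = np.empty((n_slices, side, side))
    brain = np.empty_like(raw)
    skull = np.zeros_like(raw, dtype=bool)
    # outer semi-axes of the head ellipse, modulated along the stack so the
    # middle slices cut through more tissue
    for s in range(n_slices):
        frac = s / max(n_slices - 1, 1)
        scale = 0.75 + 0.25 * np.sin(np.pi * frac)
        a_out = 0.44 * side * scale
        b_out = 0.38 * side * scale
        a_in = a_out - skull_thickness
        b_in = b_out - skull_thickness
        r_out = ((yy - cy) / b_out) ** 2 + ((xx - cx) / a_out) ** 2
        r_in = ((yy - cy) / max(b_in, 1.0)) ** 2 + ((xx - cx) / max(a_in, 1.0)) ** 2
        skull_ring = (r_out <= 1.0) & (r_in > 1.0)
        interior = r_in <= 1.0

        img = rng.normal(0.04, 0.015, (side, side))
        base = 0.50 + 0.06 * base_shift
        img[interior] = base + rng.normal(0.0, 0.05, int(interior.sum()))
        # atrophy proxy: dark region grows with severity
        radius = np.clip(0.10 * side + 0.035 * side * severity, 1.0, 0.30 * side)
        dark = ((yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2) & interior
        img[dark] = 0.18 + rng.normal(0.0, 0.03, int(dark.sum()))
        img[skull_ring] = 0.88 + rng.normal(0.0, 0.03, int(skull_ring.sum()))
        img = np.clip(img, 0.0, 1.0)

        stripped = np.where(interior, img, 0.0)
        raw[s] = img
        brain[s] = stripped
        skull[s] = skull_ring
    return raw, brain, skull


def generate_cohort(config: CohortConfig) -> List[SubjectRecord]:
    """Deterministically generate a cohort from the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_ad = int(round(n * config.ad_fraction))
    labels = np.array(["AD"] * n_ad + ["CN"] * (n - n_ad))
    rng.shuffle(labels)

    rho = config.mri_pet_correlation
    records: List[SubjectRecord] = []
    for i in range(n):
        label = str(labels[i])
        is_ad = 1.0 if label == "AD" else 0.0
        # shared disease-severity latent, expressed in MRI directly and in
        # PET through the cross-modality correlation
        mu = config.atrophy_effect * is_ad
        u_mri = rng.normal(mu, 1.0)
        # same class mean and unit variance, correlation rho with the MRI latent
        u_pet = mu + rho * (u_mri - mu) + \
            np.sqrt(max(1.0 - rho ** 2, 0.0)) * rng.normal(0.0, 1.0)
        texture = rng.normal(0.0, 1.0)

        n_slices = int(rng.integers(config.n_slices_range[0],
                                    config.n_slices_range[1] + 1))
        mri_raw, mri_brain, mri_skull = _volume(
            config.image_side, n_slices, config.skull_thickness,
            u_mri, texture, rng)
        pet_raw, pet_brain, pet_skull = _volume(
            config.image_side, n_slices, config.skull_thickness,
            u_pet, rho * texture + np.sqrt(max(1 - rho ** 2, 0)) * rng.normal(), rng)

        roi = {}
        for name, eff in config.roi_effects.items():
            # AD shrinks cortical metrics: negative shift
            roi[name] = rng.normal(-eff * is_ad, 1.0, config.n_roi)
        gene = int(rng.random() < (config.gene_ad_prob if is_ad
                                   else config.gene_cn_prob))
        cog = rng.normal(COGNITIVE_SIGNS * config.cognitive_effect * is_ad,
                         1.0, len(COGNITIVE_NAMES))

        available = {m: bool(rng.random() >= config.missing_rates.get(m, 0.0))
                     for m in MODALITIES}
        rec = SubjectRecord(
            id=f"subj{i:04d}", label=label,
            mri_volume=mri_raw if available["mri"] else None,
            mri_brain=mri_brain if available["mri"] else None,
            mri_skull_mask=mri_skull if available["mri"] else None,
            pet_volume=pet_raw if available["pet"] else None,
            pet_brain=pet_brain if available["pet"] else None,
            pet_skull_mask=pet_skull if available["pet"] else None,
            roi_volume=roi["volume"] if available["roi_volume"] else None,
            roi_thickness=roi["thickness"] if available["roi_thickness"] else None,
            roi_surface=roi["surface"] if available["roi_surface"] else None,
            apoe4=gene if available["gene"] else None,
            cognitive=cog if available["cognitive"] else None,
            available=available,
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Separability report (linear probes)
# ---------------------------------------------------------------------------
def _probe_features(cohort: List[SubjectRecord], modality: str
                    ) -> Tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for rec in cohort:
        if not rec.available.get(modality, False):
            continue
        if modality in ("mri", "pet"):
            vol = rec.mri_volume if modality == "mri" else rec.pet_volume
            m = vol.mean(axis=0)
            # 2x2 block averaging keeps the probe's dimensionality modest
            h, w = m.shape[0] // 2 * 2, m.shape[1] // 2 * 2
            x = m[:h, :w].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3)).ravel()
        elif modality == "gene":
            x = np.array([float(rec.apoe4)])
        elif modality == "cognitive":
            x = rec.cognitive
        else:
            x = getattr(rec, modality)
        xs.append(np.asarray(x, dtype=float))
        ys.append(rec.y)
    return np.array(xs), np.array(ys)


def cohort_separability_report(cohort: List[SubjectRecord],
                               cv: int = 5, seed: int = 0) -> Dict[str, float]:
    """Per-modality linear-probe balanced accuracies (stratified CV).

    Modalities missing everywhere are excluded with a warning.
    """
    import warnings

    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    from .metrics import balanced_accuracy

    per_class = min(sum(r.y for r in cohort), sum(1 - r.y for r in cohort))
    if per_class < 20:
        raise InsufficientCohortError("separability report needs >= 20 subjects per class")

    report: Dict[str, float] = {}
    for modality in MODALITIES:
        x, y = _probe_features(cohort, modality)
        if len(x) == 0:
            warnings.warn(f"modality {modality!r} missing everywhere; excluded from report")
            continue
        if np.unique(y).size < 2 or np.all(x.std(axis=0) == 0):
            report[modality] = 0.5
            continue
        probe = LogisticRegression(max_iter=2000, class_weight="balanced",
                                   C=1.0 if modality in ("mri", "pet") else 0.5)
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        pred = cross_val_predict(probe, x, y, cv=skf)
        report[modality] = balanced_accuracy(pred, y)
    return report


# ---------------------------------------------------------------------------
# Export / import (NIfTI volumes + cohort CSV)
# ---------------------------------------------------------------------------
_VOLUME_FIELDS = ("mri_volume", "mri_brain", "mri_skull_mask",
                  "pet_volume", "pet_brain", "pet_skull_mask")


def export_cohort(cohort: List[SubjectRecord], directory) -> Path:
    """Write one NIfTI per volume per subject plus a cohort-level CSV."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        row: Dict[str, object] = {"id": rec.id, "label": rec.label}
        for m in MODALITIES:
            row[f"avail_{m}"] = int(rec.available.get(m, False))
        for fieldname in _VOLUME_FIELDS:
            vol = getattr(rec, fieldname)
            if vol is not None:
                img = nib.Nifti1Image(np.asarray(vol, dtype=np.float64), np.eye(4))
                nib.save(img, directory / f"{rec.id}_{fieldname}.nii.gz")
        if rec.roi_volume is not None:
            for j, v in enumerate(rec.roi_volume):
                row[f"roi_volume_{j}"] = v
        if rec.roi_thickness is not None:
            for j, v in enumerate(rec.roi_thickness):
                row[f"roi_thickness_{j}"] = v
        if rec.roi_surface is not None:
            for j, v in enumerate(rec.roi_surface):
                row[f"roi_surface_{j}"] = v
        if rec.apoe4 is not None:
            row["apoe4"] = rec.apoe4
        if rec.cognitive is not None:
            for name, v in zip(COGNITIVE_NAMES, rec.cognitive):
                row[f"cog_{name}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "cohort.csv", index=False,
                              float_format="%.17g")
    return directory


def import_cohort(directory) -> List[SubjectRecord]:
    """Reload a cohort written by :func:`export_cohort` (lossless)."""
    import nibabel as nib

    directory = Path(directory)
    table = pd.read_csv(directory / "cohort.csv", float_precision="round_trip")
    records: List[SubjectRecord] = []
    for _, row in table.iterrows():
        available = {m: bool(row[f"avail_{m}"]) for m in MODALITIES}
        vols: Dict[str, Optional[np.ndarray]] = {}
        for fieldname in _VOLUME_FIELDS:
            path = directory / f"{row['id']}_{fieldname}.nii.gz"
            if path.exists():
                data = np.asarray(nib.load(path).dataobj, dtype=np.float64)
                vols[fieldname] = data.astype(bool) if "mask" in fieldname else data
            else:
                vols[fieldname] = None

        def _vec(prefix: str, names=None):
            if names is None:
                cols = sorted([c for c in table.columns if c.startswith(prefix)],
                              key=lambda c: int(c.rsplit("_", 1)[1]))
            else:
                cols = [f"{prefix}{n}" for n in names]
            if not cols or pd.isna(row[cols[0]]):
                return None
            return np.array([row[c] for c in cols], dtype=float)

        records.append(SubjectRecord(
            id=str(row["id"]), label=str(row["label"]),
            mri_volume=vols["mri_volume"], mri_brain=vols["mri_brain"],
            mri_skull_mask=vols["mri_skull_mask"],
            pet_volume=vols["pet_volume"], pet_brain=vols["pet_brain"],
            pet_skull_mask=vols["pet_skull_mask"],
            roi_volume=_vec("roi_volume_"), roi_thickness=_vec("roi_thickness_"),
            roi_surface=_vec("roi_surface_"),
            apoe4=None if "apoe4" not in row or pd.isna(row.get("apoe4")) else int(row["apoe4"]),
            cognitive=_vec("cog_", COGNITIVE_NAMES),
            available=available,
        ))
    return records
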