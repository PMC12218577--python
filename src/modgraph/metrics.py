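"""Evaluation metrics: balanced accuracy, mask IoU, Fréchet distance."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    pass


def balanced_accuracy(predictions: Sequence[int], truth: Sequence[int]) -> float:
    """Mean of sensitivity and specificity; both classes must be present in truth."""
    pred = np.asarray(predictions, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.shape != true.shape:
        raise MetricError("predictions and truth differ in length")
    classes = np.unique(true)
    if classes.size < 2:
        raise MetricError("balanced accuracy undefined: only one class present in truth")
    recalls = [float(np.mean(pred[true == c] == c)) for c in classes]
    return float(np.mean(recalls))


def mask_iou(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Intersection-over-union of two binary masks.

    Defined as 1.0 when both masks are empty (empty union).
    """
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(truth_mask, dtype=bool)
    if a.shape != b.shape:
        raise MetricError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def threshold_mask(image: np.ndarray, threshold: float) -> np.ndarray:
    """Binarise a regression output: pixels above `threshold` are foreground."""
    return np.asarray(image) > threshold


def frechet_distance(embeddings_a: np.ndarray, embeddings_b: np.ndarray,
                     ridge: float = 1e-6) -> float:
    """Fréchet distance between Gaussian fits of two embedding sets.

    d² = ||μ_A − μ_B||² + tr(Σ_A + Σ_B − 2 (Σ_A Σ_B)^{1/2})
    with a symmetrised matrix square root. Requires at least dim+1 vectors
    per set; near-singular covariances get a logged ridge.
    """
    a = np.atleast_2d(np.asarray(embeddings_a, dtype=float))
    b = np.atleast_2d(np.asarray(embeddings_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise MetricError("embedding dimensionalities differ")
    dim = a.shape[1]
    if a.shape[0] < dim + 1 or b.shape[0] < dim + 1:
        raise MetricError(f"need at least dim+1={dim + 1} vectors per set")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    cov_a = np.cov(a, rowvar=False)
    cov_b = np.cov(b, rowvar=False)
    cov_a = np.atleast_2d(cov_a)
    cov_b = np.atleast_2d(cov_b)

    sqrt_prod = np.atleast_2d(scipy.linalg.sqrtm(cov_a @ cov_b))
    bad = not np.isfinite(sqrt_prod).all() or (
        np.iscomplexobj(sqrt_prod) and np.abs(sqrt_prod.imag).max() > 1e-6)
    if bad:
        logger.info("frechet_distance: adding ridge %.1e to near-singular covariances", ridge)
        eye = np.eye(dim)
        sqrt_prod = np.atleast_2d(
            scipy.linalg.sqrtm((cov_a + ridge * eye) @ (cov_b + ridge * eye)))
    sqrt_prod = np.real(sqrt_prod)
    # symmetrise to wash out numerical asymmetry of sqrtm
    sqrt_prod = (sqrt_prod + sqrt_prod.T) / 2.0
    d2 = float(np.sum((mu_a - mu_b) ** 2) + np.trace(cov_a + cov_b - 2.0 * sqrt_prod))
    return max(d2, 0.0)
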