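"""Cohort scoring: run every diagnosis path under subject-level
cross-validation and assemble the per-subject 7x2 score table that feeds
the fusion layer."""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import CrossValResult, train_classifier
from .cohort import MODALITIES, SubjectRecord
from .fusion import MASK_FILL


def score_table(cohort: Sequence[SubjectRecord], folds: int = 3, seed: int = 0,
                n_slices: int = 8, image_epochs: int = 2,
                feature_epochs: int = 60, use_stripped: bool = True
                ) -> Tuple[pd.DataFrame, Dict[str, CrossValResult]]:
    """Out-of-fold probability pairs for all seven modalities.

    Every subject gets one row: label, the 14 score columns (mask fill when
    the modality is unavailable) and the 7 availability flags.
    """
    results: Dict[str, CrossValResult] = {}
    for modality in MODALITIES:
        results[modality] = train_classifier(
            cohort, modality, epochs=image_epochs, folds=folds, seed=seed,
            n_slices=n_slices, use_stripped=use_stripped,
            feature_epochs=feature_epochs)

    lookup: Dict[str, Dict[str, Tuple[float, float]]] = {m: {} for m in MODALITIES}
    for modality, res in results.items():
        for _, row in res.scores.iterrows():
            lookup[modality][row["subject"]] = (row["p_cn"], row["p_ad"])

    rows = []
    for rec in cohort:
        row: Dict[str, object] = {"subject": rec.id, "label": rec.label}
        for m in MODALITIES:
            pair = lookup[m].get(rec.id)
            if pair is None:
                row[f"p_cn_{m}"], row[f"p_ad_{m}"] = MASK_FILL, MASK_FILL
                row[f"avail_{m}"] = 0
            else:
                row[f"p_cn_{m}"], row[f"p_ad_{m}"] = pair
                row[f"avail_{m}"] = 1
        rows.append(row)
    return pd.DataFrame(rows), results
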