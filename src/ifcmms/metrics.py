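"""Binary segmentation evaluation: confusion counts and the four indices.

Evaluation is tumor-vs-rest: multi-cluster label maps are binarized by a
selected tumor cluster (by default the cluster with the brightest gray
center, matching the bright appearance of tumors in FLAIR-like images).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("ifcmms")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts; positive = tumor."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def indices(cc: ConfusionCounts) -> dict[str, float]:
    """accuracy, precision, recall, specificity from confusion counts.

    An index with a zero denominator is reported as NaN (undefined,
    deliberately distinct from 0) and logged.
    """
    out: dict[str, float] = {}

    def ratio(name: str, num: int, den: int) -> float:
        if den == 0:
            logger.warning("index %s undefined (zero denominator)", name)
            return math.nan
        return num / den

    out["accuracy"] = ratio("accuracy", cc.tp + cc.tn, cc.total)
    out["precision"] = ratio("precision", cc.tp, cc.tp + cc.fp)
    out["recall"] = ratio("recall", cc.tp, cc.tp + cc.fn)
    out["specificity"] = ratio("specificity", cc.tn, cc.tn + cc.fp)
    return out


def tumor_mask(labels: np.ndarray, gray_centers, tumor_cluster: int | None = None) -> np.ndarray:
    """Binarize a label map on the tumor cluster.

    ``tumor_cluster=None`` selects the cluster with the brightest gray
    center, the natural choice when tumors are the brightest tissue.
    """
    if tumor_cluster is None:
        tumor_cluster = int(np.argmax(np.asarray(gray_centers, dtype=float)))
    return np.asarray(labels) == tumor_cluster


def evaluate_binary(
    labels: np.ndarray,
    gray_centers,
    truth: np.ndarray,
    tumor_cluster: int | None = None,
) -> dict[str, float]:
    """Confusion indices of a label map against a binary ground-truth mask."""
    pred = tumor_mask(labels, gray_centers, tumor_cluster)
    return indices(confusion(pred, np.asarray(truth, dtype=bool)))
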