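"""Segmentation evaluation: confusion counts, accuracy, Jaccard, Dice.

Conventions for degenerate inputs: two empty masks are identical, so
Jaccard and Dice are defined as 1.0; empty versus non-empty gives 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "SegMetrics",
    "confusion_counts",
    "accuracy",
    "jaccard",
    "dice",
    "evaluate",
]


@dataclasses.dataclass(frozen=True)
class SegMetrics:
    """Confusion counts and the derived overlap scores for one mask pair."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    jaccard: float
    dice: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty masks")
    for name, m in (("pred", pred), ("truth", truth)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} values must be in {{0, 1}}")
    return pred.astype(bool), truth.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """Return (tp, tn, fp, fn); the four counts sum to the pixel count."""
    pred, truth = _check_pair(pred, truth)
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return tp, tn, fp, fn


def accuracy(counts: tuple[int, int, int, int]) -> float:
    """Pixel accuracy (tp + tn) / (tp + tn + fp + fn)."""
    tp, tn, fp, fn = counts
    total = tp + tn + fp + fn
    if total <= 0:
        raise ValueError("empty confusion counts")
    return (tp + tn) / total


def jaccard(mask_m: np.ndarray, mask_n: np.ndarray) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    m, n = _check_pair(mask_m, mask_n)
    inter = int(np.count_nonzero(m & n))
    union = int(np.count_nonzero(m)) + int(np.count_nonzero(n)) - inter
    return 1.0 if union == 0 else inter / union


def dice(mask_y: np.ndarray, mask_z: np.ndarray, *, union_denominator: bool = False) -> float:
    """Dice overlap 2|Y∩Z| / (|Y| + |Z|); 1.0 when both masks are empty.

    ``union_denominator=True`` selects the 2|Y∩Z| / |Y∪Z| variant (which
    can exceed 1) for comparison purposes.
    """
    y, z = _check_pair(mask_y, mask_z)
    inter = int(np.count_nonzero(y & z))
    ny, nz = int(np.count_nonzero(y)), int(np.count_nonzero(z))
    if ny + nz == 0:
        return 1.0
    if union_denominator:
        return 2.0 * inter / (ny + nz - inter)
    return 2.0 * inter / (ny + nz)


def evaluate(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """All metrics for one predicted/ground-truth mask pair."""
    counts = confusion_counts(pred, truth)
    return SegMetrics(
        tp=counts[0],
        tn=counts[1],
        fp=counts[2],
        fn=counts[3],
        accuracy=accuracy(counts),
        jaccard=jaccard(pred, truth),
        dice=dice(pred, truth),
    )
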