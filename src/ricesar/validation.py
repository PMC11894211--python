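"""Ground-truth handling and thematic-map accuracy assessment.

Rice/non-rice ground truth points are split (stratified by label) into a
training share used to derive classifier parameters and a validation share
compared against the map in an error matrix, from which overall accuracy,
producer's/user's accuracy and the kappa coefficient are computed:

    OA  = 100 * A / N
    PA_j = 100 * cm[j, j] / colsum_j          (omission complement)
    UA_i = 100 * cm[i, i] / rowsum_i          (commission complement)
    kappa = (N * A - B) / (N**2 - B)

with A the diagonal sum, B the sum over classes of (row total x column
total) and N the number of points.  Rows of the matrix are the mapped
class, columns the reference class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .rules import RICE, NONRICE, UNCLASSIFIABLE

__all__ = [
    "split_ground_truth",
    "confusion_matrix",
    "overall_accuracy",
    "producer_user_accuracy",
    "kappa",
    "accuracy_report",
]

logger = logging.getLogger(__name__)

CLASSES = ("rice", "nonrice")


def split_ground_truth(
    points: pd.DataFrame,
    train_fraction: float = 0.6,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/validation split of ground-truth points.

    ``points`` needs ``x``, ``y`` and ``label`` columns.  Per label,
    ``round(train_fraction * n)`` points go to training; the split is
    disjoint, exhaustive and deterministic under a fixed seed.  Returns
    copies with a ``split`` column added.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    for label, group in points.groupby("label", sort=True):
        n = len(group)
        if n < 2:
            raise ValueError(f"label {label!r} has fewer than 2 points; cannot split")
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        order = rng.permutation(n)
        train_parts.append(group.iloc[order[:n_train]])
        val_parts.append(group.iloc[order[n_train:]])
    train = pd.concat(train_parts).sort_index().assign(split="train")
    validate = pd.concat(val_parts).sort_index().assign(split="validate")
    return train, validate


def confusion_matrix(
    rice_raster: np.ndarray,
    points: pd.DataFrame,
    classes: tuple[str, str] = CLASSES,
) -> pd.DataFrame:
    """Error matrix of mapped vs reference labels at validation points.

    Points are assigned to the pixel containing their coordinates
    (column = floor(x), row = floor(y)); points falling on unclassifiable
    pixels are excluded and logged.  Points outside the raster raise,
    listing the offending indices.
    """
    rice_raster = np.asarray(rice_raster)
    h, w = rice_raster.shape
    rows = np.floor(points["y"].to_numpy(dtype=np.float64)).astype(np.int64)
    cols = np.floor(points["x"].to_numpy(dtype=np.float64)).astype(np.int64)
    outside = (rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)
    if outside.any():
        ids = points.index[outside].tolist()
        raise ValueError(f"ground-truth points outside the raster: {ids}")

    mapped_code = rice_raster[rows, cols]
    usable = mapped_code != UNCLASSIFIABLE
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("excluded %d validation points on unclassifiable pixels", n_excluded)

    rice_name, nonrice_name = classes
    mapped = np.where(mapped_code[usable] == RICE, rice_name, nonrice_name)
    reference = points["label"].to_numpy()[usable]

    cm = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=np.int64)
    cm.index.name = "mapped"
    cm.columns.name = "reference"
    for m, r in zip(mapped, reference):
        cm.loc[m, r] += 1
    return cm


def _as_array(cm) -> np.ndarray:
    arr = cm.to_numpy() if isinstance(cm, pd.DataFrame) else np.asarray(cm)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(arr < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    return arr.astype(np.float64)


def overall_accuracy(cm) -> float:
    """Percent of validation points on the diagonal of the error matrix."""
    arr = _as_array(cm)
    n = arr.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    return float(100.0 * np.trace(arr) / n)


def producer_user_accuracy(cm) -> pd.DataFrame:
    """Producer's and user's accuracy (percent) per class.

    Classes with an empty reference column (PA) or mapped row (UA) are
    reported as missing (NaN), not as zero.
    """
    arr = _as_array(cm)
    names = list(cm.index) if isinstance(cm, pd.DataFrame) else list(range(arr.shape[0]))
    colsum = arr.sum(axis=0)
    rowsum = arr.sum(axis=1)
    diag = np.diag(arr)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(colsum > 0, 100.0 * diag / colsum, np.nan)
        ua = np.where(rowsum > 0, 100.0 * diag / rowsum, np.nan)
    return pd.DataFrame(
        {"producer_pct": pa, "user_pct": ua}, index=pd.Index(names, name="class")
    )


def kappa(cm) -> float:
    """Chance-corrected agreement: (N*A - B) / (N**2 - B)."""
    arr = _as_array(cm)
    n = arr.sum()
    a = np.trace(arr)
    b = float(arr.sum(axis=1) @ arr.sum(axis=0))
    denom = n * n - b
    if denom == 0:
        raise ValueError("degenerate confusion matrix: N**2 == B, kappa undefined")
    return float((n * a - b) / denom)


def accuracy_report(cm) -> dict:
    """Bundle OA (1 decimal), kappa (2 decimals) and per-class PA/UA."""
    pa_ua = producer_user_accuracy(cm)
    return {
        "n_points": int(_as_array(cm).sum()),
        "overall_accuracy_pct": round(overall_accuracy(cm), 1),
        "kappa": round(kappa(cm), 2),
        "per_class": pa_ua.round(2),
    }
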