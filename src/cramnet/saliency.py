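"""Saliency-annotation agreement metrics.

A saliency map is binarized at a fraction of its maximum (30% by default,
inclusive comparison so the peak always survives) and compared with a
binary ground-truth region via IoU and Dice.  The pointing game scores a
hit when the map's single most activated pixel falls inside the annotation
(row-major first occurrence on ties); the normalized overlap is the
fraction of total saliency mass lying inside the annotation.  Images with
an empty annotation are excluded from the pointing game, matching the
class-stratified reporting convention.
"""

from __future__ import annotations

import numpy as np


def binarize_saliency(saliency: np.ndarray, frac: float = 0.30) -> np.ndarray:
    """Pixels >= frac * max(map); all-False for an all-zero map."""
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must lie strictly between 0 and 1")
    saliency = np.asarray(saliency, dtype=float)
    m = saliency.max()
    if m <= 0:
        return np.zeros_like(saliency, dtype=bool)
    return saliency >= frac * m


def _check_shapes(a, b):
    a, b = np.asarray(a, dtype=bool), np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """|A∩B| / |A∪B|; defined as 1 when both masks are empty."""
    a, b = _check_shapes(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); defined as 1 when both masks are empty."""
    a, b = _check_shapes(a, b)
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


def pointing_game(saliency: np.ndarray, gt: np.ndarray) -> int:
    """1 iff the most activated pixel lies inside the annotation.

    Ties at the maximum resolve to the first occurrence in row-major order.
    Raises on an empty annotation (such images are excluded from averages).
    """
    saliency = np.asarray(saliency, dtype=float)
    gt = np.asarray(gt, dtype=bool)
    if saliency.shape != gt.shape:
        raise ValueError(f"shapes differ: {saliency.shape} vs {gt.shape}")
    if not gt.any():
        raise ValueError("pointing game is undefined for an empty annotation")
    peak = np.unravel_index(np.argmax(saliency), saliency.shape)
    return int(gt[peak])


def normalized_overlap(saliency: np.ndarray, gt: np.ndarray) -> float:
    """Fraction of total saliency mass inside the annotation."""
    saliency = np.asarray(saliency, dtype=float)
    gt = np.asarray(gt, dtype=bool)
    if saliency.shape != gt.shape:
        raise ValueError(f"shapes differ: {saliency.shape} vs {gt.shape}")
    total = saliency.sum()
    if total <= 0:
        raise ValueError("normalized overlap is undefined for an all-zero map")
    return float(saliency[gt].sum() / total)


def aggregate(values, labels=None, proportion: bool = False) -> dict:
    """Mean +/- SD (population SD), optionally stratified by class label.

    With ``proportion=True`` (pointing game) only the mean is meaningful and
    SD is reported for completeness.  Returns
    ``{class_or_"all": {"mean": m, "sd": s, "n": n}}``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty batch")
    groups = {"all": values} if labels is None else {
        int(lab): values[np.asarray(labels) == lab] for lab in np.unique(labels)}
    out = {}
    for key, vals in groups.items():
        if vals.size == 0:
            continue
        out[key] = {"mean": float(vals.mean()), "sd": float(vals.std()), "n": int(vals.size)}
    return out
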