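"""Segmentation metrics and qualitative views.

Dice and IoU (Jaccard) on binary masks, slab-wise Dice along the sagittal
axis for hypothesis testing, a pooled-variance two-sample t-test (Welch
variant available), percent improvement between reported scores, maximum
intensity projections, and red/blue error overlays (red = false negative,
blue = false positive, white = true positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

from .volio import LabelVolume, Volume


@dataclass
class MetricReport:
    dice: float
    iou: float
    slab_dice: Optional[List[float]] = None
    metadata: dict = field(default_factory=dict)


def _as_bool(m) -> np.ndarray:
    data = m.data if isinstance(m, Volume) else np.asarray(m)
    return data.astype(bool)


def _check_shapes(a, b):
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def dice(a, b) -> float:
    """2|A∩B| / (|A| + |B|); two empty masks score 1 (correct absence)."""
    a, b = _as_bool(a), _as_bool(b)
    _check_shapes(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(a, b) -> float:
    """|A∩B| / |A∪B|; two empty masks score 1."""
    a, b = _as_bool(a), _as_bool(b)
    _check_shapes(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def slab_scores(pred, gt, n_slabs: int = 9, axis: int = 0) -> List[float]:
    """Dice per contiguous equal slab along ``axis`` (sagittal by default)."""
    p, g = _as_bool(pred), _as_bool(gt)
    _check_shapes(p, g)
    extent = p.shape[axis]
    if extent % n_slabs:
        raise ValueError(
            f"axis extent {extent} not divisible into {n_slabs} equal slabs"
        )
    width = extent // n_slabs
    scores = []
    for i in range(n_slabs):
        sl = [slice(None)] * p.ndim
        sl[axis] = slice(i * width, (i + 1) * width)
        scores.append(dice(p[tuple(sl)], g[tuple(sl)]))
    return scores


def two_sample_ttest(a, b, equal_var: bool = True) -> Tuple[float, float]:
    """Independent two-sample t-test (pooled variance by default).

    Degenerate zero-variance groups with equal means return (0, 1) by
    convention; zero variance with different means returns (inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def percent_improvement(new: float, old: float) -> float:
    """100 * (new - old) / old, reported to two decimals."""
    if old <= 0:
        raise ValueError(f"reference score must be positive, got {old}")
    return round(100.0 * (new - old) / old, 2)


def mip(v, axis: int = 2, roi=None) -> np.ndarray:
    """Maximum intensity projection along ``axis``; ``roi`` is an optional
    tuple of slices restricting the projected region."""
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    if roi is not None:
        data = data[tuple(roi)]
    return data.max(axis=axis)


def overlay_errors(pred, gt, axis: int = 2) -> np.ndarray:
    """MIP-space error overlay as an RGB uint8 image.

    False negatives (gt without prediction) are red, false positives blue,
    true positives white, background black.
    """
    p, g = _as_bool(pred), _as_bool(gt)
    _check_shapes(p, g)
    p2 = p.max(axis=axis)
    g2 = g.max(axis=axis)
    rgb = np.zeros(p2.shape + (3,), dtype=np.uint8)
    fn = g2 & ~p2
    fp = p2 & ~g2
    tp = p2 & g2
    rgb[fn] = (255, 0, 0)
    rgb[fp] = (0, 0, 255)
    rgb[tp] = (255, 255, 255)
    return rgb


def report(
    pred: LabelVolume,
    gt: LabelVolume,
    n_slabs: Optional[int] = None,
    axis: int = 0,
    **metadata,
) -> MetricReport:
    slabs = slab_scores(pred, gt, n_slabs, axis) if n_slabs else None
    return MetricReport(
        dice=dice(pred, gt), iou=iou(pred, gt), slab_dice=slabs,
        metadata=metadata,
    )
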