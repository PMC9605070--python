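"""Tversky / focal Tversky losses and the multi-scale + consistency objectives.

The Tversky index generalises Dice with separate false-negative (alpha) and
false-positive (beta) weights; the focal Tversky loss is (1 - TI)^(1/gamma).
The multi-scale supervision (MSS) loss is the alpha_i-weighted mean of the
focal Tversky loss over the supervision taps.  The Siamese objective adds a
consistency term comparing the deformed prediction of the clean branch with
the prediction of the deformed branch, with gradients flowing through both
branches and through the warp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Union

import numpy as np

from .autodiff import Tensor
from .deform import ElasticTransform, warp_tensor
from .nets import MultiScaleOutput

ArrayLike = Union[np.ndarray, Tensor]


@dataclass
class TverskyParams:
    """alpha weights false negatives, beta false positives; gamma in [1, 3]
    is the focal exponent.

    epsilon is the usual smooth-Dice constant (default 1, as in the focal
    Tversky literature): with a vanishing epsilon every vessel-free patch
    scores a loss near 1 no matter how good the prediction, which swamps
    patch-averaged training and validation losses in sparse volumes.
    """

    alpha: float = 0.7
    beta: float = 0.75
    gamma: float = 4.0 / 3.0
    epsilon: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if not (1.0 <= self.gamma <= 3.0):
            raise ValueError(f"gamma must lie in [1, 3], got {self.gamma}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class MSSWeights:
    """Per-tap weights alpha_i, full resolution first (default 1, 0.5, 0.25)."""

    alphas: Sequence[float] = field(default_factory=lambda: (1.0, 0.5, 0.25))

    def __post_init__(self):
        self.alphas = tuple(float(a) for a in self.alphas)
        if any(a <= 0 for a in self.alphas):
            raise ValueError("all MSS weights must be positive")


def _pair(pred: ArrayLike, target: ArrayLike):
    pred = Tensor.as_tensor(pred)
    target = Tensor.as_tensor(target)
    if pred.shape != target.shape:
        raise ValueError(
            f"prediction shape {pred.shape} != target shape {target.shape}"
        )
    return pred, target


def tversky_index(pred: ArrayLike, target: ArrayLike, p: TverskyParams) -> Tensor:
    """TI = (sum p*g + eps) / (sum p*g + a*sum (1-p)*g + b*sum p*(1-g) + eps)."""
    pred, target = _pair(pred, target)
    tp = (pred * target).sum()
    fn = ((1.0 - pred) * target).sum()
    fp = (pred * (1.0 - target)).sum()
    return (tp + p.epsilon) / (tp + p.alpha * fn + p.beta * fp + p.epsilon)


def focal_tversky_loss(pred: ArrayLike, target: ArrayLike, p: TverskyParams) -> Tensor:
    """FTL = (1 - TI)^(1/gamma) for the single foreground class."""
    ti = tversky_index(pred, target, p)
    return (1.0 - ti) ** (1.0 / p.gamma)


def mss_loss(
    out: MultiScaleOutput, target: ArrayLike, w: MSSWeights, p: TverskyParams
) -> Tensor:
    """Weighted mean of per-tap focal Tversky losses; invariant to a common
    rescaling of the weights."""
    if len(out.maps) != len(w.alphas):
        raise ValueError(
            f"{len(out.maps)} maps but {len(w.alphas)} MSS weights"
        )
    total = None
    for a, m in zip(w.alphas, out.maps):
        term = a * focal_tversky_loss(m, target, p)
        total = term if total is None else total + term
    return total / sum(w.alphas)


def supervised_loss(
    out1: MultiScaleOutput,
    y: ArrayLike,
    out2: MultiScaleOutput,
    ty: ArrayLike,
    w: MSSWeights,
    p: TverskyParams,
) -> Tensor:
    """Sum of the MSS losses of the clean branch (against y) and the deformed
    branch (against the warped label t(y))."""
    return mss_loss(out1, y, w, p) + mss_loss(out2, ty, w, p)


def consistency_loss(
    out1: MultiScaleOutput,
    out2: MultiScaleOutput,
    t: ElasticTransform,
    p: TverskyParams,
) -> Tensor:
    """Focal Tversky loss between the deformed branch's full-resolution map
    and the warped (soft, not re-binarised) map of the clean branch.

    No stop-gradient: the objective backpropagates through both branches and
    through the trilinear warp.
    """
    y1 = out1.full_res
    warped = warp_tensor(y1, t.field)
    return focal_tversky_loss(out2.full_res, warped, p)


def total_loss(sup: ArrayLike, cons: ArrayLike) -> Tensor:
    """Overall Siamese objective: supervised + consistency, unit weights."""
    return Tensor.as_tensor(sup) + Tensor.as_tensor(cons)
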