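"""Composite segmentation training loss: soft mIoU + soft Dice + Boundary.

The three components target complementary failure modes:

* **mIoU loss** ``1 - mean_i |P_i ∩ G_i| / |P_i ∪ G_i]`` over classes i,
  relaxed to products/sums of probabilities so it is differentiable
  (intersection = Σ P·G, union = Σ (P + G - P·G), smoothing ε in numerator
  and denominator).
* **Dice loss** ``1 - 2 Σ P·G / (Σ P² + Σ G²)`` accumulated over all classes
  and pixels in one global ratio.
* **Boundary loss**: the training surrogate weights predicted probability
  mass by the Euclidean distance transform to the ground-truth region
  (zero inside G, distance to the boundary ∂G outside), evaluated over an
  outer band around the boundary and normalised by the band size — zero
  for a perfect prediction and linear in P.  An exact, non-differentiable
  evaluation form (symmetric average boundary distance between hard
  masks) is exposed separately as :func:`boundary_distance`.

The total loss is ``α·L_mIoU + β·L_Dice + γ·L_Boundary`` with non-negative
weights (all 1 by default).  Every function accepts either a probability
Tensor (differentiable path used in training) or a plain array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .autodiff import Tensor, as_tensor

__all__ = [
    "LossWeights",
    "miou_loss",
    "dice_loss",
    "boundary_loss",
    "boundary_distance",
    "average_boundary_distance",
    "total_loss",
    "combine_losses",
]

EPS = 1e-6


@dataclass
class LossWeights:
    """Weights (alpha, beta, gamma) of the mIoU, Dice and Boundary terms."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be non-negative")


def _validate(P, G):
    """Common checks; returns (P as Tensor-or-array, G as float array)."""
    G = np.asarray(G, dtype=np.float64)
    P_data = P.data if isinstance(P, Tensor) else np.asarray(P, dtype=np.float64)
    if P_data.shape != G.shape:
        raise ValueError(f"shape mismatch: P {P_data.shape} vs G {G.shape}")
    if P_data.ndim < 3:
        raise ValueError("expected (C, H, W) or (B, C, H, W) maps")
    if not np.all(np.isfinite(P_data)):
        raise ValueError("non-finite probabilities")
    if P_data.min() < -1e-9 or P_data.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    if G.min() < -1e-9 or G.max() > 1 + 1e-9:
        raise ValueError("ground truth must lie in [0, 1]")
    if not isinstance(P, Tensor):
        P = P_data
    return P, G


def _sum_not_class(x, class_axis: int):
    """Sum over every axis except the class axis (works for Tensor and array)."""
    axes = tuple(a for a in range(x.ndim) if a != class_axis)
    return x.sum(axis=axes) if isinstance(x, Tensor) else x.sum(axis=axes)


def _class_axis(shape) -> int:
    return 0 if len(shape) == 3 else 1


def miou_loss(P, G, eps: float = EPS):
    """1 - mean over classes of soft IoU."""
    P, G = _validate(P, G)
    ax = _class_axis(G.shape)
    inter = _sum_not_class(P * G, ax)
    union = _sum_not_class(P + G - P * G, ax)
    iou = (inter + eps) / (union + eps)
    n_cls = G.shape[ax]
    return iou.sum() * (-1.0 / n_cls) + 1.0


def dice_loss(P, G, eps: float = EPS):
    """1 - 2 Σ P·G / (Σ P² + Σ G²), one global ratio over classes and pixels."""
    P, G = _validate(P, G)
    num = (P * G).sum() * 2.0 + eps
    den = (P * P).sum() + (G * G).sum() + eps
    return 1.0 - num / den


def _boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with a background neighbour (4-connectivity in 2-D,
    faces in n-D); the image border counts as background."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def boundary_loss(P, G, band_width: float = 5.0):
    """Distance-transform-weighted probability mass in the boundary band.

    Per class c with a non-empty ground truth: phi = Euclidean distance
    transform to the G_c region (zero inside G_c, distance to the boundary
    ∂G_c outside), evaluated over the outer boundary band
    B_w = {pixels with 0 < phi <= band_width}:

        L_c = Σ_{i in B_w} P_c(i) * phi(i) / |B_w|

    and the result is averaged over the evaluated classes.  The band keeps
    the term on the same O(1) scale as the overlap losses (saturating the
    penalty at ``band_width`` pixels); a perfect prediction scores exactly 0
    because all its mass sits where phi = 0, and the loss is linear in P.
    Classes whose ground truth is empty are skipped; if every class is empty
    the boundary is undefined and an error is raised.
    """
    P, G = _validate(P, G)
    ax = _class_axis(G.shape)
    n_cls = G.shape[ax]
    terms = []
    for c in range(n_cls):
        idx = (c,) if ax == 0 else (slice(None), c)
        Gc = G[idx].astype(bool)
        if not Gc.any():
            continue
        if Gc.ndim == 3:  # batched: distance transform per batch element
            phi = np.stack([ndimage.distance_transform_edt(~g) for g in Gc])
        else:
            phi = ndimage.distance_transform_edt(~Gc)
        band = (phi > 0) & (phi <= band_width)
        n_b = int(band.sum())
        if n_b == 0:
            continue
        Pc = P[idx]
        term = (Pc * (phi * band)).sum() * (1.0 / n_b)
        terms.append(term)
    if not terms:
        raise ValueError("boundary loss undefined: every class is all-background")
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / len(terms))


def average_boundary_distance(a_points, b_points) -> float:
    """Symmetric mean nearest-neighbour distance between two boundary point
    sets (pixels): the exact, non-differentiable reading of the boundary
    criterion."""
    from scipy.spatial import cKDTree

    a = np.atleast_2d(np.asarray(a_points, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b_points, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("boundary distance undefined for an empty point set")
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def boundary_distance(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Exact evaluation form on hard masks: symmetric average distance
    between the two masks' boundaries (4-neighbourhood, border counts as
    background)."""
    from .metrics import extract_boundary  # shared boundary definition

    return average_boundary_distance(
        extract_boundary(pred_mask), extract_boundary(truth_mask)
    )


def total_loss(P, G, w: LossWeights | None = None):
    """alpha*L_mIoU + beta*L_Dice + gamma*L_Boundary (surrogate boundary term)."""
    if w is None:
        w = LossWeights()
    if w.alpha < 0 or w.beta < 0 or w.gamma < 0:
        raise ValueError("loss weights must be non-negative")
    terms = None
    if w.alpha:
        terms = miou_loss(P, G) * w.alpha
    if w.beta:
        t = dice_loss(P, G) * w.beta
        terms = t if terms is None else terms + t
    if w.gamma:
        t = boundary_loss(P, G) * w.gamma
        terms = t if terms is None else terms + t
    if terms is None:  # all weights zero
        terms = as_tensor(0.0) if isinstance(P, Tensor) else 0.0
    return terms


def combine_losses(miou: float, dice: float, boundary: float,
                   w: LossWeights | None = None) -> float:
    """Weighted combination of already-computed component values."""
    if w is None:
        w = LossWeights()
    return w.alpha * miou + w.beta * dice + w.gamma * boundary
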