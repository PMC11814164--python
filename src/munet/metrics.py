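"""Segmentation evaluation metrics.

Pixel-count metrics (Cohen's kappa, Dice similarity coefficient, IoU,
sensitivity, precision, specificity, accuracy, balanced accuracy) are
computed from exact integer confusion counts; boundary accuracy uses the
95th-percentile Hausdorff distance

    H95(A, B) = max{ h95(A, B), h95(B, A) }

where h95(A, B) is the 95th percentile (linear-interpolation convention) of
the nearest-neighbour Euclidean distances from boundary points of A to
boundary points of B, in pixel units.

Degenerate denominators are reported as *undefined* (``None``), never as 0.
By convention a pair of empty masks scores DSC = IoU = 1 and an undefined
Hausdorff distance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "RateMetrics",
    "MetricsReport",
    "confusion",
    "kappa",
    "rate_metrics",
    "dsc_iou",
    "extract_boundary",
    "hausdorff95",
    "evaluate_case",
    "reports_to_dataframe",
]

METRIC_COLUMNS = (
    "kappa", "dsc", "iou", "sensitivity", "precision", "specificity",
    "accuracy", "balanced_accuracy", "hausdorff95",
)


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator vanishes and no value exists."""


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def p_o(self) -> float:
        """Observed agreement: fraction of pixels where the raters agree."""
        return (self.tp + self.tn) / self.total

    @property
    def p_e(self) -> float:
        """Chance agreement from the marginal products."""
        n = self.total
        pred_pos = (self.tp + self.fp) / n
        truth_pos = (self.tp + self.fn) / n
        return pred_pos * truth_pos + (1 - pred_pos) * (1 - truth_pos)


@dataclass
class RateMetrics:
    sensitivity: float | None
    precision: float | None
    specificity: float | None
    accuracy: float | None
    balanced_accuracy: float | None


@dataclass
class MetricsReport:
    region: str
    kappa: float | None = None
    dsc: float | None = None
    iou: float | None = None
    sensitivity: float | None = None
    precision: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    balanced_accuracy: float | None = None
    hausdorff95: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _as_binary(mask, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} must be binary, found values {vals[:5]}")
        mask = mask.astype(bool)
    return mask


def confusion(pred, truth) -> ConfusionCounts:
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa (P_o - P_e)/(1 - P_e)."""
    if c.total <= 0:
        raise ValueError("empty confusion table")
    pe = c.p_e
    if pe >= 1.0 - 1e-15:
        raise UndefinedMetricError(
            "kappa undefined: chance agreement P_e = 1 (both raters constant)"
        )
    return (c.p_o - pe) / (1.0 - pe)


def rate_metrics(c: ConfusionCounts) -> RateMetrics:
    """Sensitivity, precision, specificity, accuracy, balanced accuracy.

    A metric whose denominator is zero is reported as None (undefined).
    """
    if c.total <= 0:
        raise ValueError("empty confusion table")
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    acc = (c.tp + c.tn) / c.total
    ba = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    return RateMetrics(sensitivity=sens, precision=prec, specificity=spec,
                       accuracy=acc, balanced_accuracy=ba)


def dsc_iou(pred, truth) -> tuple[float, float]:
    """Dice coefficient and IoU on hard masks; both-empty pair scores (1, 1)."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    inter = int(np.count_nonzero(pred & truth))
    a = int(np.count_nonzero(pred))
    b = int(np.count_nonzero(truth))
    if a + b == 0:
        return 1.0, 1.0
    dsc = 2.0 * inter / (a + b)
    iou = inter / (a + b - inter)
    return dsc, iou


def extract_boundary(mask) -> np.ndarray:
    """Coordinates (K, ndim) of foreground pixels with a background
    face-neighbour; the image border counts as background."""
    mask = _as_binary(mask, "mask")
    if not mask.any():
        raise ValueError("boundary undefined for an all-background mask")
    if mask.all():
        raise ValueError(
            "boundary undefined for an all-foreground mask; "
            "expected both foreground and background pixels"
        )
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    boundary = mask & ~eroded
    return np.argwhere(boundary)


def hausdorff95(a_points: np.ndarray, b_points: np.ndarray) -> float:
    """Symmetric 95th-percentile Hausdorff distance between two point sets."""
    a = np.atleast_2d(np.asarray(a_points, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b_points, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("hausdorff95 undefined for an empty point set")
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    h_ab = float(np.percentile(d_ab, 95))
    h_ba = float(np.percentile(d_ba, 95))
    return max(h_ab, h_ba)


def evaluate_case(pred_labels, truth_labels) -> dict[str, MetricsReport]:
    """Per-region (ET / WT / TC) metric report for one labelled case.

    Labels follow the BraTS convention {0, 1, 2, 4}; the three nested
    evaluation regions are derived by :func:`munet.data.derive_regions`.
    Metrics whose denominators vanish are reported as None.
    """
    from .data import derive_regions

    pred_labels = np.asarray(pred_labels)
    truth_labels = np.asarray(truth_labels)
    if pred_labels.shape != truth_labels.shape:
        raise ValueError(
            f"shape mismatch: {pred_labels.shape} vs {truth_labels.shape}"
        )
    pred_regions = derive_regions(pred_labels)
    truth_regions = derive_regions(truth_labels)
    reports = {}
    for region in ("ET", "WT", "TC"):
        p = pred_regions[region]
        t = truth_regions[region]
        rep = MetricsReport(region=region)
        c = confusion(p, t)
        try:
            rep.kappa = kappa(c)
        except UndefinedMetricError:
            rep.kappa = None
        rates = rate_metrics(c)
        rep.sensitivity = rates.sensitivity
        rep.precision = rates.precision
        rep.specificity = rates.specificity
        rep.accuracy = rates.accuracy
        rep.balanced_accuracy = rates.balanced_accuracy
        rep.dsc, rep.iou = dsc_iou(p, t)
        try:
            rep.hausdorff95 = hausdorff95(extract_boundary(p), extract_boundary(t))
        except ValueError:
            rep.hausdorff95 = None
        reports[region] = rep
    return reports


def reports_to_dataframe(case_reports: dict[str, dict[str, MetricsReport]]):
    """Flatten {case_id: {region: report}} into a tidy DataFrame."""
    import pandas as pd

    rows = []
    for case_id, regions in case_reports.items():
        for region, rep in regions.items():
            row = {"case": case_id, "region": region}
            row.update({k: rep.to_dict()[k] for k in METRIC_COLUMNS})
            rows.append(row)
    return pd.DataFrame(rows, columns=["case", "region", *METRIC_COLUMNS])
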