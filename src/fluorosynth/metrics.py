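"""Segmentation and image-quality evaluation metrics.

Average precision follows the raw Riemann form AP = sum_n (r_n - r_{n-1}) * p_n
over the precision-recall curve traced at each distinct confidence threshold
(no interpolation smoothing); detections are matched to ground truth greedily
by descending confidence, each ground-truth region consumable once, with a
match requiring IoU strictly greater than the threshold.  mAP50 averages AP
over classes at IoU 0.5; mAP50:95 additionally averages over the ten
thresholds 0.50, 0.55, ..., 0.95.  Both are computed separately for bounding
boxes (B) and masks (M).

Image quality is quantified by Michelson contrast between a manually defined
object and background region, and by a robust noise estimate: 1.4826 times
the median absolute deviation of intensities in a noise region, which
approximates the Gaussian noise standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MAD_TO_SIGMA",
    "MAP5095_THRESHOLDS",
    "PRCurve",
    "RegionSpec",
    "EvalReport",
    "iou",
    "average_precision",
    "map_suite",
    "michelson_contrast",
    "estimate_noise",
]

MAD_TO_SIGMA = 1.4826  # MAD -> Gaussian sigma scaling
MAP5095_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))  # 10 thresholds


@dataclass
class PRCurve:
    """Precision-recall points ordered by descending confidence threshold."""

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.recall) < -1e-12):
            raise ValueError("recall must be non-decreasing along the curve")


@dataclass
class RegionSpec:
    """Manually defined analysis regions: object, background, noise."""

    m_obj: np.ndarray | None = None
    m_back: np.ndarray | None = None
    m_noise: np.ndarray | None = None

    def __post_init__(self) -> None:
        masks = [m for m in (self.m_obj, self.m_back, self.m_noise) if m is not None]
        shapes = {m.shape for m in masks}
        if len(shapes) > 1:
            raise ValueError("region masks must share dimensions")
        if self.m_obj is not None and self.m_back is not None:
            if np.any(np.asarray(self.m_obj, bool) & np.asarray(self.m_back, bool)):
                raise ValueError("object and background regions must be disjoint")


@dataclass
class EvalReport:
    """Assembled evaluation results."""

    ap_per_class: dict = field(default_factory=dict)
    map50_b: float | None = None
    map50_m: float | None = None
    map5095_b: float | None = None
    map5095_m: float | None = None
    lsr: float | None = None
    contrast: float | None = None
    noise_sigma: float | None = None

    def to_json(self, path: str | Path) -> None:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        payload = {k: v for k, v in vars(self).items()}
        p.write_text(json.dumps(payload, indent=1, default=float))

    def to_csv(self, path: str | Path) -> None:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        rows = ["metric,value"]
        for k, v in vars(self).items():
            if k == "ap_per_class":
                for cls, ap in v.items():
                    rows.append(f"ap_class_{cls},{ap}")
            elif v is not None:
                rows.append(f"{k},{v}")
        p.write_text("\n".join(rows) + "\n")


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks or two (x0, y0, x1, y1)
    boxes.  Both empty -> 1.0 by convention."""
    a_arr, b_arr = np.asarray(a), np.asarray(b)
    if a_arr.ndim == 2 and b_arr.ndim == 2:
        if a_arr.shape != b_arr.shape:
            raise ValueError(f"mask dimensions differ: {a_arr.shape} vs {b_arr.shape}")
        am, bm = a_arr.astype(bool), b_arr.astype(bool)
        union = np.count_nonzero(am | bm)
        if union == 0:
            return 1.0
        return np.count_nonzero(am & bm) / union
    if a_arr.shape == (4,) and b_arr.shape == (4,):
        ix0, iy0 = max(a_arr[0], b_arr[0]), max(a_arr[1], b_arr[1])
        ix1, iy1 = min(a_arr[2], b_arr[2]), min(a_arr[3], b_arr[3])
        inter = max(0.0, ix1 - ix0) * max(0.0, iy1 - iy0)
        area_a = max(0.0, a_arr[2] - a_arr[0]) * max(0.0, a_arr[3] - a_arr[1])
        area_b = max(0.0, b_arr[2] - b_arr[0]) * max(0.0, b_arr[3] - b_arr[1])
        union = area_a + area_b - inter
        if union <= 0:
            return 1.0
        return float(inter / union)
    raise ValueError("iou expects two masks of equal shape or two 4-vectors")


def _greedy_match(
    confidences: np.ndarray, iou_matrix: np.ndarray, iou_threshold: float
) -> np.ndarray:
    """TP flags: greedy by descending confidence (ties -> higher IoU), each
    ground truth consumed once, match requires IoU strictly > threshold."""
    n_det, n_gt = iou_matrix.shape
    tp = np.zeros(n_det, dtype=bool)
    order = sorted(
        range(n_det),
        key=lambda i: (-confidences[i], -(iou_matrix[i].max() if n_gt else 0.0)),
    )
    taken = np.zeros(n_gt, dtype=bool)
    for i in order:
        if n_gt == 0:
            break
        ious = np.where(taken, -1.0, iou_matrix[i])
        j = int(np.argmax(ious))
        if ious[j] > iou_threshold:
            tp[i] = True
            taken[j] = True
    return tp


def pr_curve(
    confidences: np.ndarray, tp: np.ndarray, n_gt: int
) -> PRCurve:
    """Trace (recall, precision) at each distinct confidence threshold,
    descending."""
    order = np.argsort(-confidences, kind="stable")
    conf = confidences[order]
    flags = tp[order]
    cum_tp = np.cumsum(flags)
    cum_fp = np.cumsum(~flags)
    # keep the last entry of each tied-confidence group
    distinct = np.flatnonzero(np.r_[np.diff(conf) != 0, True])
    recall = cum_tp[distinct] / n_gt
    precision = cum_tp[distinct] / (cum_tp[distinct] + cum_fp[distinct])
    return PRCurve(recall=recall, precision=precision, thresholds=conf[distinct])


def average_precision(
    confidences,
    iou_matrix,
    iou_threshold: float = 0.5,
) -> float:
    """AP from detection confidences and the detection-vs-ground-truth IoU
    matrix: AP = sum_n (r_n - r_{n-1}) * p_n over the PR curve.

    ``iou_matrix`` has shape (n_detections, n_ground_truths); with zero
    ground truths the metric is undefined and raises.
    """
    confidences = np.asarray(confidences, dtype=float)
    iou_matrix = np.asarray(iou_matrix, dtype=float)
    if confidences.size:
        iou_matrix = iou_matrix.reshape(len(confidences), -1)
        n_gt = iou_matrix.shape[1]
    else:
        n_gt = iou_matrix.shape[1] if iou_matrix.ndim == 2 else 1
    if n_gt == 0:
        raise ValueError("AP is undefined without ground-truth instances")
    if confidences.size == 0:
        return 0.0
    tp = _greedy_match(confidences, iou_matrix, iou_threshold)
    curve = pr_curve(confidences, tp, n_gt)
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(curve.recall, curve.precision):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def _geometry_iou_matrix(detections, ground_truths, geometry: str) -> np.ndarray:
    """IoU matrix; entries across different source images (optional ``img``
    key) are 0 so detections can only match ground truth from their own
    frame."""
    mat = np.zeros((len(detections), len(ground_truths)))
    for i, d in enumerate(detections):
        for j, g in enumerate(ground_truths):
            if d.get("img") is not None and g.get("img") is not None and d["img"] != g["img"]:
                continue
            mat[i, j] = iou(d[geometry], g[geometry])
    return mat


def map_suite(detections_by_class: dict, ground_truths_by_class: dict) -> EvalReport:
    """mAP50 and mAP50:95 for boxes (B) and masks (M).

    Inputs map class id -> list of dicts with keys ``confidence`` (detections
    only), ``box`` (x0, y0, x1, y1) and ``mask`` (binary array).  Classes
    present in the ground truth with no detections score AP = 0.
    """
    classes = sorted(ground_truths_by_class)
    if not classes:
        raise ValueError("no ground-truth classes to evaluate")
    report = EvalReport()
    ap50 = {"box": [], "mask": []}
    ap_all = {"box": [], "mask": []}
    for cls in classes:
        gts = ground_truths_by_class[cls]
        dets = detections_by_class.get(cls, [])
        conf = np.array([d["confidence"] for d in dets], dtype=float)
        for geom in ("box", "mask"):
            mat = _geometry_iou_matrix(dets, gts, geom)
            per_thr = [
                average_precision(conf, mat, thr) if len(dets) else 0.0
                for thr in MAP5095_THRESHOLDS
            ]
            ap50[geom].append(per_thr[0])
            ap_all[geom].append(float(np.mean(per_thr)))
        report.ap_per_class[cls] = ap50["mask"][-1]
    report.map50_b = float(np.mean(ap50["box"]))
    report.map50_m = float(np.mean(ap50["mask"]))
    report.map5095_b = float(np.mean(ap_all["box"]))
    report.map5095_m = float(np.mean(ap_all["mask"]))
    return report


def michelson_contrast(image: np.ndarray, regions: RegionSpec) -> float:
    """(mean_obj - mean_back) / (mean_obj + mean_back) over the named regions."""
    if regions.m_obj is None or regions.m_back is None:
        raise ValueError("object and background regions are required")
    img = np.asarray(image, dtype=float)
    m_obj = np.asarray(regions.m_obj, bool)
    m_back = np.asarray(regions.m_back, bool)
    if not m_obj.any() or not m_back.any():
        raise ValueError("regions must be non-empty")
    mean_obj = img[m_obj].mean()
    mean_back = img[m_back].mean()
    denom = mean_obj + mean_back
    if denom == 0:
        raise ZeroDivisionError("contrast undefined: both region means are zero")
    return float((mean_obj - mean_back) / denom)


def estimate_noise(image: np.ndarray, m_noise: np.ndarray) -> float:
    """Robust sigma estimate: 1.4826 x median(|v - median(v)|) over M_noise."""
    m = np.asarray(m_noise, bool)
    if not m.any():
        raise ValueError("noise region is empty")
    v = np.asarray(image, dtype=float)[m]
    med = np.median(v)
    return float(MAD_TO_SIGMA * np.median(np.abs(v - med)))


def roi_classification_ap(roi_max_confidences, roi_has_object) -> float:
    """Classification-mode AP: each region of interest is scored by the
    maximum detection confidence inside it and labelled MMD / non-MMD."""
    conf = np.asarray(roi_max_confidences, dtype=float)
    truth = np.asarray(roi_has_object, dtype=bool)
    n_gt = int(truth.sum())
    if n_gt == 0:
        raise ValueError("AP is undefined without positive regions")
    # positives "match" trivially: IoU matrix is identity-like over positives
    order = np.argsort(-conf, kind="stable")
    tp = truth[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    distinct = np.flatnonzero(np.r_[np.diff(conf[order]) != 0, True])
    recall = cum_tp[distinct] / n_gt
    precision = cum_tp[distinct] / (cum_tp[distinct] + cum_fp[distinct])
    r_prev, ap = 0.0, 0.0
    for r, p in zip(recall, precision):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)
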