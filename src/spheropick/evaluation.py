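"""IoU-matched instance-segmentation benchmarking.

Predicted and ground-truth objects are matched one-to-one by an optimal
assignment on the IoU matrix, restricted to pairs with IoU at or above the
threshold τ. From the matched counts two scores are computed per τ:

    P = TP / (TP + FP + FN)        detection-quality score
    S = TP / Positive              sensitivity (recall over ground truth)

The detection-quality score deliberately includes false negatives in the
denominator — it penalises both spurious and missed objects at once and is
distinct from the classical precision TP/(TP+FP), which is also emitted,
clearly labelled, for cross-tool comparison. Dataset aggregation defaults
to pooling (micro-averaging): counts are summed across images per τ before
the scores are applied; per-image macro averages are computed as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import validate_label_mask

#: default IoU threshold grid, 0.50 to 0.95 in steps of 0.05
DEFAULT_TAU_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class EvalCounts:
    """Matched-object counts at one IoU threshold."""

    tp: int
    fp: int
    fn: int
    n_gt: int
    iou_threshold: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.n_gt) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.fn != self.n_gt:
            raise ValueError(f"tp + fn = {self.tp + self.fn} must equal n_gt = {self.n_gt}")
        if not (0 < self.iou_threshold < 1):
            raise ValueError("iou_threshold must lie in (0, 1)")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        if other.iou_threshold != self.iou_threshold:
            raise ValueError("cannot pool counts at different thresholds")
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn, self.n_gt + other.n_gt,
                          self.iou_threshold)


@dataclass
class EvalCurve:
    """Scores across a grid of IoU thresholds."""

    points: list[tuple[float, float, float]]  # (tau, precision, sensitivity)
    scope: str = "pooled"
    counts: list[EvalCounts] = field(default_factory=list)

    @property
    def taus(self) -> list[float]:
        return [p[0] for p in self.points]

    def precision_at(self, tau: float) -> float:
        return dict((t, p) for t, p, _ in self.points)[tau]

    def sensitivity_at(self, tau: float) -> float:
        return dict((t, s) for t, _, s in self.points)[tau]


def object_iou(object_a: np.ndarray, object_b: np.ndarray) -> float:
    """Intersection over union of two aligned boolean pixel sets."""
    a = np.asarray(object_a).astype(bool)
    b = np.asarray(object_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("both objects are empty")
    inter = np.count_nonzero(a & b)
    return inter / union


def iou_matrix(gt: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Pairwise IoU between ground-truth and predicted labels.

    Rows index ground-truth labels 1..n_gt, columns predicted labels
    1..n_pred. Computed from the joint label histogram in one pass.
    """
    gt = validate_label_mask(gt, name="gt")
    pred = validate_label_mask(pred, name="pred")
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    n_gt = int(gt.max())
    n_pred = int(pred.max())
    if n_gt == 0 or n_pred == 0:
        return np.zeros((n_gt, n_pred))
    joint = np.bincount(gt.ravel() * (n_pred + 1) + pred.ravel(),
                        minlength=(n_gt + 1) * (n_pred + 1)).reshape(n_gt + 1, n_pred + 1)
    inter = joint[1:, 1:].astype(np.float64)
    gt_area = joint[1:, :].sum(axis=1, keepdims=True)
    pred_area = joint[:, 1:].sum(axis=0, keepdims=True)
    union = gt_area + pred_area - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def match_objects(pred: np.ndarray, gt: np.ndarray, tau: float = 0.5
                  ) -> tuple[EvalCounts, list[tuple[int, int, float]]]:
    """One-to-one matching maximising total IoU over pairs with IoU ≥ τ.

    Returns the counts and the matched (gt_label, pred_label, iou) list
    sorted by ascending (gt, pred) labels.
    """
    if not (0 < tau < 1):
        raise ValueError("tau must lie in (0, 1)")
    iou = iou_matrix(gt, pred)
    n_gt, n_pred = iou.shape
    eligible = np.where(iou >= tau, iou, 0.0)
    matches: list[tuple[int, int, float]] = []
    if n_gt and n_pred and eligible.any():
        rows, cols = linear_sum_assignment(eligible, maximize=True)
        for r, c in zip(rows, cols):
            if iou[r, c] >= tau:
                matches.append((r + 1, c + 1, float(iou[r, c])))
        matches.sort()
    tp = len(matches)
    counts = EvalCounts(tp=tp, fp=n_pred - tp, fn=n_gt - tp, n_gt=n_gt, iou_threshold=tau)
    return counts, matches


def precision_score(c: EvalCounts) -> float:
    """Detection-quality score TP/(TP+FP+FN); 1 by convention when the
    image is empty and nothing was predicted."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def classical_precision(c: EvalCounts) -> float:
    """Classical precision TP/(TP+FP); 1 when nothing was predicted."""
    denom = c.tp + c.fp
    if denom == 0:
        return 1.0
    return c.tp / denom


def sensitivity_score(c: EvalCounts) -> float:
    """Sensitivity TP/Positive over the ground-truth objects."""
    if c.n_gt == 0:
        raise ValueError("sensitivity undefined for an image without ground-truth objects")
    return c.tp / c.n_gt


@dataclass
class DatasetEvaluation:
    """Pooled and per-image curves over a dataset."""

    pooled: EvalCurve
    per_image_mean: EvalCurve
    per_image: list[EvalCurve]


def evaluate_dataset(pairs, taus=DEFAULT_TAU_GRID) -> DatasetEvaluation:
    """Score (pred, gt) mask pairs across a threshold grid.

    Pooled scope sums counts across images per τ before scoring;
    per-image scope averages per-image scores, excluding images with no
    ground-truth objects from the sensitivity average.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one (pred, gt) pair")
    taus = [float(t) for t in taus]
    if not taus:
        raise ValueError("threshold grid is empty")
    if any(not (0 < t < 1) for t in taus) or any(b <= a for a, b in zip(taus, taus[1:])):
        raise ValueError("taus must be strictly increasing within (0, 1)")

    per_image_counts = [[match_objects(pred, gt, t)[0] for t in taus] for pred, gt in pairs]

    pooled_points, pooled_counts = [], []
    for j, t in enumerate(taus):
        total = per_image_counts[0][j]
        for row in per_image_counts[1:]:
            total = total + row[j]
        pooled_points.append((t, precision_score(total),
                              sensitivity_score(total) if total.n_gt > 0 else float("nan")))
        pooled_counts.append(total)
    pooled = EvalCurve(points=pooled_points, scope="pooled", counts=pooled_counts)

    per_image_curves = []
    for row in per_image_counts:
        pts = [(c.iou_threshold, precision_score(c),
                sensitivity_score(c) if c.n_gt > 0 else float("nan")) for c in row]
        per_image_curves.append(EvalCurve(points=pts, scope="per_image", counts=row))

    mean_points = []
    for j, t in enumerate(taus):
        ps = [curve.points[j][1] for curve in per_image_curves]
        ss = [curve.points[j][2] for curve in per_image_curves
              if not np.isnan(curve.points[j][2])]
        mean_points.append((t, float(np.mean(ps)), float(np.mean(ss)) if ss else float("nan")))
    per_image_mean = EvalCurve(points=mean_points, scope="per_image_mean")

    return DatasetEvaluation(pooled=pooled, per_image_mean=per_image_mean,
                             per_image=per_image_curves)
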