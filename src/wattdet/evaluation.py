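"""Detection metrics: P/R/F1, AP, mAP@0.5, mAP@0.5:0.95, confusion matrix.

Boxes are axis-aligned ``(x1, y1, x2, y2)`` corners in any consistent
unit.  Average precision uses all-point (continuous) integration of the
precision envelope; an 11-point variant is switchable.  Confidence ties
break by ascending detection index for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError

__all__ = [
    "Detection", "TruthBox", "MetricsReport",
    "iou", "nms", "match_and_count", "average_precision",
    "map_over_thresholds", "confusion_matrix", "f1", "evaluate_detections",
    "detect_items", "pr_curve",
    "gradcam_heatmap",
]

IOU_THRESHOLDS = np.arange(0.5, 0.9999, 0.05)   # 0.50, 0.55, ..., 0.95


@dataclass
class Detection:
    """A scored predicted box."""

    class_id: int
    box: np.ndarray            # (4,) x1,y1,x2,y2
    confidence: float
    image_id: int = 0

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.box.shape != (4,):
            raise DimensionError("box must be (x1, y1, x2, y2)")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class TruthBox:
    """A ground-truth box."""

    class_id: int
    box: np.ndarray
    image_id: int = 0

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.box.shape != (4,):
            raise DimensionError("box must be (x1, y1, x2, y2)")


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two corner-format boxes, in [0, 1]."""
    a = np.asarray(box_a, dtype=np.float64)
    b = np.asarray(box_b, dtype=np.float64)
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = ((a[2] - a[0]) * (a[3] - a[1])
             + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return float(inter / union) if union > 0 else 0.0


def _iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """(Na, Nb) pairwise IoU."""
    if len(boxes_a) == 0 or len(boxes_b) == 0:
        return np.zeros((len(boxes_a), len(boxes_b)))
    a = boxes_a[:, None]
    b = boxes_b[None]
    ix = np.clip(np.minimum(a[..., 2], b[..., 2])
                 - np.maximum(a[..., 0], b[..., 0]), 0, None)
    iy = np.clip(np.minimum(a[..., 3], b[..., 3])
                 - np.maximum(a[..., 1], b[..., 1]), 0, None)
    inter = ix * iy
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    union = area_a + area_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def _sorted_indices(dets: list[Detection]) -> list[int]:
    """Descending confidence; ties by ascending index."""
    return sorted(range(len(dets)),
                  key=lambda i: (-dets[i].confidence, i))


def nms(detections: list[Detection], iou_thresh: float = 0.7,
        conf_thresh: float = 0.25) -> list[Detection]:
    """Class-wise greedy suppression by descending confidence."""
    kept: list[Detection] = []
    alive = [d for d in detections if d.confidence >= conf_thresh]
    for cls in sorted({d.class_id for d in alive}):
        group = [d for d in alive if d.class_id == cls]
        order = _sorted_indices(group)
        chosen: list[Detection] = []
        for i in order:
            if all(iou(group[i].box, c.box) <= iou_thresh for c in chosen):
                chosen.append(group[i])
        kept.extend(chosen)
    return kept


def match_and_count(detections: list[Detection], truths: list[TruthBox],
                    iou_thresh: float = 0.5
                    ) -> tuple[int, int, int, list[bool]]:
    """Greedy one-to-one matching in descending confidence order.

    A detection is a true positive iff it shares the class of, and has
    IoU strictly above ``iou_thresh`` with, a not-yet-matched truth of
    the same image.  Returns ``(TP, FP, FN, per_detection_flags)`` with
    flags ordered like the sorted detections.
    """
    order = _sorted_indices(detections)
    used = [False] * len(truths)
    flags: list[bool] = []
    for i in order:
        d = detections[i]
        best_j, best_iou = -1, iou_thresh
        for j, t in enumerate(truths):
            if used[j] or t.class_id != d.class_id \
                    or t.image_id != d.image_id:
                continue
            v = iou(d.box, t.box)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0:
            used[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    tp = sum(flags)
    return tp, len(flags) - tp, len(truths) - tp, flags


def average_precision(flags: list[bool], n_truths: int,
                      method: str = "continuous") -> float:
    """Area under the precision envelope from ranked TP/FP flags.

    ``method="continuous"`` integrates the exact envelope over all
    recall points; ``"11point"`` samples recall at 0, 0.1, ..., 1.
    """
    if n_truths == 0:
        return 0.0
    if not flags:
        return 0.0
    tps = np.cumsum(np.asarray(flags, dtype=np.float64))
    fps = np.cumsum(~np.asarray(flags, dtype=bool))
    recall = tps / n_truths
    precision = tps / (tps + fps)
    # precision envelope: running max from the right
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    if method == "11point":
        pts = np.linspace(0, 1, 11)
        return float(np.mean([p[np.searchsorted(r, t, side="left")]
                              if t <= r[-1] else 0.0 for t in pts]))
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def map_over_thresholds(detections: list[Detection],
                        truths: list[TruthBox],
                        num_classes: int = 6) -> tuple[float, float, dict]:
    """Class-mean AP at IoU 0.5 and averaged over IoU 0.50:0.95.

    Classes with no ground-truth instances are excluded from the means.
    Returns ``(mAP@0.5, mAP@0.5:0.95, per_class)`` where ``per_class``
    maps class id to ``{"ap50": ..., "ap5095": ...}``.
    """
    per_class: dict[int, dict] = {}
    ap50s, ap5095s = [], []
    for cls in range(num_classes):
        cls_t = [t for t in truths if t.class_id == cls]
        if not cls_t:
            continue
        cls_d = [d for d in detections if d.class_id == cls]
        aps = []
        for thr in IOU_THRESHOLDS:
            _, _, _, flags = match_and_count(cls_d, cls_t, iou_thresh=thr)
            aps.append(average_precision(flags, len(cls_t)))
        per_class[cls] = {"ap50": aps[0], "ap5095": float(np.mean(aps))}
        ap50s.append(aps[0])
        ap5095s.append(per_class[cls]["ap5095"])
    map50 = float(np.mean(ap50s)) if ap50s else 0.0
    map5095 = float(np.mean(ap5095s)) if ap5095s else 0.0
    return map50, map5095, per_class


def confusion_matrix(detections: list[Detection], truths: list[TruthBox],
                     conf: float = 0.25, iou_thresh: float = 0.5,
                     num_classes: int = 6
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(num_classes+1)^2 counts and the row-normalized form.

    Rows are true classes (last row = background), columns predicted
    classes (last column = background).  Matching is class-agnostic by
    IoU so that class swaps land off-diagonal.
    """
    n = num_classes + 1
    mat = np.zeros((n, n), dtype=np.int64)
    dets = [d for d in detections if d.confidence >= conf]
    for img in sorted({t.image_id for t in truths}
                      | {d.image_id for d in dets}):
        img_t = [t for t in truths if t.image_id == img]
        img_d = [dets[i] for i in _sorted_indices(dets)
                 if dets[i].image_id == img]
        used_t = [False] * len(img_t)
        for d in img_d:
            best_j, best = -1, iou_thresh
            for j, t in enumerate(img_t):
                if used_t[j]:
                    continue
                v = iou(d.box, t.box)
                if v > best:
                    best, best_j = v, j
            if best_j >= 0:
                used_t[best_j] = True
                mat[img_t[best_j].class_id, d.class_id] += 1
            else:
                mat[num_classes, d.class_id] += 1
        for j, t in enumerate(img_t):
            if not used_t[j]:
                mat[t.class_id, num_classes] += 1
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        norm = np.where(sums > 0, mat / np.maximum(sums, 1), 0.0)
    return mat, norm


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall."""
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


@dataclass
class MetricsReport:
    """Aggregate + per-class detection metrics."""

    precision: float
    recall: float
    f1: float
    map50: float
    map5095: float
    per_class: dict = field(default_factory=dict)
    confusion: np.ndarray | None = None
    confusion_normalized: np.ndarray | None = None
    pr_curves: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"precision": self.precision, "recall": self.recall,
             "f1": self.f1, "map50": self.map50, "map5095": self.map5095,
             "per_class": {str(k): v for k, v in self.per_class.items()}}
        if self.confusion is not None:
            d["confusion"] = self.confusion.tolist()
        return d


def pr_curve(detections: list[Detection], truths: list[TruthBox],
             iou_thresh: float = 0.5) -> np.ndarray:
    """(n, 2) array of (recall, precision) points in ranking order."""
    _, _, _, flags = match_and_count(detections, truths, iou_thresh)
    if not flags:
        return np.zeros((0, 2))
    tps = np.cumsum(np.asarray(flags, dtype=np.float64))
    fps = np.cumsum(~np.asarray(flags, dtype=bool))
    return np.stack([tps / max(len(truths), 1), tps / (tps + fps)], axis=1)


def evaluate_detections(detections: list[Detection],
                        truths: list[TruthBox], num_classes: int = 6,
                        conf: float = 0.25, iou_thresh: float = 0.5
                        ) -> MetricsReport:
    """Full metrics report at the standard operating point."""
    strong = [d for d in detections if d.confidence >= conf]
    tp, fp, fn, _ = match_and_count(strong, truths, iou_thresh)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    map50, map5095, per_class = map_over_thresholds(
        detections, truths, num_classes)
    mat, norm = confusion_matrix(detections, truths, conf, iou_thresh,
                                 num_classes)
    curves = {}
    for cls in range(num_classes):
        cls_d = [d for d in detections if d.class_id == cls]
        cls_t = [t for t in truths if t.class_id == cls]
        if cls_t:
            curves[cls] = pr_curve(cls_d, cls_t, iou_thresh)
    return MetricsReport(precision=p, recall=r, f1=f1(p, r),
                         map50=map50, map5095=map5095, per_class=per_class,
                         confusion=mat, confusion_normalized=norm,
                         pr_curves=curves)


def detect_items(model, items, size: int | None = None,
                 conf: float = 0.05, nms_iou: float = 0.7
                 ) -> tuple[list[Detection], list[TruthBox]]:
    """Run the detector over dataset items; boxes come out in pixels.

    Convenience wrapper used by the CLI, tests and training-set
    evaluation: decode, threshold, class-wise NMS, and ground-truth
    conversion with matching image ids.
    """
    from .training import _to_batch

    size = size or model.cfg.input_size
    model.eval()
    dets: list[Detection] = []
    truths: list[TruthBox] = []
    for i, it in enumerate(items):
        raw = model.predict_raw(_to_batch([it], size))
        boxes, scores = model.head.decode(raw)
        img_dets = []
        for a in range(boxes.shape[1]):
            c = int(scores[0, a].argmax())
            s = float(scores[0, a, c])
            if s >= conf:
                img_dets.append(Detection(c, boxes[0, a], s, image_id=i))
        dets.extend(nms(img_dets, iou_thresh=nms_iou, conf_thresh=conf))
        truths.extend(TruthBox(a.class_id, a.corners(size, size), image_id=i)
                      for a in it.annots)
    return dets, truths


def gradcam_heatmap(model, image: np.ndarray, layer_tag: int = 9
                    ) -> np.ndarray:
    """Gradient-weighted activation map of one layer, in [0, 1].

    ``image``: (3, H, W) float array in [0, 1].  The score is the sum of
    the maximal class logits of the raw head output.
    """
    from . import nn
    x = nn.Tensor(np.asarray(image, dtype=np.float32)[None])
    was_training = model.layers[0].training
    model.eval()
    y: dict[int, nn.Tensor] = {}
    cur = x
    for i, (layer, f) in enumerate(zip(model.layers, model.froms)):
        if i == len(model.layers) - 1:
            inp = [y[j] for j in f]
        elif isinstance(f, tuple):
            inp = [y[f[0]], y[f[1]]]
        else:
            inp = cur
        cur = layer(inp)
        y[i] = cur
    raw = cur
    nc = model.head.nc
    score = None
    for r in raw:
        cls_logits = r[:, 4 * model.head.reg_max:]
        s = cls_logits.max(axis=1).sum()
        score = s if score is None else score + s
    target = y[layer_tag]
    score.backward()
    if was_training:
        model.train()
    grad = target.grad[0] if target.grad is not None \
        else np.zeros_like(target.data[0])
    act = target.data[0]
    weights = grad.mean(axis=(1, 2), keepdims=True)
    cam = np.maximum((weights * act).sum(axis=0), 0.0)
    lo, hi = cam.min(), cam.max()
    cam = (cam - lo) / (hi - lo) if hi > lo else np.full_like(cam, 0.0)
    h, w = image.shape[-2:]
    fy, fx = h // cam.shape[0], w // cam.shape[1]
    return np.repeat(np.repeat(cam, fy, axis=0), fx, axis=1)
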