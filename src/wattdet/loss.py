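"""Anchor-free detection loss: IoU box term, BCE classification,
distribution-focal regression.

Ground truth is assigned to the centre cell of the pyramid level whose
stride suits the object's size; classification is binary cross-entropy
over every location, box terms act on assigned cells only.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import DimensionError

__all__ = ["detection_loss", "assign_targets"]

LOSS_GAIN = {"box": 7.5, "cls": 0.5, "dfl": 1.5}


def _softplus(x: nn.Tensor) -> nn.Tensor:
    # stable: log(1 + exp(-|x|)) + relu(x)
    return ((-x.abs()).exp() + 1.0).log() + x.relu()


def _bce_with_logits(x: nn.Tensor, target: np.ndarray) -> nn.Tensor:
    return _softplus(x) - x * target


def _minimum(a: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
    return a - (a - b).relu()


def assign_targets(annots_per_image, shapes, strides, img_size: int,
                   num_classes: int):
    """Map normalized centre-format boxes to (scale, cell) assignments.

    Returns per-scale classification targets (N, nc, H, W) and a list of
    positive assignments ``(scale, image, cell_index, ltrb_stride_units,
    class_id)``.  The scale is the smallest stride whose distribution
    range can represent the box's extents from its centre cell.
    """
    n = len(annots_per_image)
    cls_targets = [np.zeros((n, num_classes, h, w), dtype=np.float32)
                   for h, w in shapes]
    positives = []   # (scale, img, flat_cell, ltrb, cls)
    taken = [set() for _ in shapes]
    for img, annots in enumerate(annots_per_image):
        for a in annots:
            cx, cy = a.cx * img_size, a.cy * img_size
            bw, bh = a.w * img_size, a.h * img_size
            # size-relative level choice: small boxes on the fine grid,
            # large ones on the coarse grid
            ratio = max(a.w, a.h)
            scale = 0 if ratio <= 0.25 else 1 if ratio <= 0.5 else 2
            scale = min(scale, len(strides) - 1)
            s = strides[scale]
            h, w = shapes[scale]
            gx = min(int(cx / s), w - 1)
            gy = min(int(cy / s), h - 1)
            if (img, gy, gx) in taken[scale]:
                # centre collision: fall back to a coarser level
                placed = False
                for s2 in range(scale + 1, len(strides)):
                    ss = strides[s2]
                    g2x = min(int(cx / ss), shapes[s2][1] - 1)
                    g2y = min(int(cy / ss), shapes[s2][0] - 1)
                    if (img, g2y, g2x) not in taken[s2]:
                        scale, s, (h, w) = s2, ss, shapes[s2]
                        gx, gy = g2x, g2y
                        placed = True
                        break
                if not placed:
                    continue
            taken[scale].add((img, gy, gx))
            cls_targets[scale][img, a.class_id, gy, gx] = 1.0
            ax, ay = (gx + 0.5) * s, (gy + 0.5) * s
            ltrb = np.array([ax - (cx - bw / 2), ay - (cy - bh / 2),
                             (cx + bw / 2) - ax, (cy + bh / 2) - ay],
                            dtype=np.float64) / s
            ltrb = np.clip(ltrb, 0.0, 15.0 - 1e-3)
            positives.append((scale, img, gy * w + gx, ltrb, a.class_id))
    return cls_targets, positives


def detection_loss(predictions: list[nn.Tensor], targets,
                   img_size: int, num_classes: int = 6, reg_max: int = 16,
                   strides=(8, 16, 32)) -> tuple[nn.Tensor, dict]:
    """Composite loss on raw per-scale head outputs.

    ``targets`` is a list (one entry per image) of box annotations with
    normalized ``cx, cy, w, h`` and ``class_id`` attributes.
    """
    if not targets:
        raise DimensionError("empty image batch")
    shapes = [(p.shape[2], p.shape[3]) for p in predictions]
    cls_targets, positives = assign_targets(
        targets, shapes, list(strides), img_size, num_classes)

    cls_loss = None
    for p, t in zip(predictions, cls_targets):
        logits = p[:, 4 * reg_max:]
        term = _bce_with_logits(logits, t).sum()
        cls_loss = term if cls_loss is None else cls_loss + term
    n_pos = max(len(positives), 1)
    cls_loss = cls_loss * (1.0 / n_pos)

    if not positives:
        total = cls_loss * LOSS_GAIN["cls"]
        return total, {"cls": float(cls_loss.data),
                       "box": 0.0, "dfl": 0.0,
                       "total": float(total.data)}

    box_terms, dfl_terms = [], []
    by_scale: dict[int, list] = {}
    for pos in positives:
        by_scale.setdefault(pos[0], []).append(pos)
    for s_idx, pos_list in by_scale.items():
        p = predictions[s_idx]
        n, _, h, w = p.shape
        box_logits = p[:, : 4 * reg_max].reshape(n, 4, reg_max, h * w)
        imgs = np.array([q[1] for q in pos_list])
        cells = np.array([q[2] for q in pos_list])
        tgt = np.stack([q[3] for q in pos_list])          # (P, 4)
        sel = box_logits.transpose(0, 3, 1, 2)[imgs, cells]   # (P, 4, reg_max)
        prob = sel.softmax(axis=-1)
        bins = np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max)
        dist = (prob * bins).sum(axis=-1)                 # (P, 4) l,t,r,b
        # IoU between predicted and target extents around the shared anchor
        tgt_t = nn.Tensor(tgt.astype(np.float32))
        iw = _minimum(dist[:, 2:3], tgt_t[:, 2:3]) \
            + _minimum(dist[:, 0:1], tgt_t[:, 0:1])
        ih = _minimum(dist[:, 3:4], tgt_t[:, 3:4]) \
            + _minimum(dist[:, 1:2], tgt_t[:, 1:2])
        iw = iw.clamp(0.0)
        ih = ih.clamp(0.0)
        inter = (iw * ih).reshape(-1)
        area_p = ((dist[:, 0] + dist[:, 2]) * (dist[:, 1] + dist[:, 3]))
        area_t = (tgt[:, 0] + tgt[:, 2]) * (tgt[:, 1] + tgt[:, 3])
        union = area_p + nn.Tensor(area_t.astype(np.float32)) - inter + 1e-7
        box_terms.append((1.0 - inter / union).sum())
        # distribution-focal: cross-entropy to the two adjacent bins
        tl = np.floor(tgt).astype(np.int64)
        tr = tl + 1
        wl = tr - tgt
        wr = tgt - tl
        logp = (prob + 1e-9).log()                        # (P, 4, reg_max)
        pi = np.arange(len(pos_list))[:, None]
        fi = np.arange(4)[None, :]
        dfl = -(logp[pi, fi, tl] * wl + logp[pi, fi, tr] * wr)
        dfl_terms.append(dfl.sum() * 0.25)
    box_loss = sum(box_terms[1:], box_terms[0]) * (1.0 / n_pos)
    dfl_loss = sum(dfl_terms[1:], dfl_terms[0]) * (1.0 / n_pos)
    total = (LOSS_GAIN["box"] * box_loss + LOSS_GAIN["cls"] * cls_loss
             + LOSS_GAIN["dfl"] * dfl_loss)
    return total, {"cls": float(cls_loss.data), "box": float(box_loss.data),
                   "dfl": float(dfl_loss.data), "total": float(total.data)}
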