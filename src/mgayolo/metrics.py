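"""Box geometry, non-maximum suppression and detection evaluation.

Detections are ``(n, 6)`` float arrays of ``x1, y1, x2, y2, conf, cls``
and ground truths ``(m, 5)`` arrays of ``x1, y1, x2, y2, cls``, pixel
xyxy with ``x1 < x2`` and ``y1 < y2``.

Evaluation follows the COCO-style protocol: greedy confidence-ordered
matching of detections to unmatched ground truths at each IoU threshold,
101-point interpolated average precision, AP50 at threshold 0.5 and mAP
as the mean over thresholds 0.50:0.95:0.05.  Reported per-class
precision/recall are taken at the confidence that maximises F1 on the
IoU-0.5 curve.  Classes without ground-truth labels are reported as NaN
and excluded from aggregate means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "iou", "box_iou", "nms", "match_detections", "evaluate", "EvalResult",
    "confusion", "ConfusionMatrix",
    "save_detections_coco", "load_detections_coco",
]

COCO_IOU_THRESHOLDS = np.round(np.arange(0.5, 0.96, 0.05), 2)


def _validate_boxes(b: np.ndarray) -> None:
    b = np.asarray(b, dtype=np.float64).reshape(-1, b.shape[-1])
    if b.shape[0] and (np.any(b[:, 2] <= b[:, 0]) or np.any(b[:, 3] <= b[:, 1])):
        raise ValueError("degenerate box: need x1 < x2 and y1 < y2")


def iou(a, b) -> float:
    """Intersection-over-union of two single boxes (xyxy)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    _validate_boxes(a.reshape(1, -1))
    _validate_boxes(b.reshape(1, -1))
    return float(box_iou(a.reshape(1, 4), b.reshape(1, 4))[0, 0])


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU matrix between (n,4) and (m,4) xyxy boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(dets: np.ndarray, iou_thr: float = 0.45) -> np.ndarray:
    """Greedy per-class non-maximum suppression.

    Keeps the highest-confidence box, suppresses same-class boxes with
    IoU strictly above ``iou_thr``, repeats; returns the surviving
    detections sorted by confidence descending.  Independent of input
    order among distinct confidences.
    """
    if not 0.0 <= iou_thr <= 1.0:
        raise ValueError(f"iou_thr must be in [0, 1], got {iou_thr}")
    dets = np.asarray(dets, dtype=np.float64).reshape(-1, 6)
    if dets.shape[0] == 0:
        return dets
    _validate_boxes(dets[:, :4])
    keep: list[np.ndarray] = []
    for c in np.unique(dets[:, 5]):
        d = dets[dets[:, 5] == c]
        # stable ordering: confidence desc, then x1/y1 for reproducible ties
        order = np.lexsort((d[:, 1], d[:, 0], -d[:, 4]))
        d = d[order]
        while d.shape[0]:
            keep.append(d[0])
            if d.shape[0] == 1:
                break
            ious = box_iou(d[:1, :4], d[1:, :4])[0]
            d = d[1:][ious <= iou_thr]
    out = np.stack(keep, axis=0)
    return out[np.argsort(-out[:, 4], kind="stable")]


def match_detections(det_boxes: np.ndarray, gt_boxes: np.ndarray,
                     thr: float) -> np.ndarray:
    """Confidence-ordered greedy matching within one image and class.

    ``det_boxes`` must already be sorted by confidence descending.
    Each detection claims the still-unmatched ground truth with the
    largest IoU >= ``thr``; returns a boolean TP flag per detection.
    """
    det_boxes = np.asarray(det_boxes, dtype=np.float64).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    tp = np.zeros(det_boxes.shape[0], dtype=bool)
    if gt_boxes.shape[0] == 0 or det_boxes.shape[0] == 0:
        return tp
    ious = box_iou(det_boxes, gt_boxes)
    taken = np.zeros(gt_boxes.shape[0], dtype=bool)
    for i in range(det_boxes.shape[0]):
        cand = np.where(~taken & (ious[i] >= thr))[0]
        if cand.size:
            j = cand[np.argmax(ious[i][cand])]
            taken[j] = True
            tp[i] = True
    return tp


def _ap_101(recall: np.ndarray, precision: np.ndarray) -> float:
    """101-point interpolated average precision.

    ``p(r) = max{precision at recall >= r}`` sampled at 101 evenly
    spaced recall points (0 beyond the maximum achieved recall).
    """
    if recall.size == 0:
        return 0.0
    env = np.flip(np.maximum.accumulate(np.flip(precision)))
    grid = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, grid, side="left")
    vals = np.where(idx < recall.size, env[np.minimum(idx, recall.size - 1)],
                    0.0)
    return float(vals.mean())


@dataclass
class EvalResult:
    """Per-class and aggregate detection quality."""

    class_names: list[str]
    labels: np.ndarray          # ground-truth count per class
    precision: np.ndarray       # per class, at the max-F1 operating point
    recall: np.ndarray
    ap50: np.ndarray
    ap: np.ndarray              # mean AP over the IoU threshold ladder
    iou_thresholds: np.ndarray = field(
        default_factory=lambda: COCO_IOU_THRESHOLDS.copy())

    def _agg(self, v: np.ndarray) -> float:
        ok = ~np.isnan(v)
        return float(v[ok].mean()) if ok.any() else float("nan")

    @property
    def mean_precision(self) -> float:
        return self._agg(self.precision)

    @property
    def mean_recall(self) -> float:
        return self._agg(self.recall)

    @property
    def map50(self) -> float:
        return self._agg(self.ap50)

    @property
    def map(self) -> float:
        return self._agg(self.ap)

    def to_table(self) -> str:
        rows = [f"{'Category':<12}{'Labels':>8}{'Precision':>11}{'Recall':>9}"
                f"{'AP50':>8}{'mAP':>8}"]
        rows.append(f"{'All':<12}{int(self.labels.sum()):>8}"
                    f"{self.mean_precision:>11.3f}{self.mean_recall:>9.3f}"
                    f"{self.map50:>8.3f}{self.map:>8.3f}")
        for i, name in enumerate(self.class_names):
            rows.append(f"{name:<12}{int(self.labels[i]):>8}"
                        f"{self.precision[i]:>11.3f}{self.recall[i]:>9.3f}"
                        f"{self.ap50[i]:>8.3f}{self.ap[i]:>8.3f}")
        return "\n".join(rows)

    def to_json(self) -> str:
        def clean(v):
            return [None if np.isnan(x) else round(float(x), 6) for x in v]
        return json.dumps({
            "class_names": self.class_names,
            "labels": [int(x) for x in self.labels],
            "precision": clean(self.precision), "recall": clean(self.recall),
            "ap50": clean(self.ap50), "ap": clean(self.ap),
            "mean_precision": self.mean_precision,
            "mean_recall": self.mean_recall,
            "map50": self.map50, "map": self.map}, indent=2)


def evaluate(dets_per_image, gts_per_image, nc: int | None = None,
             iou_thresholds=None, class_names=None) -> EvalResult:
    """Evaluate detections against ground truths over a set of images."""
    thrs = (COCO_IOU_THRESHOLDS if iou_thresholds is None
            else np.asarray(iou_thresholds, dtype=np.float64))
    dets = [np.asarray(d, dtype=np.float64).reshape(-1, 6) for d in dets_per_image]
    gts = [np.asarray(g, dtype=np.float64).reshape(-1, 5) for g in gts_per_image]
    if len(dets) != len(gts):
        raise ValueError("detections and ground truths must pair per image")
    if nc is None:
        ids = [d[:, 5] for d in dets] + [g[:, 4] for g in gts]
        nc = int(max((arr.max() for arr in ids if arr.size), default=-1)) + 1
    nc = max(nc, 1)
    names = (list(class_names) if class_names is not None
             else [f"class{i}" for i in range(nc)])
    labels = np.zeros(nc)
    precision = np.full(nc, np.nan)
    recall = np.full(nc, np.nan)
    ap50 = np.full(nc, np.nan)
    ap_mean = np.full(nc, np.nan)
    for c in range(nc):
        n_gt = int(sum((g[:, 4] == c).sum() for g in gts))
        labels[c] = n_gt
        if n_gt == 0:
            continue  # undefined, excluded from aggregates
        # gather (conf, image, det) for this class, confidence-descending
        recs = []
        for img, d in enumerate(dets):
            for row in d[d[:, 5] == c]:
                recs.append((row[4], img, row))
        recs.sort(key=lambda r: -r[0])
        # group by image, preserving global confidence order
        per_img_idx: dict[int, list[int]] = {}
        for k, (_, img, _) in enumerate(recs):
            per_img_idx.setdefault(img, []).append(k)
        gt_boxes = {img: g[g[:, 4] == c, :4] for img, g in enumerate(gts)}
        aps = []
        p50 = r50 = None
        for t in thrs:
            tp_flags = np.zeros(len(recs), dtype=bool)
            for img, idxs in per_img_idx.items():
                boxes = np.stack([recs[k][2][:4] for k in idxs])
                flags = match_detections(boxes, gt_boxes[img], t)
                tp_flags[np.asarray(idxs)] = flags
            tps = np.cumsum(tp_flags)
            fps = np.cumsum(~tp_flags)
            rec_curve = tps / n_gt
            pre_curve = tps / np.maximum(tps + fps, 1e-12)
            aps.append(_ap_101(rec_curve, pre_curve) if len(recs) else 0.0)
            if np.isclose(t, 0.5):
                if len(recs):
                    f1 = 2 * pre_curve * rec_curve / np.maximum(
                        pre_curve + rec_curve, 1e-12)
                    k = int(np.argmax(f1))
                    p50, r50 = float(pre_curve[k]), float(rec_curve[k])
                else:
                    p50, r50 = 0.0, 0.0
        ap_mean[c] = float(np.mean(aps))
        i50 = int(np.argmin(np.abs(thrs - 0.5)))
        ap50[c] = aps[i50]
        precision[c] = p50 if p50 is not None else 0.0
        recall[c] = r50 if r50 is not None else 0.0
    return EvalResult(names, labels, precision, recall, ap50, ap_mean,
                      thrs.copy())


@dataclass
class ConfusionMatrix:
    """(nc+1) x (nc+1) confusion counts with a trailing background
    row/column; ``matrix[pred, true]``."""

    matrix: np.ndarray
    class_names: list[str]

    def normalized(self) -> np.ndarray:
        """Column-normalised over the true condition."""
        col = self.matrix.sum(axis=0, keepdims=True)
        return np.divide(self.matrix, col, out=np.zeros_like(self.matrix),
                         where=col > 0)

    def to_tsv(self, normalized: bool = False) -> str:
        m = self.normalized() if normalized else self.matrix
        names = self.class_names + ["background"]
        lines = ["pred\\true\t" + "\t".join(names)]
        for i, name in enumerate(names):
            vals = "\t".join(f"{v:.4f}" if normalized else f"{int(v)}"
                             for v in m[i])
            lines.append(f"{name}\t{vals}")
        return "\n".join(lines) + "\n"

    def to_heatmap(self, path) -> None:
        """Render the column-normalised matrix as a heatmap image."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        m = self.normalized()
        names = self.class_names + ["background"]
        fig, ax = plt.subplots(figsize=(1.2 * len(names), 1.0 * len(names)))
        im = ax.imshow(m, cmap="Blues", vmin=0, vmax=1)
        ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
        ax.set_yticks(range(len(names)), names)
        ax.set_xlabel("true")
        ax.set_ylabel("predicted")
        for i in range(len(names)):
            for j in range(len(names)):
                if m[i, j] > 0:
                    ax.text(j, i, f"{m[i, j]:.2f}", ha="center", va="center",
                            color="white" if m[i, j] > 0.5 else "black",
                            fontsize=8)
        fig.colorbar(im, ax=ax, fraction=0.046)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def confusion(dets_per_image, gts_per_image, nc: int,
              conf_thr: float = 0.25, iou_thr: float = 0.45,
              class_names=None) -> ConfusionMatrix:
    """Detection confusion matrix (class-aware matching at one IoU)."""
    if not (0 <= conf_thr <= 1 and 0 <= iou_thr <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    names = (list(class_names) if class_names is not None
             else [f"class{i}" for i in range(nc)])
    m = np.zeros((nc + 1, nc + 1))
    for d, g in zip(dets_per_image, gts_per_image):
        d = np.asarray(d, dtype=np.float64).reshape(-1, 6)
        g = np.asarray(g, dtype=np.float64).reshape(-1, 5)
        d = d[d[:, 4] > conf_thr]
        d = d[np.argsort(-d[:, 4], kind="stable")]
        taken = np.zeros(g.shape[0], dtype=bool)
        for row in d:
            if g.shape[0]:
                ious = box_iou(row[None, :4], g[:, :4])[0]
                cand = np.where(~taken & (ious >= iou_thr))[0]
            else:
                cand = np.array([], dtype=int)
            if cand.size:
                j = cand[np.argmax(ious[cand])]
                taken[j] = True
                m[int(row[5]), int(g[j, 4])] += 1
            else:
                m[int(row[5]), nc] += 1  # predicted on background
        for j in np.where(~taken)[0]:
            m[nc, int(g[j, 4])] += 1      # missed ground truth
    return ConfusionMatrix(m, names)


# -- COCO-JSON detection dumps ------------------------------------------

def save_detections_coco(dets_per_image, image_ids, path: str | Path) -> None:
    """Write detections as a COCO results list (xywh boxes)."""
    out = []
    for img_id, d in zip(image_ids, dets_per_image):
        d = np.asarray(d, dtype=np.float64).reshape(-1, 6)
        for x1, y1, x2, y2, conf, cls in d:
            out.append({"image_id": img_id,
                        "category_id": int(cls),
                        "bbox": [round(float(x1), 2), round(float(y1), 2),
                                 round(float(x2 - x1), 2),
                                 round(float(y2 - y1), 2)],
                        "score": round(float(conf), 5)})
    Path(path).write_text(json.dumps(out, indent=1))


def load_detections_coco(path: str | Path):
    """Read a COCO results list back into per-image (n,6) arrays."""
    recs = json.loads(Path(path).read_text())
    per_img: dict = {}
    for r in recs:
        x, y, w, h = r["bbox"]
        per_img.setdefault(r["image_id"], []).append(
            [x, y, x + w, y + h, r["score"], r["category_id"]])
    return {k: np.asarray(v, dtype=np.float64) for k, v in per_img.items()}
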