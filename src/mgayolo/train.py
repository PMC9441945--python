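"""Loss, learning-rate schedule and a desk-scale SGD training loop.

The schedule is the one-cycle cosine form: with ``x`` the current epoch,

    lf(x) = ((1 - cos(pi * x / epochs)) / 2) * (lrf - 1) + 1
    lr(x) = lr0 * lf(x)

so training starts at ``lr0`` and ends at ``lr0 * lrf``.

The loss is the standard anchor-based one-stage composite: CIoU box
regression, binary cross-entropy objectness with per-level balance
weights (extended to four levels for the P6 model), and binary
cross-entropy classification.  Targets are assigned with the
multi-anchor scheme: an anchor matches when the box/anchor side ratios
lie within ``anchor_t``, and each match is replicated into the two
nearest neighbour cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .datapipe import AnnotatedImage, AugmentConfig, augment, letterbox, \
    apply_letterbox, mosaic4
from .model import DetectionModel
from .nn import Tensor

__all__ = ["TrainConfig", "LossBreakdown", "lr_at", "build_targets",
           "compute_loss", "SGD", "fit", "kmeans_anchors"]


def kmeans_anchors(wh: np.ndarray, n_levels: int, per_level: int = 3,
                   iters: int = 50, seed: int = 0) -> list[list[float]]:
    """Estimate anchors from training box sizes by k-means on (w, h).

    Runs Lloyd's algorithm with IoU-style distance ``1 - min(r,1/r)``
    aggregated over both sides, then sorts centroids by area and splits
    them across the detection levels (small anchors to fine strides).
    """
    wh = np.asarray(wh, dtype=np.float64).reshape(-1, 2)
    k = n_levels * per_level
    if wh.shape[0] < k:
        raise ValueError(f"need at least {k} boxes to fit {k} anchors")
    rng = np.random.default_rng(seed)
    centers = wh[rng.choice(wh.shape[0], k, replace=False)].copy()
    for _ in range(iters):
        r = wh[:, None] / centers[None]                  # (n, k, 2)
        sim = np.minimum(r, 1.0 / r).prod(axis=2)        # shape affinity
        assign = sim.argmax(axis=1)
        for j in range(k):
            pts = wh[assign == j]
            if pts.shape[0]:
                centers[j] = np.median(pts, axis=0)
    order = np.argsort(centers.prod(axis=1))
    centers = centers[order]
    return [centers[i * per_level:(i + 1) * per_level].round(1).flatten()
            .tolist() for i in range(n_levels)]


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults follow common one-stage
    practice; lr0/lrf are the published schedule endpoints)."""

    epochs: int = 50
    lr0: float = 0.01
    lrf: float = 0.2
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_epochs: float = 3.0
    batch: int = 8
    img_size: int = 640
    seed: int = 0
    box_gain: float = 0.05
    cls_gain: float = 0.5
    obj_gain: float = 1.0
    anchor_t: float = 4.0
    obj_iou_ratio: float = 1.0   # objectness target = (1-r) + r*IoU
    mosaic: bool = False
    augment_cfg: AugmentConfig | None = None

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0 < self.lrf <= 1:
            raise ValueError("lrf must lie in (0, 1]")


@dataclass
class LossBreakdown:
    box: float
    obj: float
    cls: float

    @property
    def total(self) -> float:
        return self.box + self.obj + self.cls


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Scheduled learning rate at an epoch boundary."""
    if cfg.epochs <= 0:
        raise ValueError("epochs must be positive")
    if not 0 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    lf = ((1 - math.cos(math.pi * epoch / cfg.epochs)) / 2) * (cfg.lrf - 1) + 1
    return cfg.lr0 * lf


# -- target assignment ---------------------------------------------------

def build_targets(pred_shapes, targets: np.ndarray, model: DetectionModel,
                  anchor_t: float = 4.0):
    """Assign ground-truth boxes to anchors, cells and levels.

    ``targets`` is ``(n, 6)``: image index, class, cx, cy, w, h in input
    pixels.  Returns, per detection level, index arrays ``(b, a, gj, gi)``
    plus regression targets ``txy`` (cell-relative), ``twh`` and anchor
    sizes in grid units, and the class ids.
    """
    det = model.detect
    out = []
    g = 0.5  # neighbour-cell reach
    offsets = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1]], np.float64)
    for i in range(det.nl):
        stride = float(det.stride[i])
        anchors = det.anchors[i] / stride            # grid units
        ny, nx = pred_shapes[i][2], pred_shapes[i][3]
        if targets.shape[0] == 0:
            out.append(tuple(np.zeros(0, np.int64) for _ in range(4))
                       + (np.zeros((0, 2)), np.zeros((0, 2)),
                          np.zeros((0, 2)), np.zeros(0, np.int64)))
            continue
        t = targets.astype(np.float64).copy()
        t[:, 2:] /= stride
        # anchor-ratio filter, replicated per anchor
        rows = []
        for a_idx, (aw, ah) in enumerate(anchors):
            r = t[:, 4:6] / (aw, ah)
            keep = np.maximum(r, 1.0 / r).max(axis=1) < anchor_t
            tk = t[keep]
            if tk.shape[0]:
                rows.append(np.concatenate(
                    [tk, np.full((tk.shape[0], 1), a_idx)], axis=1))
        if not rows:
            out.append(tuple(np.zeros(0, np.int64) for _ in range(4))
                       + (np.zeros((0, 2)), np.zeros((0, 2)),
                          np.zeros((0, 2)), np.zeros(0, np.int64)))
            continue
        t = np.concatenate(rows, axis=0)
        # neighbour cells: centre plus the two closest sides
        gxy = t[:, 2:4]
        gxi = np.array([nx, ny]) - gxy
        j, k = ((gxy % 1 < g) & (gxy > 1)).T
        l, m = ((gxi % 1 < g) & (gxi > 1)).T
        mask = np.stack([np.ones_like(j), j, k, l, m])
        t = np.tile(t, (5, 1, 1))[mask]
        off = (np.zeros_like(np.tile(gxy, (5, 1, 1))) +
               offsets[:, None] * g)[mask]
        gij = (t[:, 2:4] - off).astype(np.int64)
        gi = gij[:, 0].clip(0, nx - 1)
        gj = gij[:, 1].clip(0, ny - 1)
        b = t[:, 0].astype(np.int64)
        a = t[:, 6].astype(np.int64)
        txy = t[:, 2:4] - gij
        twh = t[:, 4:6]
        out.append((b, a, gj, gi, txy, twh, anchors[a], t[:, 1].astype(np.int64)))
    return out


# -- loss ----------------------------------------------------------------

def _bce_with_logits(x: Tensor, z: np.ndarray | Tensor) -> Tensor:
    """Elementwise stable binary cross-entropy on logits."""
    zdata = z if isinstance(z, Tensor) else Tensor(np.asarray(z, np.float32))
    return (1.0 - zdata) * x + (-x).softplus()


def _ciou(pxy: Tensor, pwh: Tensor, txy: np.ndarray, twh: np.ndarray) -> Tensor:
    """Complete IoU between predicted and target boxes (cxcywh, grid units)."""
    eps = 1e-7
    tx, ty = Tensor(txy[:, 0]), Tensor(txy[:, 1])
    tw, th = Tensor(twh[:, 0]), Tensor(twh[:, 1])
    px, py = pxy[:, 0], pxy[:, 1]
    pw, ph = pwh[:, 0], pwh[:, 1]
    p_x1, p_x2 = px - pw * 0.5, px + pw * 0.5
    p_y1, p_y2 = py - ph * 0.5, py + ph * 0.5
    t_x1, t_x2 = tx - tw * 0.5, tx + tw * 0.5
    t_y1, t_y2 = ty - th * 0.5, ty + th * 0.5
    iw = (p_x2.minimum(t_x2) - p_x1.maximum(t_x1)).clamp(0.0)
    ih = (p_y2.minimum(t_y2) - p_y1.maximum(t_y1)).clamp(0.0)
    inter = iw * ih
    union = pw * ph + tw * th - inter + eps
    iou = inter / union
    cw = p_x2.maximum(t_x2) - p_x1.minimum(t_x1)
    ch = p_y2.maximum(t_y2) - p_y1.minimum(t_y1)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((tx - px) ** 2.0 + (ty - py) ** 2.0) * 0.25 * 4.0
    v = (4.0 / math.pi ** 2) * ((tw / th).arctan() - (pw / ph).arctan()) ** 2.0
    with nn.no_grad():
        alpha = (v.detach() / (1.0 - iou.detach().data + v.data + eps)).data
    return iou - rho2 / c2 - Tensor(alpha) * v


def compute_loss(preds, targets: np.ndarray, model: DetectionModel,
                 cfg: TrainConfig | None = None):
    """Composite detection loss.

    Returns ``(total, LossBreakdown)`` where ``total`` is the scalar
    Tensor to differentiate and the breakdown holds gain-weighted floats.
    Aborts with a diagnostic if any component goes non-finite.
    """
    cfg = cfg or TrainConfig()
    det = model.detect
    nl, nc = det.nl, det.nc
    balance = [4.0, 1.0, 0.4] if nl == 3 else [4.0, 1.0, 0.25, 0.06]
    shapes = [p.shape for p in preds]
    assigned = build_targets(shapes, targets, model, cfg.anchor_t)
    img_size = shapes[0][3] * int(det.stride[0])
    lbox = Tensor(0.0)
    lobj = Tensor(0.0)
    lcls = Tensor(0.0)
    for i, (p, (b, a, gj, gi, txy, twh, anch, tcls)) in enumerate(
            zip(preds, assigned)):
        tobj = np.zeros(p.shape[:4], dtype=np.float32)
        if b.shape[0]:
            ps = p[b, a, gj, gi]                 # (m, no)
            pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2.0 * Tensor(anch)
            iou = _ciou(pxy, pwh, txy, twh)
            lbox = lbox + (1.0 - iou).mean()
            r = cfg.obj_iou_ratio
            tobj[b, a, gj, gi] = (1.0 - r) + r * np.clip(iou.data, 0, None)
            if nc > 1:
                z = np.zeros((b.shape[0], nc), np.float32)
                z[np.arange(b.shape[0]), tcls] = 1.0
                lcls = lcls + _bce_with_logits(ps[:, 5:], z).mean()
        lobj = lobj + _bce_with_logits(p[..., 4], tobj).mean() * balance[i]
    box_g = cfg.box_gain * 3.0 / nl
    obj_g = cfg.obj_gain * (img_size / 640.0) ** 2 * 3.0 / nl
    cls_g = cfg.cls_gain * nc / 80.0 * 3.0 / nl
    total = lbox * box_g + lobj * obj_g + lcls * cls_g
    bd = LossBreakdown(float(lbox.data) * box_g, float(lobj.data) * obj_g,
                       float(lcls.data) * cls_g)
    if not math.isfinite(bd.total):
        raise FloatingPointError(
            f"non-finite loss: box={bd.box} obj={bd.obj} cls={bd.cls}")
    return total, bd


# -- optimiser -----------------------------------------------------------

class SGD:
    """Stochastic gradient descent with momentum; weight decay applied to
    convolution weights only (biases and norm parameters excluded)."""

    def __init__(self, params, lr: float, momentum: float = 0.937,
                 weight_decay: float = 5e-4):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim == 4:
                g = g + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data = p.data - self.lr * buf

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# -- training loop -------------------------------------------------------

def _prepare(item: AnnotatedImage, img_size: int, stride: int):
    img, scale, pad = letterbox(item.image, img_size, stride)
    boxes = apply_letterbox(item.boxes, scale, pad)
    x = img.astype(np.float32).transpose(2, 0, 1) / 255.0
    return x, boxes, item.class_ids


def recalibrate_bn(model: DetectionModel, batches: list[np.ndarray]) -> None:
    """Replace batch-norm running statistics with the average batch
    statistics over the given list of input batches (useful after short
    training runs, where the exponential running average still lags)."""
    from .nn.layers import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [(bn.momentum, bn.running_mean.copy(), bn.running_var.copy())
             for bn in bns]
    for bn in bns:
        bn.running_mean[:] = 0.0
        bn.running_var[:] = 0.0
    model.train()
    with nn.no_grad():
        for k, xb in enumerate(batches, 1):
            for bn in bns:
                bn.momentum = 1.0 / k     # running mean of batch stats
            model.forward(Tensor(xb))
    for bn, (mom, _, _) in zip(bns, saved):
        bn.momentum = mom
    model.eval()


def fit(model: DetectionModel, dataset: list[AnnotatedImage],
        cfg: TrainConfig, val_hook=None):
    """Train with SGD + the cosine schedule; returns a per-epoch log.

    The log records the scheduled learning rate and the loss breakdown.
    ``val_hook(model, epoch)`` runs after each epoch when given (e.g. a
    held-out evaluation); its return value is stored in the log.  Fixed
    seed + fixed data imply a reproducible loss trajectory.  If the loss
    diverges (total > 1e4 or non-finite) the last epoch-end checkpoint
    is restored and training stops early.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    model.init_detect_biases(cfg.img_size)
    opt = SGD(model.parameters(), lr_at(0, cfg), cfg.momentum,
              cfg.weight_decay)
    stride = model.max_stride
    prepared = [_prepare(it, cfg.img_size, stride) for it in dataset]
    recal_batches = [np.stack([p[0] for p in prepared[i:i + cfg.batch]])
                     for i in range(0, min(len(prepared), 4 * cfg.batch),
                                    cfg.batch)]
    nb = max(1, math.ceil(len(prepared) / cfg.batch))
    warmup_iters = max(int(cfg.warmup_epochs * nb), 1) \
        if cfg.warmup_epochs > 0 else 0
    log: list[dict] = []
    last_good = model.state_dict()
    it_count = 0
    for epoch in range(cfg.epochs):
        base_lr = lr_at(epoch, cfg)
        model.train()
        order = rng.permutation(len(prepared))
        sums = np.zeros(3)
        for start in range(0, len(prepared), cfg.batch):
            idx = order[start:start + cfg.batch]
            xs, tgt = [], []
            for bi, j in enumerate(idx):
                if cfg.mosaic:
                    picks = [dataset[j]] + [dataset[k] for k in
                                            rng.integers(0, len(dataset), 3)]
                    item = mosaic4(picks, cfg.img_size // 2, rng,
                                   cfg.augment_cfg)
                    x = item.image.astype(np.float32).transpose(2, 0, 1) / 255
                    boxes, cids = item.boxes, item.class_ids
                    xs.append(x)
                    for (x1, y1, x2, y2), c in zip(boxes, cids):
                        tgt.append([bi, c, (x1 + x2) / 2, (y1 + y2) / 2,
                                    max(x2 - x1, 2.0), max(y2 - y1, 2.0)])
                    continue
                x, boxes, cids = prepared[j]
                if cfg.augment_cfg is not None:
                    img = (x.transpose(1, 2, 0) * 255).astype(np.uint8)
                    item = augment(AnnotatedImage(img, boxes, cids),
                                   cfg.augment_cfg, rng)
                    x = item.image.astype(np.float32).transpose(2, 0, 1) / 255
                    boxes, cids = item.boxes, item.class_ids
                xs.append(x)
                for (x1, y1, x2, y2), c in zip(boxes, cids):
                    tgt.append([bi, c, (x1 + x2) / 2, (y1 + y2) / 2,
                                max(x2 - x1, 2.0), max(y2 - y1, 2.0)])
            xb = np.stack(xs)
            targets = (np.asarray(tgt, np.float64) if tgt
                       else np.zeros((0, 6)))
            if warmup_iters and it_count < warmup_iters:
                opt.lr = base_lr * (it_count + 1) / warmup_iters
            else:
                opt.lr = base_lr
            preds = model.forward(Tensor(xb))
            total, bd = compute_loss(preds, targets, model, cfg)
            opt.zero_grad()
            total.backward(np.float32(len(idx)))  # sum-over-batch scaling
            opt.step()
            sums += (bd.box, bd.obj, bd.cls)
            it_count += 1
        mean = sums / nb
        entry = {"epoch": epoch, "lr": base_lr,
                 "box": float(mean[0]), "obj": float(mean[1]),
                 "cls": float(mean[2]), "total": float(mean.sum())}
        if not math.isfinite(entry["total"]) or entry["total"] > 1e4:
            model.load_state_dict(last_good)
            entry["diverged"] = True
            log.append(entry)
            break
        last_good = model.state_dict()
        if val_hook is not None:
            recalibrate_bn(model, recal_batches)
            entry["val"] = val_hook(model, epoch)
            model.train()
        log.append(entry)
    recalibrate_bn(model, recal_batches)
    model.eval()
    return log
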