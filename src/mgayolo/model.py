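"""Config-driven detector assembly, forward inference and profiling.

A model is described by a declarative layer list (YAML or dict): each row
is ``[from, repeats, block, args]`` where *from* indexes previously built
layers (-1 = previous).  Channel arguments are scaled by
``width_multiple`` (rounded up to a multiple of 8) and repeats by
``depth_multiple``, the familiar small/medium/large scaling scheme of
one-stage detectors.  Bundled named configs cover the full ablation
ladder from the plain baseline to the four-head ghost/C3MB/CBAM/GELU
model (see :data:`VARIANTS`).

The profiler reports trainable parameter counts and multiply–accumulate
counts per layer; GFLOPs are reported as ``2 x MACs / 1e9`` for one
forward pass.  Convolution/linear layers are counted by the product
``h' * w' * k * k * (c/groups) * n``; batch norm is counted at two
MAC-equivalents per element (rescale + shift), the convention of the
profilers these reference figures are customarily produced with.
Pooling and activations are excluded.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import blocks, nn
from .blocks import (C3, C3MB, SPP, C3Ghost, Concat, ConfigError, ConvBnAct,
                     Detect, Focus, GhostConv, ShapeError)
from .nn import Tensor

__all__ = [
    "VARIANTS", "load_config", "build_model", "DetectionModel",
    "ProfileReport", "count_parameters", "estimate_flops",
    "decode_predictions", "predict",
]

#: Bundled config names, in ablation-ladder order.
VARIANTS = (
    "yolov5s",
    "yolov5s-ghost",
    "yolov5s-ghost-c3mb",
    "yolov5s-ghost-c3mb-se",
    "yolov5s-ghost-c3mb-ca",
    "yolov5s-ghost-c3mb-cbam",
    "yolov5s-ghost-c3mb-cbam-head",
    "mga-yolo",
)

_BLOCK_MAP = {
    "Focus": Focus, "Conv": ConvBnAct, "C3": C3, "SPP": SPP,
    "GhostConv": GhostConv, "C3Ghost": C3Ghost, "C3MB": C3MB,
    "Upsample": nn.Upsample, "nn.Upsample": nn.Upsample,
    "Concat": Concat, "Detect": Detect,
}


def make_divisible(x: float, divisor: int = 8) -> int:
    return int(math.ceil(x / divisor) * divisor)


def load_config(name_or_path: str | Path) -> dict:
    """Load a bundled config by name or an arbitrary YAML file by path."""
    p = Path(name_or_path)
    if p.suffix in {".yaml", ".yml"} and p.exists():
        text = p.read_text()
    elif str(name_or_path) in VARIANTS:
        ref = importlib.resources.files("mgayolo.configs") / f"{name_or_path}.yaml"
        text = ref.read_text()
    elif p.exists():
        text = p.read_text()
    else:
        raise FileNotFoundError(
            f"no bundled config or file named {name_or_path!r}; "
            f"bundled: {', '.join(VARIANTS)}")
    cfg = yaml.safe_load(text)
    for key in ("nc", "depth_multiple", "width_multiple", "anchors",
                "backbone", "head"):
        if key not in cfg:
            raise ConfigError(f"model config missing required key {key!r}")
    return cfg


class _Layer:
    """Bookkeeping wrapper: a built block plus its graph metadata."""

    __slots__ = ("module", "f", "i", "kind", "c2")

    def __init__(self, module, f, i, kind, c2):
        self.module, self.f, self.i, self.kind, self.c2 = module, f, i, kind, c2


class DetectionModel(nn.Module):
    """A built detector: layer graph, skip-connection save list, strides."""

    def __init__(self, cfg: dict | str | Path, nc: int | None = None,
                 seed: int = 0):
        super().__init__()
        if not isinstance(cfg, dict):
            cfg = load_config(cfg)
        self.cfg = cfg = dict(cfg)
        if nc is not None:
            cfg["nc"] = nc
        self.nc = int(cfg["nc"])
        self.variant_name = cfg.get("variant", "custom")
        nn.seed_all(seed)
        self.layers, self.save = self._build(cfg)
        for i, lyr in enumerate(self.layers):
            self._modules[f"layer{i}"] = lyr.module
        # alias only (already registered as the last layer module)
        object.__setattr__(self, "detect", self.layers[-1].module)
        self.stride = self._infer_strides()
        self.detect.stride = self.stride
        self._init_weights()
        self.eval()

    # -- construction ---------------------------------------------------
    def _build(self, cfg: dict):
        gd = float(cfg["depth_multiple"])
        gw = float(cfg["width_multiple"])
        act = cfg.get("activation", "silu")
        mb_e = float(cfg.get("mb_expansion", 6))
        mb_attn = cfg.get("mb_attention", "cbam")
        ch: list[int] = []  # ch[j] = output channels of layer j
        layers: list[_Layer] = []
        save: set[int] = set()

        def resolve(x: int, i: int) -> int:
            return 3 if i == 0 else ch[x if x >= 0 else i + x]

        for i, (f, n, kind, args) in enumerate(
                list(cfg["backbone"]) + list(cfg["head"])):
            if kind not in _BLOCK_MAP:
                raise ConfigError(f"unknown block kind {kind!r} at layer {i}")
            fs = f if isinstance(f, list) else [f]
            for x in fs:
                j = x if x >= 0 else i + x
                if not (0 <= j <= i - 1) and not (x == -1 and i == 0):
                    raise ConfigError(f"layer {i}: dangling from-index {x}")
            n_ = max(round(n * gd), 1) if n > 1 else n
            c1 = resolve(fs[0], i)
            if kind in ("Conv", "GhostConv", "Focus", "SPP", "C3", "C3Ghost",
                        "C3MB"):
                c2 = make_divisible(args[0] * gw, 8)
            elif kind == "Concat":
                c2 = sum(resolve(x, i) for x in fs)
            else:
                c2 = c1
            if kind == "Focus":
                m = Focus(c1, c2, args[1] if len(args) > 1 else 3, act=act)
            elif kind == "Conv":
                m = ConvBnAct(c1, c2, args[1], args[2], act=act)
            elif kind == "GhostConv":
                m = GhostConv(c1, c2, args[1], args[2], act=act)
            elif kind == "C3":
                sc = args[1] if len(args) > 1 else True
                m = C3(c1, c2, n_, sc, act=act)
            elif kind == "C3Ghost":
                sc = args[1] if len(args) > 1 else True
                m = C3Ghost(c1, c2, n_, sc, act=act)
            elif kind == "C3MB":
                m = C3MB(c1, c2, n_, expansion=mb_e, attention=mb_attn, act=act)
            elif kind == "SPP":
                m = SPP(c1, c2, tuple(args[1]), act=act)
            elif kind in ("Upsample", "nn.Upsample"):
                m = nn.Upsample(2)
            elif kind == "Concat":
                m = Concat(1)
            else:  # Detect
                anchors = cfg["anchors"]
                in_ch = [resolve(x, i) for x in fs]
                m = Detect(self.nc, anchors, in_ch)
            layers.append(_Layer(m, f, i, kind, c2))
            ch.append(c2)
            for x in fs:
                if x != -1:
                    save.add(x if x >= 0 else i + x)
        return layers, sorted(save)

    def _infer_strides(self) -> np.ndarray:
        size = 128  # divisible by every stride in both 3- and 4-head models
        with nn.no_grad():
            self.eval()
            preds = self._forward(np.zeros((1, 3, size, size), np.float32))
        return np.array([size / p.shape[2] for p in preds], dtype=np.float32)

    def _init_weights(self) -> None:
        self.init_detect_biases(640)

    def init_detect_biases(self, img_size: int) -> None:
        """Set objectness/class prior biases for the expected grid sizes
        (roughly 8 objects per image, balanced classes)."""
        for conv, s in zip(self.detect.m, self.detect.stride):
            b = conv.bias.data.reshape(self.detect.na, -1)
            b[:, 4] = math.log(8.0 / (img_size / s) ** 2)
            b[:, 5:] = math.log(0.6 / (self.nc - 0.99))
            conv.bias.data = b.reshape(-1)

    # -- inference ------------------------------------------------------
    @property
    def max_stride(self) -> int:
        return int(self.stride.max())

    def _forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        outputs: dict[int, Tensor] = {}
        y = x
        for lyr in self.layers[:-1]:
            if lyr.f == -1:
                inp = y
            elif isinstance(lyr.f, list):
                inp = [y if j == -1 else outputs[j if j >= 0 else lyr.i + j]
                       for j in lyr.f]
            else:
                inp = outputs[lyr.f if lyr.f >= 0 else lyr.i + lyr.f]
            y = lyr.module(inp)
            if lyr.i in self.save:
                outputs[lyr.i] = y
        det = self.layers[-1]
        heads = [y if j == -1 else outputs[j] for j in det.f]
        return det.module(heads)

    def forward(self, x):
        """Run the detector; returns one raw map per head,
        shape (batch, anchors, ny, nx, nc + 5)."""
        arr = x.data if isinstance(x, Tensor) else np.asarray(x)
        h, w = arr.shape[2], arr.shape[3]
        ms = self.max_stride
        if h % ms or w % ms:
            raise ShapeError(
                f"input {h}x{w} not divisible by the largest stride {ms}")
        return self._forward(x)


def build_model(cfg: dict | str | Path, nc: int | None = None,
                seed: int = 0) -> DetectionModel:
    """Build a detector from a bundled config name, YAML path or dict."""
    return DetectionModel(cfg, nc=nc, seed=seed)


# -- profiling -----------------------------------------------------------

@dataclass
class ProfileReport:
    """Parameter and multiply–accumulate census of a built model."""

    variant: str
    img_size: int
    total_params: int
    total_macs: int
    per_layer: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def gmacs(self) -> float:
        return self.total_macs / 1e9

    @property
    def gflops(self) -> float:
        return 2.0 * self.total_macs / 1e9

    def to_tsv(self) -> str:
        lines = ["layer\tparams\tmacs"]
        lines += [f"{n}\t{p}\t{m}" for n, p, m in self.per_layer]
        lines.append(f"TOTAL\t{self.total_params}\t{self.total_macs}")
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        w = max((len(n) for n, _, _ in self.per_layer), default=10) + 2
        rows = [f"{'layer':<{w}}{'params':>12}{'MACs':>16}"]
        rows += [f"{n:<{w}}{p:>12,}{m:>16,}" for n, p, m in self.per_layer]
        rows.append("-" * (w + 28))
        rows.append(f"{'total':<{w}}{self.total_params:>12,}{self.total_macs:>16,}")
        rows.append(f"{self.variant} @ {self.img_size}: "
                    f"{self.total_params:,} params, {self.gmacs:.2f} GMACs, "
                    f"{self.gflops:.1f} GFLOPs")
        return "\n".join(rows)


def count_parameters(model: DetectionModel) -> int:
    """Total trainable elements: conv weights/biases + batch-norm affine."""
    return model.num_parameters()


def estimate_flops(model: DetectionModel, img_size: int = 640) -> ProfileReport:
    """Profile parameters and MACs at ``img_size``.

    Per-module MAC counts are exact polynomials of degree <= 2 in the
    input side length (quadratic for ordinary convolutions, linear for
    the 1-D encodings of coordinate attention, constant for convolutions
    on globally pooled maps).  Three probe forwards at small stride
    multiples determine each polynomial exactly, which is then evaluated
    at ``img_size`` — identical to profiling a full-size forward, at a
    fraction of the cost.
    """
    ms = model.max_stride
    if img_size % ms:
        raise ShapeError(f"img_size {img_size} not divisible by stride {ms}")
    model.eval()
    counts: list[dict[int, int]] = []
    mods: dict[int, nn.Module] = {}
    for k in (1, 2, 3):
        with nn.no_grad(), nn.profile_macs() as prof:
            model.forward(np.zeros((1, 3, k * ms, k * ms), np.float32))
        d: dict[int, int] = {}
        for mod, macs in prof:
            d[id(mod)] = d.get(id(mod), 0) + macs
            mods[id(mod)] = mod
        counts.append(d)
    n = img_size // ms
    mod_macs: dict[int, int] = {}
    for key in counts[0]:
        f1, f2, f3 = (c.get(key, 0) for c in counts)
        d2 = f3 - 2 * f2 + f1  # exact second difference (twice the quad term)
        mod_macs[key] = f1 + (n - 1) * (f2 - f1) + (n - 1) * (n - 2) * d2 // 2
    per_layer = []
    total_macs = 0
    for lyr in model.layers:
        macs = sum(mod_macs.get(id(m), 0) for m in lyr.module.modules()
                   if isinstance(m, (nn.Conv2d, nn.BatchNorm2d)))
        total_macs += macs
        per_layer.append((f"{lyr.i}:{lyr.kind}", lyr.module.num_parameters(), macs))
    return ProfileReport(model.variant_name, img_size,
                         count_parameters(model), total_macs, per_layer)


def _merge(prof):
    acc: dict[int, list] = {}
    for mod, macs in prof:
        if id(mod) in acc:
            acc[id(mod)][1] += macs
        else:
            acc[id(mod)] = [mod, macs]
    return [(m, v) for m, v in acc.values()]


# -- decoding ------------------------------------------------------------

def decode_predictions(preds, anchors: np.ndarray, strides: np.ndarray,
                       conf_thr: float = 0.25, img_size: int | None = None):
    """Turn raw head maps into pixel-space detections.

    Per cell and anchor: ``xy = (2*sigma(t_xy) - 0.5 + grid) * stride``,
    ``wh = (2*sigma(t_wh))^2 * anchor``; confidence = objectness x class
    probability (both sigmoided); detections with confidence strictly
    above ``conf_thr`` are returned as ``(n, 6)`` arrays of
    ``x1, y1, x2, y2, conf, class`` per image, clipped to the canvas.
    """
    from scipy.special import expit

    if len(preds) != len(anchors) or len(preds) != len(strides):
        raise ConfigError("anchor/stride census does not match head count")
    batch = preds[0].shape[0]
    out = [[] for _ in range(batch)]
    for p, anc, s in zip(preds, anchors, strides):
        a = p.data if isinstance(p, Tensor) else np.asarray(p)
        n, na, ny, nx, no = a.shape
        sig = expit(a)
        gy, gx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        grid = np.stack([gx, gy], axis=-1)[None, None]          # (1,1,ny,nx,2)
        xy = (2.0 * sig[..., 0:2] - 0.5 + grid) * s
        wh = (2.0 * sig[..., 2:4]) ** 2 * anc.reshape(1, na, 1, 1, 2)
        conf_all = sig[..., 4:5] * sig[..., 5:]
        cls = conf_all.argmax(axis=-1)
        conf = conf_all.max(axis=-1)
        keep = conf > conf_thr
        for b in range(batch):
            kb = keep[b]
            if not kb.any():
                continue
            xyb, whb = xy[b][kb], wh[b][kb]
            boxes = np.concatenate([xyb - whb / 2, xyb + whb / 2], axis=1)
            if img_size is not None:
                boxes = boxes.clip(0, img_size)
            ok = (boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])
            if not ok.any():
                continue
            out[b].append(np.concatenate(
                [boxes[ok], conf[b][kb][ok][:, None],
                 cls[b][kb][ok][:, None]], axis=1))
    return [np.concatenate(o, axis=0) if o else np.zeros((0, 6), np.float32)
            for o in out]


def predict(model: DetectionModel, images, conf_thr: float = 0.25,
            iou_thr: float = 0.45, img_size: int = 640):
    """End-to-end inference on a list of HxWx3 uint8 images.

    Each image is letterboxed to ``img_size``, passed through the model
    in eval mode, decoded, suppressed with per-class NMS, and the boxes
    are mapped back to the original pixel frame.  Returns one ``(n, 6)``
    array of ``x1, y1, x2, y2, conf, cls`` per image.
    """
    from .datapipe import letterbox, invert_letterbox
    from .metrics import nms

    model.eval()
    ms = model.max_stride
    out = []
    for img in images:
        img = np.asarray(img)
        padded, scale, pad = letterbox(img, img_size, ms)
        x = padded.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
        with nn.no_grad():
            preds = model.forward(Tensor(x))
        dets = decode_predictions(preds, model.detect.anchors,
                                  model.detect.stride, conf_thr,
                                  img_size=max(padded.shape[:2]))[0]
        if dets.shape[0]:
            dets = nms(dets, iou_thr)
            dets[:, :4] = invert_letterbox(dets[:, :4], scale, pad)
            h, w = img.shape[:2]
            dets[:, [0, 2]] = dets[:, [0, 2]].clip(0, w)
            dets[:, [1, 3]] = dets[:, [1, 3]].clip(0, h)
        out.append(dets)
    return out
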