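"""Seeded generator of synthetic multi-leaf scenes with ground truth.

Scenes emulate the structure of field photographs of apple foliage: a
cluttered soil/vegetation background and several elliptical leaves, each
carrying the procedural lesion phenotype of its class —

* ``healthy``   — uniform green blade, no lesions;
* ``rust``      — small saturated orange-yellow spots;
* ``scab``      — dark olive-green blotches strung along the mid-vein;
* ``black rot`` — larger round spots of concentric brown/tan rings
  ("frog-eye" pattern).

Every leaf gets one tight bounding box and one class id.  The four
phenotypes are deliberately colour-separable so that desk-scale training
runs can reach high detection quality quickly; the generator is a stand-in
for real orchard imagery, not a model of it.  All randomness flows
through one :class:`numpy.random.Generator`, so a fixed seed reproduces
scenes byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .datapipe import CLASS_NAMES, AnnotatedImage, write_annotations

__all__ = ["SceneSpec", "generate_scene", "generate_dataset"]


@dataclass
class SceneSpec:
    """Knobs of the procedural scene model."""

    canvas: int = 640
    n_leaves: tuple[int, int] = (2, 4)       # inclusive range per scene
    background_clutter: float = 0.5          # 0 = flat, 1 = busy
    min_leaf_frac: float = 0.22              # leaf semi-axis vs canvas
    max_leaf_frac: float = 0.40
    max_box_overlap: float = 0.5             # visible fraction >= 1 - this
    seed: int = 0

    def __post_init__(self):
        if self.canvas < 64:
            raise ValueError("canvas must be at least 64 px")
        if not 0 <= self.background_clutter <= 1:
            raise ValueError("background_clutter must lie in [0, 1]")
        lo, hi = self.n_leaves
        if lo < 1 or hi < lo:
            raise ValueError("n_leaves must be a non-empty positive range")


# per-class style: base leaf green is common; lesion colours and blade
# tints are chosen so the TINTED blade colours (0.5 green + 0.5 tint)
# land far apart: healthy = bright green, rust = golden orange,
# scab = very dark olive, black rot = blue-purple
_LEAF_GREENS = [(55, 125, 40), (70, 140, 48), (48, 112, 36)]
_RUST_ORANGE = [(250, 165, 10), (255, 195, 20), (240, 140, 5)]
_SCAB_OLIVE = [(50, 50, 5), (38, 42, 0), (62, 58, 12)]
_ROT_RINGS = [(40, 8, 60), (215, 160, 230), (145, 15, 170)]  # purple frog-eye
_TINTS = {"healthy": None, "rust": (255, 125, 0),
          "scab": (35, 35, 0), "black rot": (145, 15, 170)}
# background: desaturated gray/straw tones, far from any blade colour
_SOIL = [(150, 145, 138), (128, 124, 118), (168, 160, 150), (142, 138, 126)]


def _background(canvas: int, clutter: float,
                rng: np.random.Generator) -> np.ndarray:
    """Low-frequency soil-toned noise plus optional clutter blobs."""
    coarse = rng.integers(0, 255, (8, 8, 3), dtype=np.uint8)
    base = np.asarray(Image.fromarray(coarse).resize(
        (canvas, canvas), Image.BILINEAR)).astype(np.float32)
    soil = np.array(_SOIL[int(rng.integers(len(_SOIL)))], np.float32)
    img = (0.65 * soil + 0.35 * base).clip(0, 255).astype(np.uint8)
    pil = Image.fromarray(img)
    draw = ImageDraw.Draw(pil)
    n_blobs = int(clutter * 40)
    for _ in range(n_blobs):
        x, y = rng.integers(0, canvas, 2)
        r = int(rng.integers(canvas // 40, canvas // 8))
        col = tuple(int(c) for c in
                    np.array(_SOIL[int(rng.integers(len(_SOIL)))])
                    + rng.integers(-25, 25, 3))
        col = tuple(int(np.clip(c, 0, 255)) for c in col)
        if rng.random() < 0.5:
            draw.ellipse([x - r, y - r, x + r, y + r], fill=col)
        else:
            x2, y2 = x + rng.integers(-r, r + 1), y + rng.integers(-r, r + 1)
            draw.line([x, y, int(x2), int(y2)], fill=col,
                      width=max(1, r // 6))
    return np.asarray(pil)


def _leaf_polygon(cx: float, cy: float, a: float, b: float, theta: float,
                  n: int = 48) -> np.ndarray:
    """Rotated ellipse outline, slightly pinched at the tip (leaf-ish)."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    # pinch one end to suggest a leaf tip
    rx = a * (1 - 0.15 * np.cos(t) ** 2)
    x = rx * np.cos(t)
    y = b * np.sin(t)
    ct, st = np.cos(theta), np.sin(theta)
    return np.stack([cx + x * ct - y * st, cy + x * st + y * ct], axis=1)


def _draw_lesions(draw: ImageDraw.ImageDraw, cls: int, cx: float, cy: float,
                  a: float, b: float, theta: float,
                  rng: np.random.Generator) -> None:
    ct, st = np.cos(theta), np.sin(theta)

    def to_canvas(u, v):  # ellipse frame -> canvas
        return cx + u * ct - v * st, cy + u * st + v * ct

    name = CLASS_NAMES[cls]
    if name == "healthy":
        return
    if name == "rust":
        for _ in range(int(rng.integers(8, 16))):
            u = rng.uniform(-0.75, 0.75) * a
            v = rng.uniform(-0.75, 0.75) * b * np.sqrt(
                max(0.0, 1 - (u / a) ** 2))
            x, y = to_canvas(u, v)
            r = rng.uniform(0.03, 0.07) * min(a, b)
            col = _RUST_ORANGE[int(rng.integers(len(_RUST_ORANGE)))]
            draw.ellipse([x - r, y - r, x + r, y + r], fill=col)
    elif name == "scab":
        for _ in range(int(rng.integers(4, 8))):
            u = rng.uniform(-0.8, 0.8) * a          # along the mid-vein
            v = rng.uniform(-0.18, 0.18) * b
            x, y = to_canvas(u, v)
            r1 = rng.uniform(0.10, 0.20) * min(a, b)
            r2 = r1 * rng.uniform(0.6, 1.0)
            col = _SCAB_OLIVE[int(rng.integers(len(_SCAB_OLIVE)))]
            draw.ellipse([x - r1, y - r2, x + r1, y + r2], fill=col)
    else:  # black rot: concentric "frog eye" rings
        for _ in range(int(rng.integers(3, 6))):
            u = rng.uniform(-0.6, 0.6) * a
            v = rng.uniform(-0.6, 0.6) * b * np.sqrt(
                max(0.0, 1 - (u / a) ** 2))
            x, y = to_canvas(u, v)
            r = rng.uniform(0.12, 0.22) * min(a, b)
            dark, tan, mid = _ROT_RINGS
            for radius, col in ((r, dark), (0.66 * r, tan), (0.33 * r, mid)):
                draw.ellipse([x - radius, y - radius, x + radius, y + radius],
                             fill=col)


def generate_scene(spec: SceneSpec, rng: np.random.Generator,
                   class_ids: list[int] | None = None,
                   source_id: str = "scene") -> AnnotatedImage:
    """Render one multi-leaf scene; one tight box + class id per leaf.

    ``class_ids`` fixes the class of each leaf (and the leaf count);
    otherwise classes are drawn uniformly.
    """
    c = spec.canvas
    if class_ids is None:
        n = int(rng.integers(spec.n_leaves[0], spec.n_leaves[1] + 1))
        class_ids = [int(rng.integers(len(CLASS_NAMES))) for _ in range(n)]
    n = len(class_ids)
    max_r = spec.max_leaf_frac * c / 2
    if n > max(1, int((c / max_r) ** 2)):
        raise ValueError(f"canvas {c} too small for {n} leaves")
    img = _background(c, spec.background_clutter, rng)
    pil = Image.fromarray(img)
    draw = ImageDraw.Draw(pil)
    boxes: list[np.ndarray] = []
    placed_cls: list[int] = []
    for cls in class_ids:
        for _attempt in range(80):
            # progressively shrink the size range so crowded scenes
            # still place every leaf
            hi = spec.max_leaf_frac - (spec.max_leaf_frac - spec.min_leaf_frac) \
                * min(_attempt / 40.0, 1.0)
            a = rng.uniform(spec.min_leaf_frac, max(hi, spec.min_leaf_frac * 1.01)) * c / 2
            b = a * rng.uniform(0.55, 0.8)
            theta = rng.uniform(0, np.pi)
            margin = a + 2
            cx = rng.uniform(margin, c - margin)
            cy = rng.uniform(margin, c - margin)
            poly = _leaf_polygon(cx, cy, a, b, theta)
            box = np.array([poly[:, 0].min(), poly[:, 1].min(),
                            poly[:, 0].max(), poly[:, 1].max()], np.float32)
            box = box.clip(0, c)
            area = (box[2] - box[0]) * (box[3] - box[1])
            visible_ok = True
            for prev in boxes:
                ix = max(0.0, min(box[2], prev[2]) - max(box[0], prev[0]))
                iy = max(0.0, min(box[3], prev[3]) - max(box[1], prev[1]))
                if ix * iy > spec.max_box_overlap * area:
                    visible_ok = False
                    break
            if visible_ok:
                break
        else:
            raise ValueError(
                f"could not place {n} leaves on canvas {c} without "
                f"excessive overlap; reduce n_leaves or leaf size")
        green = np.array(_LEAF_GREENS[int(rng.integers(len(_LEAF_GREENS)))])
        # diseased blades carry a global tint toward the lesion colour
        # (chlorosis/necrosis-style), keeping mean box hue separable
        tint = _TINTS[CLASS_NAMES[cls]]
        if tint is not None:
            green = (0.5 * green + 0.5 * np.array(tint)).astype(int)
        green = tuple(int(v) for v in green)
        draw.polygon([tuple(p) for p in poly], fill=green)
        # mid-vein
        tip = (cx + a * np.cos(theta), cy + a * np.sin(theta))
        base = (cx - a * np.cos(theta), cy - a * np.sin(theta))
        vein = tuple(int(v * 0.8) for v in green)
        draw.line([base, tip], fill=vein, width=max(1, int(0.03 * b)))
        _draw_lesions(draw, cls, cx, cy, a, b, theta, rng)
        boxes.append(box)
        placed_cls.append(cls)
    return AnnotatedImage(np.asarray(pil),
                          np.stack(boxes) if boxes else np.zeros((0, 4)),
                          placed_cls, source_id)


def generate_dataset(n_images: int, spec: SceneSpec, outdir: str | Path,
                     fmt: str = "yolo_txt",
                     split: tuple[float, float, float] = (0.54, 0.23, 0.23),
                     ) -> dict[str, list[str]]:
    """Write ``n_images`` scenes + annotations and train/val/test manifests.

    Leaf classes are assigned round-robin from a shuffled pool so the
    per-class label counts stay balanced (within a few percent at
    realistic sizes).  Returns the manifest mapping split name to the
    list of image ids; also written as ``<split>.txt`` files.
    """
    if abs(sum(split) - 1.0) > 1e-6:
        raise ValueError(f"split ratios must sum to 1, got {split}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    items: list[AnnotatedImage] = []
    pool: list[int] = []
    for i in range(n_images):
        n = int(rng.integers(spec.n_leaves[0], spec.n_leaves[1] + 1))
        cls = []
        for _ in range(n):
            if not pool:
                pool = list(rng.permutation(len(CLASS_NAMES)))
            cls.append(int(pool.pop()))
        items.append(generate_scene(spec, rng, class_ids=cls,
                                    source_id=f"scene{i:05d}"))
    write_annotations(items, outdir, fmt)
    n_train = int(round(split[0] * n_images))
    n_val = int(round(split[1] * n_images))
    ids = [it.source_id for it in items]
    manifest = {"train": ids[:n_train],
                "val": ids[n_train:n_train + n_val],
                "test": ids[n_train + n_val:]}
    for name, lst in manifest.items():
        (outdir / f"{name}.txt").write_text("\n".join(lst) + "\n")
    return manifest
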