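"""Annotation I/O, letterboxing and the augmentation pipeline.

Annotated images carry pixel ``xyxy`` boxes (0-based, half-open for
rasterisation) with 0-based class ids; the fixed class-name order is
``healthy, rust, scab, black rot``.  Three interchange formats are
supported and round-trip to within a pixel:

* YOLO text — one ``cls cx cy w h`` line per box, normalised to [0, 1];
* Pascal VOC XML — one XML file per image, 1-based inclusive corners;
* COCO JSON — one JSON file per dataset with images/annotations/categories.

Augmentation follows common one-stage-detector practice: photometric HSV
jitter (boxes untouched), a random affine (translate / scale / rotate /
shear) applied identically to image and boxes, horizontal flips, and the
four-image mosaic collage.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CLASS_NAMES", "AnnotatedImage", "AugmentConfig",
    "read_annotations", "write_annotations", "letterbox", "apply_letterbox",
    "invert_letterbox", "hsv_jitter", "random_affine", "augment", "mosaic4",
]

#: Fixed class-name -> id order for the four leaf categories.
CLASS_NAMES = ("healthy", "rust", "scab", "black rot")


@dataclass
class AnnotatedImage:
    """An RGB image with one pixel-space xyxy box + class id per object."""

    image: np.ndarray                 # (H, W, 3) uint8
    boxes: np.ndarray                 # (n, 4) float32 xyxy
    class_ids: np.ndarray             # (n,) int64
    source_id: str = ""

    def __post_init__(self):
        self.image = np.ascontiguousarray(self.image, dtype=np.uint8)
        self.boxes = np.asarray(self.boxes, dtype=np.float32).reshape(-1, 4)
        self.class_ids = np.asarray(self.class_ids, dtype=np.int64).reshape(-1)
        if len(self.boxes) != len(self.class_ids):
            raise ValueError("boxes and class_ids must pair one-to-one")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def clipped(self) -> "AnnotatedImage":
        """Clip boxes to the canvas, dropping those that degenerate."""
        b = self.boxes.copy()
        b[:, [0, 2]] = b[:, [0, 2]].clip(0, self.width)
        b[:, [1, 3]] = b[:, [1, 3]].clip(0, self.height)
        keep = (b[:, 2] - b[:, 0] >= 2) & (b[:, 3] - b[:, 1] >= 2)
        return AnnotatedImage(self.image, b[keep], self.class_ids[keep],
                              self.source_id)


@dataclass
class AugmentConfig:
    """Augmentation magnitudes (photometric gains, affine ranges)."""

    hsv_h: float = 0.015
    hsv_s: float = 0.7
    hsv_v: float = 0.4
    degrees: float = 0.0
    translate: float = 0.1
    scale: float = 0.5
    shear: float = 0.0
    fliplr_prob: float = 0.5
    mosaic: bool = True
    min_box_px: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.fliplr_prob <= 1.0:
            raise ValueError("fliplr_prob must be a probability")
        if min(self.hsv_h, self.hsv_s, self.hsv_v, self.scale) < 0:
            raise ValueError("gains must be non-negative")

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(hsv_h=0, hsv_s=0, hsv_v=0, degrees=0, translate=0,
                   scale=0, shear=0, fliplr_prob=0, mosaic=False)


# -- reading and writing -------------------------------------------------

def _read_image(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def _iter_images(root: Path):
    img_dir = root / "images" if (root / "images").is_dir() else root
    for p in sorted(img_dir.iterdir()):
        if p.suffix.lower() in {".jpg", ".jpeg", ".png"}:
            yield p


def read_annotations(root: str | Path, fmt: str) -> list[AnnotatedImage]:
    """Load a dataset directory in ``yolo_txt``, ``voc_xml`` or
    ``coco_json`` layout into pixel-space annotated images."""
    root = Path(root)
    if fmt == "yolo_txt":
        return _read_yolo(root)
    if fmt == "voc_xml":
        return _read_voc(root)
    if fmt == "coco_json":
        return _read_coco(root)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_yolo(root: Path) -> list[AnnotatedImage]:
    out = []
    lbl_dir = root / "labels" if (root / "labels").is_dir() else root
    for img_path in _iter_images(root):
        img = _read_image(img_path)
        h, w = img.shape[:2]
        lbl = lbl_dir / f"{img_path.stem}.txt"
        boxes, cids = [], []
        if lbl.exists():
            for ln, line in enumerate(lbl.read_text().splitlines(), 1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 5:
                    raise ValueError(f"{lbl}:{ln}: expected 5 fields, "
                                     f"got {len(parts)}")
                try:
                    c = int(parts[0])
                    cx, cy, bw, bh = map(float, parts[1:])
                except ValueError as e:
                    raise ValueError(f"{lbl}:{ln}: malformed record") from e
                boxes.append([(cx - bw / 2) * w, (cy - bh / 2) * h,
                              (cx + bw / 2) * w, (cy + bh / 2) * h])
                cids.append(c)
        out.append(AnnotatedImage(img, np.array(boxes, np.float32).reshape(-1, 4),
                                  cids, img_path.stem).clipped())
    return out


def _read_voc(root: Path) -> list[AnnotatedImage]:
    out = []
    ann_dir = root / "annotations" if (root / "annotations").is_dir() else root
    name_to_id = {n: i for i, n in enumerate(CLASS_NAMES)}
    for img_path in _iter_images(root):
        img = _read_image(img_path)
        xml = ann_dir / f"{img_path.stem}.xml"
        boxes, cids = [], []
        if xml.exists():
            try:
                tree = ET.parse(xml)
            except ET.ParseError as e:
                raise ValueError(f"{xml}: malformed XML: {e}") from e
            for obj in tree.getroot().iter("object"):
                name = obj.findtext("name", "")
                if name not in name_to_id:
                    raise ValueError(f"{xml}: unknown class name {name!r}")
                bb = obj.find("bndbox")
                if bb is None:
                    raise ValueError(f"{xml}: object without bndbox")
                # VOC corners are 1-based inclusive
                x1 = float(bb.findtext("xmin")) - 1
                y1 = float(bb.findtext("ymin")) - 1
                x2 = float(bb.findtext("xmax"))
                y2 = float(bb.findtext("ymax"))
                boxes.append([x1, y1, x2, y2])
                cids.append(name_to_id[name])
        out.append(AnnotatedImage(img, np.array(boxes, np.float32).reshape(-1, 4),
                                  cids, img_path.stem).clipped())
    return out


def _read_coco(root: Path) -> list[AnnotatedImage]:
    ann_file = (root / "annotations.json" if (root / "annotations.json").exists()
                else root / "coco.json")
    if not ann_file.exists():
        raise FileNotFoundError(f"no annotations.json under {root}")
    try:
        data = json.loads(ann_file.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{ann_file}: malformed JSON: {e}") from e
    per_img: dict[int, list] = {}
    for a in data.get("annotations", []):
        x, y, w, h = a["bbox"]
        per_img.setdefault(a["image_id"], []).append(
            ([x, y, x + w, y + h], a["category_id"]))
    out = []
    img_dir = root / "images" if (root / "images").is_dir() else root
    for info in sorted(data["images"], key=lambda r: r["file_name"]):
        img = _read_image(img_dir / info["file_name"])
        anns = per_img.get(info["id"], [])
        boxes = np.array([b for b, _ in anns], np.float32).reshape(-1, 4)
        cids = [c for _, c in anns]
        out.append(AnnotatedImage(img, boxes, cids,
                                  Path(info["file_name"]).stem).clipped())
    return out


def write_annotations(items: list[AnnotatedImage], root: str | Path,
                      fmt: str) -> None:
    """Write images + annotations in the requested standard layout
    (inverse of :func:`read_annotations` up to coordinate rounding)."""
    root = Path(root)
    items = sorted(items, key=lambda it: it.source_id)
    (root / "images").mkdir(parents=True, exist_ok=True)
    for it in items:
        Image.fromarray(it.image).save(root / "images" / f"{it.source_id}.png")
    if fmt == "yolo_txt":
        (root / "labels").mkdir(exist_ok=True)
        for it in items:
            lines = []
            for (x1, y1, x2, y2), c in zip(it.boxes, it.class_ids):
                cx, cy = (x1 + x2) / 2 / it.width, (y1 + y2) / 2 / it.height
                bw, bh = (x2 - x1) / it.width, (y2 - y1) / it.height
                lines.append(f"{c} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
            (root / "labels" / f"{it.source_id}.txt").write_text(
                "\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "voc_xml":
        (root / "annotations").mkdir(exist_ok=True)
        for it in items:
            e = ET.Element("annotation")
            ET.SubElement(e, "filename").text = f"{it.source_id}.png"
            size = ET.SubElement(e, "size")
            ET.SubElement(size, "width").text = str(it.width)
            ET.SubElement(size, "height").text = str(it.height)
            ET.SubElement(size, "depth").text = "3"
            for (x1, y1, x2, y2), c in zip(it.boxes, it.class_ids):
                obj = ET.SubElement(e, "object")
                ET.SubElement(obj, "name").text = CLASS_NAMES[int(c)]
                bb = ET.SubElement(obj, "bndbox")
                ET.SubElement(bb, "xmin").text = str(int(round(x1)) + 1)
                ET.SubElement(bb, "ymin").text = str(int(round(y1)) + 1)
                ET.SubElement(bb, "xmax").text = str(int(round(x2)))
                ET.SubElement(bb, "ymax").text = str(int(round(y2)))
            ET.indent(e)
            ET.ElementTree(e).write(root / "annotations" / f"{it.source_id}.xml")
    elif fmt == "coco_json":
        images, annotations = [], []
        aid = 1
        for iid, it in enumerate(items, 1):
            images.append({"id": iid, "file_name": f"{it.source_id}.png",
                           "width": it.width, "height": it.height})
            for (x1, y1, x2, y2), c in zip(it.boxes, it.class_ids):
                annotations.append({
                    "id": aid, "image_id": iid, "category_id": int(c),
                    "bbox": [round(float(x1), 2), round(float(y1), 2),
                             round(float(x2 - x1), 2), round(float(y2 - y1), 2)],
                    "area": round(float((x2 - x1) * (y2 - y1)), 2),
                    "iscrowd": 0})
                aid += 1
        categories = [{"id": i, "name": n} for i, n in enumerate(CLASS_NAMES)]
        (root / "annotations.json").write_text(json.dumps(
            {"images": images, "annotations": annotations,
             "categories": categories}, indent=1))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")


# -- letterboxing --------------------------------------------------------

def letterbox(img: np.ndarray, target: int, stride: int = 32,
              fill: int = 114):
    """Aspect-preserving resize (long side -> ``target``) plus constant
    padding of the short side up to the next stride multiple.

    Returns ``(padded_image, scale, (pad_x, pad_y))``; map a source box
    through ``x * scale + pad`` (see :func:`apply_letterbox`).
    """
    if target % stride:
        raise ValueError(f"target {target} not divisible by stride {stride}")
    h, w = img.shape[:2]
    scale = target / max(h, w)
    nw, nh = max(1, int(round(w * scale))), max(1, int(round(h * scale)))
    resized = np.asarray(Image.fromarray(img).resize((nw, nh), Image.BILINEAR))
    ph = (nh + stride - 1) // stride * stride
    pw = (nw + stride - 1) // stride * stride
    canvas = np.full((ph, pw, 3), fill, dtype=np.uint8)
    px, py = (pw - nw) // 2, (ph - nh) // 2
    canvas[py:py + nh, px:px + nw] = resized
    return canvas, scale, (float(px), float(py))


def apply_letterbox(boxes: np.ndarray, scale: float, pad) -> np.ndarray:
    b = np.asarray(boxes, dtype=np.float32).reshape(-1, 4).copy()
    b[:, [0, 2]] = b[:, [0, 2]] * scale + pad[0]
    b[:, [1, 3]] = b[:, [1, 3]] * scale + pad[1]
    return b


def invert_letterbox(boxes: np.ndarray, scale: float, pad) -> np.ndarray:
    b = np.asarray(boxes, dtype=np.float32).reshape(-1, 4).copy()
    b[:, [0, 2]] = (b[:, [0, 2]] - pad[0]) / scale
    b[:, [1, 3]] = (b[:, [1, 3]] - pad[1]) / scale
    return b


# -- augmentation --------------------------------------------------------

def _rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    return np.asarray(Image.fromarray(img).convert("HSV"))


def _hsv_to_rgb(img: np.ndarray) -> np.ndarray:
    return np.asarray(Image.fromarray(img, mode="HSV").convert("RGB"))


def hsv_jitter(img: np.ndarray, gains: tuple[float, float, float],
               rng: np.random.Generator) -> np.ndarray:
    """Random hue shift and saturation/value rescale; geometry untouched."""
    gh, gs, gv = gains
    if gh == gs == gv == 0:
        return img
    r = rng.uniform(-1, 1, 3) * (gh, gs, gv) + (0, 1, 1)
    hsv = _rgb_to_hsv(img).astype(np.float32)
    hsv[..., 0] = (hsv[..., 0] + r[0] * 255) % 256
    hsv[..., 1] = np.clip(hsv[..., 1] * r[1], 0, 255)
    hsv[..., 2] = np.clip(hsv[..., 2] * r[2], 0, 255)
    return _hsv_to_rgb(hsv.astype(np.uint8))


def random_affine(item: AnnotatedImage, cfg: AugmentConfig,
                  rng: np.random.Generator) -> AnnotatedImage:
    """Random rotation/scale/shear/translation applied to image and boxes
    through the same matrix; boxes are clipped and tiny remnants dropped."""
    h, w = item.image.shape[:2]
    ang = np.deg2rad(rng.uniform(-cfg.degrees, cfg.degrees))
    s = rng.uniform(1 - cfg.scale, 1 + cfg.scale)
    shx = np.tan(np.deg2rad(rng.uniform(-cfg.shear, cfg.shear)))
    shy = np.tan(np.deg2rad(rng.uniform(-cfg.shear, cfg.shear)))
    tx = rng.uniform(-cfg.translate, cfg.translate) * w
    ty = rng.uniform(-cfg.translate, cfg.translate) * h
    cx, cy = w / 2, h / 2
    rot = np.array([[s * np.cos(ang), -s * np.sin(ang)],
                    [s * np.sin(ang), s * np.cos(ang)]])
    shear_m = np.array([[1, shx], [shy, 1]])
    a = rot @ shear_m
    # full affine: y = A (x - c) + c + t
    off = np.array([cx, cy]) - a @ np.array([cx, cy]) + np.array([tx, ty])
    m = np.eye(3)
    m[:2, :2], m[:2, 2] = a, off
    if np.allclose(m, np.eye(3)):
        return item
    inv = np.linalg.inv(m)
    out = Image.fromarray(item.image).transform(
        (w, h), Image.AFFINE, data=inv[:2].reshape(6), resample=Image.BILINEAR,
        fillcolor=(114, 114, 114))
    if item.boxes.shape[0]:
        corners = np.stack([
            item.boxes[:, [0, 1]], item.boxes[:, [2, 1]],
            item.boxes[:, [0, 3]], item.boxes[:, [2, 3]]], axis=1)  # (n,4,2)
        pts = corners @ a.T + off
        nb = np.concatenate([pts.min(axis=1), pts.max(axis=1)], axis=1)
    else:
        nb = item.boxes
    return AnnotatedImage(np.asarray(out), nb, item.class_ids,
                          item.source_id).clipped()


def augment(item: AnnotatedImage, cfg: AugmentConfig,
            rng: np.random.Generator) -> AnnotatedImage:
    """Photometric then geometric augmentation of one annotated image."""
    img = hsv_jitter(item.image, (cfg.hsv_h, cfg.hsv_s, cfg.hsv_v), rng)
    item = AnnotatedImage(img, item.boxes, item.class_ids, item.source_id)
    item = random_affine(item, cfg, rng)
    if cfg.fliplr_prob > 0 and rng.random() < cfg.fliplr_prob:
        w = item.width
        b = item.boxes.copy()
        b[:, [0, 2]] = w - b[:, [2, 0]]
        item = AnnotatedImage(item.image[:, ::-1], b, item.class_ids,
                              item.source_id)
    return item


def mosaic4(items: list[AnnotatedImage], canvas: int,
            rng: np.random.Generator,
            cfg: AugmentConfig | None = None) -> AnnotatedImage:
    """Four-image mosaic: a 2x2 collage on a ``2*canvas`` square around a
    random centre drawn from the central half; each tile is letterbox
    scaled to ``canvas`` and boxes are remapped and clipped.  The collage
    is then passed through :func:`augment` when a config is given.
    """
    if len(items) != 4:
        raise ValueError(f"mosaic needs exactly 4 images, got {len(items)}")
    size = 2 * canvas
    out = np.full((size, size, 3), 114, dtype=np.uint8)
    xc = int(rng.uniform(canvas // 2, canvas + canvas // 2))
    yc = int(rng.uniform(canvas // 2, canvas + canvas // 2))
    all_boxes, all_cids = [], []
    for idx, it in enumerate(items):
        scale = canvas / max(it.height, it.width)
        nw = max(1, int(round(it.width * scale)))
        nh = max(1, int(round(it.height * scale)))
        tile = np.asarray(Image.fromarray(it.image).resize(
            (nw, nh), Image.BILINEAR))
        if idx == 0:   # top-left, anchored at the centre
            x1, y1 = max(xc - nw, 0), max(yc - nh, 0)
            x2, y2 = xc, yc
        elif idx == 1:  # top-right
            x1, y1 = xc, max(yc - nh, 0)
            x2, y2 = min(xc + nw, size), yc
        elif idx == 2:  # bottom-left
            x1, y1 = max(xc - nw, 0), yc
            x2, y2 = xc, min(yc + nh, size)
        else:           # bottom-right
            x1, y1 = xc, yc
            x2, y2 = min(xc + nw, size), min(yc + nh, size)
        tw, th = x2 - x1, y2 - y1
        sx = nw - tw if idx in (0, 2) else 0   # crop from the far side
        sy = nh - th if idx in (0, 1) else 0
        out[y1:y2, x1:x2] = tile[sy:sy + th, sx:sx + tw]
        if it.boxes.shape[0]:
            b = it.boxes * scale
            b[:, [0, 2]] += x1 - sx
            b[:, [1, 3]] += y1 - sy
            all_boxes.append(b)
            all_cids.append(it.class_ids)
    boxes = (np.concatenate(all_boxes) if all_boxes
             else np.zeros((0, 4), np.float32))
    cids = (np.concatenate(all_cids) if all_cids
            else np.zeros((0,), np.int64))
    sid = "mosaic-" + "-".join(it.source_id for it in items)
    collage = AnnotatedImage(out, boxes, cids, sid).clipped()
    if cfg is not None:
        collage = augment(collage, cfg, rng)
    return collage
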