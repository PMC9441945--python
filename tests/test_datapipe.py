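"""Annotation format round-trips, letterbox geometry and augmentation
invariants (photometric ops never touch boxes; geometric ops move boxes
and labels together)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgayolo.datapipe import (CLASS_NAMES, AnnotatedImage, AugmentConfig,
                              apply_letterbox, augment, hsv_jitter,
                              invert_letterbox, letterbox, mosaic4,
                              read_annotations, write_annotations)


def make_item(rng, h=96, w=128, n_boxes=3, source_id="img0"):
    img = rng.integers(0, 255, (h, w, 3), dtype=np.uint8)
    xy = rng.uniform(0, [w - 20, h - 20], (n_boxes, 2))
    wh = rng.uniform(8, 20, (n_boxes, 2))
    boxes = np.concatenate([xy, xy + wh], axis=1).astype(np.float32)
    cids = rng.integers(0, 4, n_boxes)
    return AnnotatedImage(img, boxes, cids, source_id)


# -- format I/O ----------------------------------------------------------

def test_yolo_line_denormalisation(tmp_path):
    img_dir = tmp_path / "images"
    img_dir.mkdir()
    from PIL import Image
    Image.new("RGB", (640, 640)).save(img_dir / "a.png")
    (tmp_path / "labels").mkdir()
    (tmp_path / "labels" / "a.txt").write_text("1 0.5 0.5 0.5 0.5\n")
    items = read_annotations(tmp_path, "yolo_txt")
    assert len(items) == 1
    assert items[0].class_ids.tolist() == [1]          # rust
    assert np.allclose(items[0].boxes[0], [160, 160, 480, 480], atol=0.5)


def test_empty_label_file_yields_zero_boxes(tmp_path):
    from PIL import Image
    (tmp_path / "images").mkdir()
    Image.new("RGB", (64, 64)).save(tmp_path / "images" / "a.png")
    (tmp_path / "labels").mkdir()
    (tmp_path / "labels" / "a.txt").write_text("")
    items = read_annotations(tmp_path, "yolo_txt")
    assert items[0].boxes.shape == (0, 4)


def test_malformed_yolo_record_names_file_and_line(tmp_path):
    from PIL import Image
    (tmp_path / "images").mkdir()
    Image.new("RGB", (64, 64)).save(tmp_path / "images" / "a.png")
    (tmp_path / "labels").mkdir()
    (tmp_path / "labels" / "a.txt").write_text("1 0.5 0.5\n")
    with pytest.raises(ValueError, match=r"a\.txt:1"):
        read_annotations(tmp_path, "yolo_txt")


@pytest.mark.parametrize("fmt", ["yolo_txt", "voc_xml", "coco_json"])
def test_format_round_trip_within_one_pixel(tmp_path, rng, fmt):
    items = [make_item(rng, source_id=f"img{i}") for i in range(3)]
    write_annotations(items, tmp_path / fmt, fmt)
    back = read_annotations(tmp_path / fmt, fmt)
    assert [b.source_id for b in back] == [it.source_id for it in items]
    for orig, rt in zip(items, back):
        assert np.array_equal(orig.class_ids, rt.class_ids)
        assert np.abs(orig.boxes - rt.boxes).max() <= 1.0
        assert np.array_equal(orig.image, rt.image)  # png is lossless


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_round_trip_fuzz_yolo(tmp_path_factory, seed):
    rng = np.random.default_rng(seed)
    tmp = tmp_path_factory.mktemp(f"fuzz{seed % 1000}")
    items = [make_item(rng, h=int(rng.integers(40, 200)),
                       w=int(rng.integers(40, 200)),
                       n_boxes=int(rng.integers(0, 5)))]
    write_annotations(items, tmp, "yolo_txt")
    back = read_annotations(tmp, "yolo_txt")
    assert np.abs(items[0].boxes - back[0].boxes).max(initial=0) <= 1.0


def test_coco_output_has_schema_keys(tmp_path, rng):
    import json
    write_annotations([make_item(rng)], tmp_path, "coco_json")
    data = json.loads((tmp_path / "annotations.json").read_text())
    assert set(data) >= {"images", "annotations", "categories"}
    assert [c["name"] for c in data["categories"]] == list(CLASS_NAMES)


# -- letterbox -----------------------------------------------------------

def test_letterbox_pads_short_side_to_stride_multiple():
    img = np.zeros((720, 1280, 3), np.uint8)
    padded, scale, pad = letterbox(img, 640, stride=64)
    assert padded.shape[1] == 640          # long side
    assert padded.shape[0] == 384          # 360 padded up to 384
    assert abs(scale - 0.5) < 1e-9


def test_letterbox_square_input_zero_padding():
    img = np.zeros((320, 320, 3), np.uint8)
    padded, scale, pad = letterbox(img, 640, stride=32)
    assert padded.shape[:2] == (640, 640) and pad == (0.0, 0.0)


def test_letterbox_box_round_trip_within_half_pixel(rng):
    img = np.zeros((300, 500, 3), np.uint8)
    _, scale, pad = letterbox(img, 640, stride=32)
    boxes = rng.uniform(0, 290, (5, 4)).astype(np.float32)
    boxes[:, 2:] += 5
    back = invert_letterbox(apply_letterbox(boxes, scale, pad), scale, pad)
    assert np.abs(back - boxes).max() < 0.5


def test_letterbox_rejects_non_stride_target():
    with pytest.raises(ValueError):
        letterbox(np.zeros((64, 64, 3), np.uint8), 100, stride=64)


# -- augmentation --------------------------------------------------------

def test_hsv_jitter_leaves_geometry_untouched(rng):
    item = make_item(rng)
    out = hsv_jitter(item.image, (0.05, 0.5, 0.5), rng)
    assert out.shape == item.image.shape
    # boxes are not part of the photometric path at all


def test_identity_config_is_identity(rng):
    item = make_item(rng)
    out = augment(item, AugmentConfig.identity(), rng)
    assert np.array_equal(out.image, item.image)
    assert np.allclose(out.boxes, item.boxes)


def test_fliplr_maps_boxes_mirror(rng):
    item = AnnotatedImage(np.zeros((640, 640, 3), np.uint8),
                          np.array([[10, 10, 20, 20]], np.float32), [0])
    cfg = AugmentConfig.identity()
    cfg.fliplr_prob = 1.0
    out = augment(item, cfg, rng)
    assert np.allclose(out.boxes[0], [620, 10, 630, 20])


def test_augment_is_deterministic_under_fixed_seed(rng):
    item = make_item(rng)
    cfg = AugmentConfig()
    a = augment(item, cfg, np.random.default_rng(5))
    b = augment(item, cfg, np.random.default_rng(5))
    assert np.array_equal(a.image, b.image)
    assert np.allclose(a.boxes, b.boxes)


def test_geometric_augment_keeps_class_pairing(rng):
    item = make_item(rng, n_boxes=4)
    cfg = AugmentConfig(translate=0.2, scale=0.3, degrees=15)
    out = augment(item, cfg, np.random.default_rng(2))
    assert len(out.boxes) == len(out.class_ids)
    assert set(out.class_ids) <= set(item.class_ids)


# -- mosaic --------------------------------------------------------------

def test_mosaic_conserves_boxes_without_heavy_clipping(rng):
    items = [make_item(rng, h=100, w=100, n_boxes=1, source_id=f"m{i}")
             for i in range(4)]
    # keep each box central so tiling cannot clip it away
    for it in items:
        it.boxes[:] = [40, 40, 60, 60]
    out = mosaic4(items, canvas=100, rng=np.random.default_rng(0))
    assert out.image.shape == (200, 200, 3)
    assert len(out.boxes) == 4
    assert np.all(out.boxes[:, [0, 1]] >= 0)
    assert np.all(out.boxes[:, [2, 3]] <= 200)


def test_mosaic_boxes_inside_canvas(rng):
    items = [make_item(rng, n_boxes=3, source_id=f"m{i}") for i in range(4)]
    out = mosaic4(items, canvas=96, rng=np.random.default_rng(3))
    if out.boxes.shape[0]:
        assert out.boxes.min() >= 0 and out.boxes.max() <= 192
    assert len(out.boxes) <= 12  # clipping may drop, never add


def test_mosaic_deterministic_and_needs_four(rng):
    items = [make_item(rng, source_id=f"m{i}") for i in range(4)]
    a = mosaic4(items, 96, np.random.default_rng(1))
    b = mosaic4(items, 96, np.random.default_rng(1))
    assert np.array_equal(a.image, b.image) and np.allclose(a.boxes, b.boxes)
    with pytest.raises(ValueError):
        mosaic4(items[:3], 96, rng)
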