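"""Metric checks: IoU geometry, NMS semantics, the AP/mAP pipeline
against hand-computed values and an exhaustive matching oracle, and
confusion-matrix bookkeeping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgayolo.metrics import (ConfusionMatrix, box_iou, confusion, evaluate,
                             iou, load_detections_coco, nms,
                             save_detections_coco)


def det(x1, y1, x2, y2, conf, cls):
    return [x1, y1, x2, y2, conf, cls]


def gt(x1, y1, x2, y2, cls):
    return [x1, y1, x2, y2, cls]


# -- IoU -----------------------------------------------------------------

def test_iou_hand_cases():
    assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
    assert abs(iou((0, 0, 2, 2), (1, 0, 3, 2)) - 1 / 3) < 1e-12
    assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0


def test_iou_rejects_degenerate_boxes():
    with pytest.raises(ValueError):
        iou((0, 0, 0, 2), (0, 0, 1, 1))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-50, 50), min_size=4, max_size=4),
       st.lists(st.floats(-50, 50), min_size=4, max_size=4),
       st.floats(-20, 20), st.floats(-20, 20))
def test_iou_symmetric_and_translation_invariant(a, b, dx, dy):
    ax1, ay1, aw, ah = a
    bx1, by1, bw, bh = b
    ba = (ax1, ay1, ax1 + abs(aw) + 1, ay1 + abs(ah) + 1)
    bb = (bx1, by1, bx1 + abs(bw) + 1, by1 + abs(bh) + 1)
    assert abs(iou(ba, bb) - iou(bb, ba)) < 1e-12
    shift = np.array([dx, dy, dx, dy])
    assert abs(iou(np.array(ba) + shift, np.array(bb) + shift)
               - iou(ba, bb)) < 1e-9


# -- NMS -----------------------------------------------------------------

def test_nms_suppresses_same_class_overlap():
    dets = np.array([det(0, 0, 10, 10, 0.9, 0),
                     det(1, 0, 11, 10, 0.8, 0)])
    out = nms(dets, 0.45)
    assert out.shape[0] == 1 and out[0, 4] == 0.9


def test_nms_keeps_different_classes():
    dets = np.array([det(0, 0, 10, 10, 0.9, 0),
                     det(0, 0, 10, 10, 0.8, 1)])
    assert nms(dets, 0.45).shape[0] == 2


def test_nms_empty_input_and_bad_threshold():
    assert nms(np.zeros((0, 6)), 0.5).shape == (0, 6)
    with pytest.raises(ValueError):
        nms(np.zeros((0, 6)), 1.5)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_nms_independent_of_input_order(seed):
    r = np.random.default_rng(seed)
    n = 8
    xy = r.uniform(0, 50, (n, 2))
    wh = r.uniform(5, 25, (n, 2))
    dets = np.concatenate(
        [xy, xy + wh, r.permutation(n).reshape(-1, 1) / n + 0.05,
         r.integers(0, 2, (n, 1))], axis=1)
    base = nms(dets, 0.45)
    shuffled = nms(dets[r.permutation(n)], 0.45)
    assert np.allclose(base, shuffled)


# -- evaluation ----------------------------------------------------------

def test_perfect_detections_score_one():
    gts = [np.array([gt(0, 0, 10, 10, 0), gt(20, 20, 40, 50, 1)])]
    dets = [np.array([det(0, 0, 10, 10, 1.0, 0),
                      det(20, 20, 40, 50, 1.0, 1)])]
    res = evaluate(dets, gts, nc=2)
    assert res.map50 == 1.0 and res.map == 1.0
    assert res.mean_precision == 1.0 and res.mean_recall == 1.0


def test_single_detection_at_iou_0625_gives_ap50_one_map_03():
    """One GT, one detection with IoU 0.625: a true positive at
    thresholds 0.50/0.55/0.60 only, so mAP = 3/10."""
    gts = [np.array([gt(0, 0, 10, 10, 0)])]
    dets = [np.array([det(0, 0, 10, 16, 0.9, 0)])]
    assert abs(iou(gts[0][0][:4], dets[0][0][:4]) - 0.625) < 1e-12
    res = evaluate(dets, gts, nc=1)
    assert res.ap50[0] == 1.0
    assert abs(res.map - 0.3) < 1e-9


def test_precision_recall_from_counts():
    """9 TP and 1 FP retained at the operating point: precision
    TP/(TP+FP) = 0.9, recall TP/(TP+FN) = 1.0."""
    gts, dets = [], []
    for i in range(9):
        gts.append(np.array([gt(0, 0, 10, 10, 0)]))
        dets.append(np.array([det(0, 0, 10, 10, 0.8, 0)]))
    gts.append(np.zeros((0, 5)))
    # false positive ranked first, so every cut of the list includes it
    dets.append(np.array([det(50, 50, 60, 60, 0.95, 0)]))
    res = evaluate(dets, gts, nc=1)
    assert abs(res.precision[0] - 0.9) < 1e-9
    assert res.recall[0] == 1.0


def test_classes_without_labels_are_excluded_from_aggregate():
    gts = [np.array([gt(0, 0, 10, 10, 0)])]
    dets = [np.array([det(0, 0, 10, 10, 0.9, 0)])]
    res = evaluate(dets, gts, nc=3)
    assert np.isnan(res.ap50[1]) and np.isnan(res.ap50[2])
    assert res.map50 == 1.0


def test_map_non_increasing_in_iou_threshold(rng):
    gts, dets = [], []
    for _ in range(6):
        n = rng.integers(1, 4)
        g = []
        d = []
        for _ in range(n):
            x, y = rng.uniform(0, 60, 2)
            w, h = rng.uniform(8, 30, 2)
            g.append([x, y, x + w, y + h, rng.integers(0, 2)])
            jit = rng.uniform(-4, 4, 4)
            d.append([x + jit[0], y + jit[1], x + w + jit[2], y + h + jit[3],
                      rng.uniform(0.3, 1.0), g[-1][4]])
        gts.append(np.array(g))
        dets.append(np.array(d))
    thrs = np.arange(0.5, 0.96, 0.05)
    aps = [evaluate(dets, gts, nc=2, iou_thresholds=[t]).map for t in thrs]
    assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))


def _oracle_match(det_boxes, gt_boxes, thr):
    """Enumeration oracle for the confidence-priority matching semantics.

    Enumerates every one-to-one assignment of detections (in confidence
    order) to ground truths, keeps the valid ones (assigned pairs have
    IoU >= thr), and returns the assignment that is lexicographically
    best under the per-detection key (matched, IoU) — i.e. earlier
    (higher-confidence) detections are satisfied first, each preferring
    the highest-IoU ground truth.  This reconstructs the defined greedy
    semantics by global search instead of sequential state mutation.
    """
    nd, ng = len(det_boxes), len(gt_boxes)
    ious = box_iou(det_boxes, gt_boxes) if nd and ng else np.zeros((nd, ng))
    best_key, best_flags = None, np.zeros(nd, bool)
    for assign in itertools.product(range(ng + 1), repeat=nd):
        used = [a for a in assign if a < ng]
        if len(used) != len(set(used)):
            continue
        if any(a < ng and ious[i, a] < thr for i, a in enumerate(assign)):
            continue
        key = tuple((1, ious[i, a]) if a < ng else (0, 0.0)
                    for i, a in enumerate(assign))
        if best_key is None or key > best_key:
            best_key = key
            best_flags = np.array([a < ng for a in assign])
    return best_flags


def test_matcher_agrees_with_enumeration_oracle_on_small_instances(rng):
    """On instances with <= 4 boxes per side, the sequential matcher
    reproduces the assignment found by exhaustive enumeration."""
    from mgayolo.metrics import match_detections

    for trial in range(40):
        nd, ng = rng.integers(1, 5), rng.integers(1, 5)
        mk = lambda n: np.concatenate(
            [rng.uniform(0, 40, (n, 2)), rng.uniform(10, 40, (n, 2))], axis=1)
        d4 = mk(nd)
        d4[:, 2:] += d4[:, :2]
        g4 = mk(ng)
        g4[:, 2:] += g4[:, :2]
        conf_order = np.argsort(-rng.uniform(0.1, 1, nd))
        d4 = d4[conf_order]
        for thr in (0.3, 0.5):
            ours = match_detections(d4, g4, thr)
            oracle = _oracle_match(d4, g4, thr)
            assert np.array_equal(ours, oracle), f"trial {trial} thr {thr}"


# -- confusion matrix ----------------------------------------------------

def test_confusion_perfect_is_identity_block():
    gts = [np.array([gt(0, 0, 10, 10, 0), gt(20, 20, 30, 30, 1)])]
    dets = [np.array([det(0, 0, 10, 10, 0.9, 0),
                      det(20, 20, 30, 30, 0.9, 1)])]
    cm = confusion(dets, gts, nc=2)
    assert np.allclose(cm.matrix[:2, :2], np.eye(2))
    assert cm.matrix[2].sum() == 0


def test_confusion_no_detections_all_background_row():
    gts = [np.array([gt(0, 0, 10, 10, 0), gt(20, 20, 30, 30, 1)])]
    cm = confusion([np.zeros((0, 6))], gts, nc=2)
    assert cm.matrix[2, 0] == 1 and cm.matrix[2, 1] == 1
    assert cm.matrix[:2].sum() == 0


def test_confusion_misclassified_match_lands_off_diagonal():
    gts = [np.array([gt(0, 0, 10, 10, 1)])]
    dets = [np.array([det(0, 0, 10, 10, 0.9, 0)])]
    cm = confusion(dets, gts, nc=2)
    norm = cm.normalized()
    assert norm[0, 1] == 1.0  # predicted 0, truth 1
    assert cm.matrix.sum() == 1


def test_confusion_columns_normalise_to_one():
    r = np.random.default_rng(1)
    gts, dets = [], []
    for _ in range(5):
        g = [[x, x, x + 10, x + 10, int(c)] for x, c in
             zip(r.uniform(0, 50, 3), r.integers(0, 3, 3))]
        d = [[*row[:4], r.uniform(0.3, 1.0), r.integers(0, 3)] for row in g]
        gts.append(np.array(g, float))
        dets.append(np.array(d, float))
    cm = confusion(dets, gts, nc=3)
    norm = cm.normalized()
    sums = norm.sum(axis=0)
    nonzero = cm.matrix.sum(axis=0) > 0
    assert np.allclose(sums[nonzero], 1.0)


def test_coco_detection_dump_round_trip(tmp_path):
    dets = [np.array([det(1, 2, 11, 22, 0.75, 3)]),
            np.array([det(5, 5, 9, 9, 0.5, 0), det(0, 0, 4, 4, 0.25, 1)])]
    path = tmp_path / "dets.json"
    save_detections_coco(dets, ["a", "b"], path)
    back = load_detections_coco(path)
    assert set(back) == {"a", "b"}
    assert np.allclose(back["b"][:, :4], dets[1][:, :4], atol=0.01)
    assert np.allclose(back["a"][0, 4], 0.75, atol=1e-5)
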