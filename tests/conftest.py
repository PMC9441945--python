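"""Shared fixtures: seeded RNGs, tiny synthetic scenes, and built models.

Model builds and profiler runs are session-scoped because they are the
most expensive fixtures; everything downstream treats them as read-only.
"""

import numpy as np
import pytest

from mgayolo.model import build_model, load_config


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def baseline_model():
    return build_model("yolov5s", seed=0)


@pytest.fixture(scope="session")
def mga_model():
    return build_model("mga-yolo", seed=0)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A width-reduced four-head config for fast forward/training tests."""
    cfg = load_config("mga-yolo")
    cfg["width_multiple"] = 0.25
    cfg["variant"] = "mga-yolo-tiny"
    cfg["anchors"] = [[round(a * 0.4) for a in row] for row in cfg["anchors"]]
    return cfg


@pytest.fixture(scope="session")
def tiny_p5_cfg():
    """A width-reduced three-head (stride 8/16/32) config."""
    cfg = load_config("yolov5s-ghost-c3mb-cbam")
    cfg["width_multiple"] = 0.25
    cfg["variant"] = "tiny-p5"
    cfg["anchors"] = [[round(a * 0.4) for a in row] for row in cfg["anchors"]]
    return cfg


def finite_difference(f, x, eps=1e-3):
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
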