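"""Network building blocks for lightweight leaf-disease detectors.

The vocabulary here is the one used by mobile one-stage detectors:

* :class:`ConvBnAct` — convolution + batch norm + activation ("CBL"/"CBS").
* :class:`Focus` — 2x2 space-to-depth slicing followed by a convolution.
* :class:`GhostConv` — a Ghost module: an ordinary convolution computes
  half the output channels (the *intrinsic* maps) and a cheap 5x5
  depthwise convolution derives the other half (the *ghost* maps); the
  two halves are concatenated.  The multiply–accumulate cost approaches
  half that of an ordinary convolution of the same shape.
* :class:`GhostBottleneck` / :class:`C3Ghost` — residual stack of two
  Ghost modules, and the CSP ("C3") stage built from it.
* :class:`CBAM` — channel attention (global max+avg pooling through a
  shared bottleneck MLP) followed by spatial attention (channelwise
  max+mean through a small odd-kernel convolution), both as
  multiplicative sigmoid gates.  :class:`SqueezeExcite` and :class:`CoordAtt` are the two
  alternative gates used for ablations.
* :class:`MBConvA` — inverted residual bottleneck (1x1 expand -> 3x3
  depthwise -> 1x1 linear projection) with an attention module on the
  expanded maps and no activation after the depthwise stage.
* :class:`C3MB` — the CSP stage whose inner block is MBConvA.
* :class:`SPP`, :class:`Concat`, :class:`Detect` — the standard YOLO
  spatial-pyramid-pooling neck entry, route concatenation and the
  anchor-based prediction head.

All blocks are shape-honest: attention never changes tensor shape,
stride-2 blocks halve spatial dims, and residual blocks require matching
channel counts.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import concat

__all__ = [
    "ConfigError", "ShapeError", "ConvBnAct", "DWConv", "Focus", "Bottleneck",
    "C3", "SPP", "Concat", "GhostConv", "GhostBottleneck", "C3Ghost",
    "ChannelAttention", "SpatialAttention", "CBAM", "SqueezeExcite", "CoordAtt",
    "make_attention", "MBConvA", "C3MB", "Detect",
]


class ConfigError(ValueError):
    """A block was configured with inconsistent hyperparameters."""


class ShapeError(ValueError):
    """An input tensor does not meet a block's shape contract."""


class ConvBnAct(nn.Module):
    """k x k convolution (no bias) -> batch norm -> activation."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, g: int = 1, act: str = "silu"):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, p, groups=g, bias=False)
        self.bn = nn.BatchNorm2d(c2)
        self.act = nn.Activation(act)

    def forward(self, x):
        if x.shape[1] != self.conv.c1:
            raise ShapeError(
                f"expected {self.conv.c1} input channels, got {x.shape[1]}")
        return self.act(self.bn(self.conv(x)))


class DWConv(ConvBnAct):
    """Depthwise convolution (groups = channels)."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 act: str = "silu"):
        if c2 % c1:
            raise ConfigError("depthwise conv needs c2 divisible by c1")
        super().__init__(c1, c2, k, s, g=c1, act=act)


class Focus(nn.Module):
    """Space-to-depth 2x2 slicing then convolution: (c,h,w) -> (4c,h/2,w/2)."""

    def __init__(self, c1: int, c2: int, k: int = 3, act: str = "silu"):
        super().__init__()
        self.conv = ConvBnAct(4 * c1, c2, k, 1, act=act)

    def forward(self, x):
        return self.conv(concat([
            x[:, :, ::2, ::2], x[:, :, 1::2, ::2],
            x[:, :, ::2, 1::2], x[:, :, 1::2, 1::2]], axis=1))


class Bottleneck(nn.Module):
    """Classic residual bottleneck: 1x1 then 3x3, optional identity add."""

    def __init__(self, c1: int, c2: int, shortcut: bool = True, e: float = 1.0,
                 act: str = "silu"):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBnAct(c1, c_, 1, 1, act=act)
        self.cv2 = ConvBnAct(c_, c2, 3, 1, act=act)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class _CSPStage(nn.Module):
    """Two-branch cross-stage-partial stage of the C3 form.

    Branch A: 1x1 conv then ``n`` stacked inner blocks; branch B: 1x1
    conv; concatenate; final 1x1 conv.  Subclasses choose the inner
    block.
    """

    def __init__(self, c1: int, c2: int, n: int, inner, e: float = 0.5,
                 act: str = "silu"):
        super().__init__()
        if n < 1:
            raise ConfigError("CSP stage needs at least one inner block")
        c_ = int(c2 * e)
        self.cv1 = ConvBnAct(c1, c_, 1, 1, act=act)
        self.cv2 = ConvBnAct(c1, c_, 1, 1, act=act)
        self.cv3 = ConvBnAct(2 * c_, c2, 1, 1, act=act)
        self.m = nn.Sequential(*[inner(c_) for _ in range(n)])

    def forward(self, x):
        return self.cv3(concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3(_CSPStage):
    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True,
                 e: float = 0.5, act: str = "silu"):
        super().__init__(c1, c2, n,
                         lambda c: Bottleneck(c, c, shortcut, 1.0, act), e, act)


class SPP(nn.Module):
    """Spatial pyramid pooling over kernels (5, 9, 13), then projection."""

    def __init__(self, c1: int, c2: int, ks=(5, 9, 13), act: str = "silu"):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBnAct(c1, c_, 1, 1, act=act)
        self.cv2 = ConvBnAct(c_ * (len(ks) + 1), c2, 1, 1, act=act)
        self.ks = tuple(ks)

    def forward(self, x):
        x = self.cv1(x)
        return self.cv2(concat(
            [x] + [nn.max_pool2d(x, k, 1, k // 2) for k in self.ks], axis=1))


class Concat(nn.Module):
    def __init__(self, axis: int = 1):
        super().__init__()
        self.axis = axis

    def forward(self, xs):
        if self.axis != 1:
            return concat(xs, axis=self.axis)
        hw = {tuple(x.shape[2:]) for x in xs}
        if len(hw) > 1:
            raise ShapeError(f"concat with mismatched spatial dims: {sorted(hw)}")
        return concat(xs, axis=1)


# -- ghost family --------------------------------------------------------

class GhostConv(nn.Module):
    """Ghost module: intrinsic maps by ordinary conv, ghost maps by cheap
    5x5 depthwise conv, concatenated (s = 2: half intrinsic, half ghost)."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 act: str = "silu", dw_k: int = 5):
        super().__init__()
        if c2 % 2:
            raise ConfigError(f"GhostConv needs even out_channels, got {c2}")
        c_ = c2 // 2
        self.cv1 = ConvBnAct(c1, c_, k, s, act=act)          # intrinsic maps
        self.cv2 = ConvBnAct(c_, c_, dw_k, 1, g=c_, act=act)  # ghost maps

    def forward(self, x):
        y = self.cv1(x)
        return concat([y, self.cv2(y)], axis=1)


class GhostBottleneck(nn.Module):
    """Residual block of two stacked Ghost modules (stride 1).

    Activation is enabled on the first Ghost module only; the second is
    linear, following the ghost-net convention.  ``hidden_ratio`` sets
    the width of the intermediate maps relative to ``c2``.
    """

    def __init__(self, c1: int, c2: int, act: str = "silu",
                 hidden_ratio: float = 0.5, shortcut: bool = True,
                 dw: bool = True):
        super().__init__()
        if shortcut and c1 != c2:
            raise ConfigError(
                f"GhostBottleneck shortcut needs c1 == c2, got {c1} != {c2}")
        c_ = max(2, int(round(c2 * hidden_ratio / 2)) * 2)
        self.gc1 = GhostConv(c1, c_, 1, 1, act=act)
        # linear 3x3 depthwise stage between the two ghost convs
        self.dw = DWConv(c_, c_, 3, 1, act="none") if dw else nn.Identity()
        self.gc2 = GhostConv(c_, c2, 1, 1, act="none")
        self.add = shortcut

    def forward(self, x):
        y = self.gc2(self.dw(self.gc1(x)))
        return x + y if self.add else y


class C3Ghost(_CSPStage):
    """CSP stage whose inner blocks are GhostBottlenecks."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True,
                 e: float = 0.5, act: str = "silu"):
        super().__init__(c1, c2, n,
                         lambda c: GhostBottleneck(c, c, act, shortcut=shortcut),
                         e, act)


# -- attention gates -----------------------------------------------------

class ChannelAttention(nn.Module):
    """Global max+avg pooled features through a shared bottleneck MLP."""

    def __init__(self, c: int, reduction: int = 16):
        super().__init__()
        if c < reduction:
            raise ConfigError(f"channels {c} smaller than reduction {reduction}")
        mid = max(1, c // reduction)
        self.fc1 = nn.Conv2d(c, mid, 1, bias=True)
        self.fc2 = nn.Conv2d(mid, c, 1, bias=True)

    def _mlp(self, v):
        return self.fc2(self.fc1(v).maximum(0.0))

    def forward(self, x):
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.max_reduce(3, keepdims=True).max_reduce(2, keepdims=True)
        return x * (self._mlp(avg) + self._mlp(mx)).sigmoid()


class SpatialAttention(nn.Module):
    """Channelwise max+mean maps through a k x k conv -> sigmoid gate."""

    def __init__(self, k: int = 3):
        super().__init__()
        if k % 2 == 0:
            raise ConfigError("spatial attention kernel must be odd")
        self.conv = nn.Conv2d(2, 1, k, p=k // 2, bias=True)

    def forward(self, x):
        pooled = concat([x.mean(axis=1, keepdims=True),
                         x.max_reduce(1, keepdims=True)], axis=1)
        return x * self.conv(pooled).sigmoid()


class CBAM(nn.Module):
    """Channel then spatial attention, applied in that fixed order.

    Defaults (reduction 16, 3x3 spatial conv) are the ones used inside
    MBConvA; any odd spatial kernel is accepted.
    """

    def __init__(self, c: int, reduction: int = 16, spatial_k: int = 3):
        super().__init__()
        self.channel = ChannelAttention(c, reduction)
        self.spatial = SpatialAttention(spatial_k)

    def forward(self, x):
        return self.spatial(self.channel(x))


class SqueezeExcite(nn.Module):
    """Squeeze-and-excitation channel gate (global avg pool -> MLP)."""

    def __init__(self, c: int, reduction: int = 4):
        super().__init__()
        mid = max(1, c // reduction)
        self.fc1 = nn.Conv2d(c, mid, 1, bias=True)
        self.fc2 = nn.Conv2d(mid, c, 1, bias=True)

    def forward(self, x):
        v = x.mean(axis=(2, 3), keepdims=True)
        return x * self.fc2(self.fc1(v).maximum(0.0)).sigmoid()


class CoordAtt(nn.Module):
    """Coordinate attention: two 1-D pooled encodings share a bottleneck,
    then per-axis sigmoid gates restore positional sensitivity."""

    def __init__(self, c: int, reduction: int = 32):
        super().__init__()
        mid = max(8, c // reduction)
        self.conv1 = nn.Conv2d(c, mid, 1, bias=True)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv_h = nn.Conv2d(mid, c, 1, bias=True)
        self.conv_w = nn.Conv2d(mid, c, 1, bias=True)

    def forward(self, x):
        n, c, h, w = x.shape
        xh = x.mean(axis=3, keepdims=True)                    # (n,c,h,1)
        xw = x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (n,c,w,1)
        y = concat([xh, xw], axis=2)
        y = nn.ACTIVATIONS["hard_swish"](self.bn1(self.conv1(y)))
        ah = self.conv_h(y[:, :, :h]).sigmoid()
        aw = self.conv_w(y[:, :, h:]).sigmoid().transpose(0, 1, 3, 2)
        return x * ah * aw


def make_attention(kind: str, c: int) -> nn.Module:
    """Attention factory for the MBConvA slot (``none``/``cbam``/``se``/``ca``)."""
    if kind == "none":
        return nn.Identity()
    if kind == "cbam":
        return CBAM(c)
    if kind == "se":
        return SqueezeExcite(c)
    if kind == "ca":
        return CoordAtt(c)
    raise ConfigError(f"unknown attention kind {kind!r}")


# -- inverted residual bottleneck with attention -------------------------

class MBConvA(nn.Module):
    """Mobile inverted residual bottleneck with an attention slot.

    1x1 expansion conv (activated) -> 3x3 depthwise conv (linear, no
    activation) -> attention on the expanded maps -> 1x1 linear
    projection; identity shortcut when shapes allow.
    """

    def __init__(self, c1: int, c2: int, expansion: float = 6.0,
                 attention: str = "cbam", act: str = "gelu", s: int = 1):
        super().__init__()
        if expansion < 1:
            raise ConfigError(f"expansion ratio must be >= 1, got {expansion}")
        ce = int(round(c1 * expansion))
        self.expand = ConvBnAct(c1, ce, 1, 1, act=act)
        self.dw = ConvBnAct(ce, ce, 3, s, g=ce, act="none")
        self.attn = make_attention(attention, ce)
        self.project = ConvBnAct(ce, c2, 1, 1, act="none")
        self.add = (c1 == c2) and s == 1

    def forward(self, x):
        y = self.project(self.attn(self.dw(self.expand(x))))
        return x + y if self.add else y


class C3MB(_CSPStage):
    """CSP stage whose inner blocks are MBConvA."""

    def __init__(self, c1: int, c2: int, n: int = 1, expansion: float = 6.0,
                 attention: str = "cbam", e: float = 0.5, act: str = "silu"):
        super().__init__(
            c1, c2, n,
            lambda c: MBConvA(c, c, expansion, attention, act), e, act)


# -- detection head ------------------------------------------------------

class Detect(nn.Module):
    """Anchor-based prediction head: one 1x1 conv per scale emitting
    ``na * (nc + 5)`` channels (box xywh + objectness + class scores)."""

    def __init__(self, nc: int, anchors, ch):
        super().__init__()
        self.nc = nc
        self.no = nc + 5
        self.nl = len(anchors)
        if len(ch) != self.nl:
            raise ConfigError(
                f"{len(ch)} input scales for {self.nl} anchor groups")
        self.na = len(anchors[0]) // 2
        self.anchors = np.asarray(anchors, dtype=np.float32).reshape(
            self.nl, self.na, 2)  # pixel units, buffer (not a parameter)
        self.m = nn.Sequential(
            *[nn.Conv2d(c, self.no * self.na, 1, bias=True) for c in ch])
        self.stride = np.ones(self.nl, dtype=np.float32)  # set by the model

    def forward(self, xs):
        out = []
        for i, x in enumerate(xs):
            n, _, ny, nx = x.shape
            y = self.m.mods[i](x)
            out.append(y.reshape(n, self.na, self.no, ny, nx)
                        .transpose(0, 1, 3, 4, 2))  # (n, na, ny, nx, no)
        return out
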