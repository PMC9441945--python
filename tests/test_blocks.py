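"""Block-level contracts: shapes, ghost-module channel split and cheap-op
cost, attention invariants, residual identities and activation curves."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from mgayolo import nn
from mgayolo.blocks import (CBAM, C3, C3MB, SPP, Bottleneck, C3Ghost,
                            ConfigError, ConvBnAct, CoordAtt, Focus,
                            GhostBottleneck, GhostConv, MBConvA, ShapeError,
                            SqueezeExcite)
from mgayolo.nn import Tensor, no_grad
from mgayolo.nn.layers import gelu, profile_macs


def _x(c, h, w, n=1, seed=0):
    r = np.random.default_rng(seed)
    return Tensor(r.normal(0, 1, (n, c, h, w)).astype(np.float32))


def _macs_of(module, x):
    with no_grad(), profile_macs() as prof:
        module.eval()
        module(x)
    return sum(m for mod, m in prof if isinstance(mod, nn.Conv2d))


# -- ghost convolution ---------------------------------------------------

def test_ghost_conv_output_is_half_intrinsic_half_ghost():
    gc = GhostConv(64, 128, 1, 1)
    out = gc(_x(64, 32, 32))
    assert out.shape == (1, 128, 32, 32)
    # first half of channels is the primary conv output, i.e. equals cv1
    with no_grad():
        y = gc.cv1(_x(64, 32, 32))
    assert np.allclose(out.data[:, :64], y.data, atol=1e-5)


def test_ghost_conv_stride_two_halves_spatial_dims():
    gc = GhostConv(16, 16, 3, 2)
    assert gc(_x(16, 8, 8)).shape == (1, 16, 4, 4)


def test_ghost_conv_rejects_odd_out_channels():
    with pytest.raises(ConfigError):
        GhostConv(16, 15)


def test_ghost_conv_rejects_channel_mismatch():
    with pytest.raises(ShapeError):
        GhostConv(16, 32)(_x(8, 8, 8))


def test_ghost_conv_mac_ratio_approaches_half_of_dense_conv():
    """Cheap-operation speed-up: the ghost module should cost ~1/s (s=2)
    of the equivalent dense convolution, within 15% for c >= 64."""
    for c in (64, 128, 256):
        x = _x(c, 16, 16)
        dense = _macs_of(ConvBnAct(c, c, 3, 1), x)
        ghost = _macs_of(GhostConv(c, c, 3, 1), x)
        assert abs(ghost / dense - 0.5) < 0.15


def test_conv_mac_product_formula():
    """MACs of a k x k conv = h' * w' * k * k * c * n."""
    conv = nn.Conv2d(16, 32, 3, 1, 1, bias=False)
    with no_grad(), profile_macs() as prof:
        conv(_x(16, 10, 10))
    assert prof[0][1] == 10 * 10 * 3 * 3 * 16 * 32 == 460_800


# -- ghost bottleneck ----------------------------------------------------

def test_ghost_bottleneck_preserves_shape():
    gb = GhostBottleneck(32, 32)
    assert gb(_x(32, 16, 16)).shape == (1, 32, 16, 16)


def test_ghost_bottleneck_zero_weights_is_identity():
    gb = GhostBottleneck(32, 32)
    for p in gb.parameters():
        p.data[:] = 0.0
    x = _x(32, 8, 8)
    assert np.allclose(gb(x).data, x.data)


def test_ghost_bottleneck_shortcut_needs_matching_channels():
    with pytest.raises(ConfigError):
        GhostBottleneck(32, 64, shortcut=True)


def test_ghost_bottleneck_cheaper_than_dense_bottleneck():
    assert (GhostBottleneck(32, 32).num_parameters()
            < Bottleneck(32, 32).num_parameters())


# -- attention -----------------------------------------------------------

@pytest.mark.parametrize("attn_cls", [CBAM, SqueezeExcite, CoordAtt])
def test_attention_preserves_shape(attn_cls):
    m = attn_cls(64)
    x = _x(64, 12, 12)
    assert m(x).shape == x.shape


@pytest.mark.parametrize("attn_cls", [CBAM, SqueezeExcite, CoordAtt])
def test_attention_weights_strictly_shrink_magnitude(attn_cls):
    """Sigmoid gates lie in (0,1): |output| < |input| elementwise
    wherever the input is non-zero."""
    m = attn_cls(64)
    x = _x(64, 6, 6, seed=3)
    y = m(x)
    nz = np.abs(x.data) > 1e-6
    assert np.all(np.abs(y.data[nz]) < np.abs(x.data[nz]) + 1e-7)


def test_cbam_zero_logits_halves_input():
    """With all attention logits zero, each sigmoid gate is 0.5, so the
    channel and spatial stages jointly scale the input by 0.25."""
    m = CBAM(32)
    for p in m.parameters():
        p.data[:] = 0.0
    x = _x(32, 5, 5)
    assert np.allclose(m(x).data, 0.25 * x.data, atol=1e-6)


def test_cbam_spatial_map_constant_for_uniform_input():
    """Uniform input -> constant pooled maps -> constant attention away
    from the padded border of the spatial convolution."""
    m = CBAM(16)
    x = Tensor(np.full((1, 16, 8, 8), 0.7, np.float32))
    with no_grad():
        gated = m.spatial(x)
    k = m.spatial.conv.k // 2
    interior = (gated.data / x.data)[:, :, k:-k, k:-k]
    assert np.allclose(interior, interior[:, :, :1, :1], atol=1e-6)


def test_channel_attention_needs_enough_channels():
    with pytest.raises(ConfigError):
        CBAM(8, reduction=16)


# -- inverted residual bottleneck ---------------------------------------

def test_mbconv_preserves_shape_with_shortcut():
    m = MBConvA(64, 64, expansion=1)
    assert m(_x(64, 20, 20)).shape == (1, 64, 20, 20)


def test_mbconv_zeroed_projection_is_identity():
    m = MBConvA(32, 32, expansion=2)
    m.project.conv.weight.data[:] = 0.0
    m.project.bn.weight.data[:] = 1.0
    m.project.bn.bias.data[:] = 0.0
    x = _x(32, 6, 6)
    m.eval()
    assert np.allclose(m(x).data, x.data, atol=1e-6)


def test_mbconv_rejects_fractional_expansion():
    with pytest.raises(ConfigError):
        MBConvA(32, 32, expansion=0.5)


def test_mbconv_attention_swap_changes_params_not_shape():
    cbam = MBConvA(64, 64, expansion=2, attention="cbam")
    se = MBConvA(64, 64, expansion=2, attention="se")
    assert cbam.num_parameters() != se.num_parameters()
    x = _x(64, 8, 8)
    assert cbam(x).shape == se(x).shape


# -- CSP stages ----------------------------------------------------------

def test_csp_stage_preserves_spatial_dims():
    stage = C3MB(128, 128, n=1, expansion=2)
    assert stage(_x(128, 40, 40)).shape == (1, 128, 40, 40)


def test_csp_repeats_stack_exactly_n_inner_blocks():
    stage = C3Ghost(64, 64, n=2)
    assert len(stage.m) == 2
    assert all(isinstance(b, GhostBottleneck) for b in stage.m)


def test_c3ghost_cheaper_than_c3():
    assert (C3Ghost(128, 128, n=1).num_parameters()
            < C3(128, 128, n=1).num_parameters())


def test_csp_rejects_zero_repeats():
    with pytest.raises(ConfigError):
        C3(32, 32, n=0)


# -- standard blocks -----------------------------------------------------

def test_focus_space_to_depth():
    f = Focus(3, 32, 3)
    assert f.conv.conv.c1 == 12
    assert f(_x(3, 64, 64)).shape == (1, 32, 32, 32)


def test_spp_preserves_spatial_dims_and_quadruples_prepool_channels():
    spp = SPP(64, 64)
    assert spp.cv2.conv.c1 == 4 * 32  # c1/2 pooled at {5,9,13} + identity
    assert spp(_x(64, 16, 16)).shape == (1, 64, 16, 16)


# -- activation curves ---------------------------------------------------

def test_gelu_matches_normal_cdf_form():
    x = np.linspace(-4, 4, 41).astype(np.float32)
    y = gelu(Tensor(x)).data
    assert np.allclose(y, x * norm.cdf(x), atol=1e-5)
    assert abs(float(gelu(Tensor(np.float32(0.0))).data)) < 1e-7
    assert abs(float(gelu(Tensor(np.float32(-1.0))).data) + 0.1587) < 1e-3


def test_gelu_close_to_sigmoid_approximation():
    """x * sigmoid(1.702 x) tracks GELU closely on [-5, 5]; the true
    sup-norm of the difference is ~0.0203, attained near |x| ~ 2.3."""
    x = np.linspace(-5, 5, 2001)
    exact = x * norm.cdf(x)
    approx = x * expit(1.702 * x)
    assert np.abs(exact - approx).max() < 0.021


def test_gelu_has_single_negative_minimum_near_minus_three_quarters():
    x = np.linspace(-5, 5, 10001)
    y = x * norm.cdf(x)
    i = int(np.argmin(y))
    assert -0.9 < x[i] < -0.6
    assert y[i] < 0
    # non-monotonic: decreasing before the minimum, increasing after
    assert y[i - 200] > y[i] < y[i + 200]
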