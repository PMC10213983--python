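"""Multi-scale extractor and CBAM attention: shapes, bounds, wiring, and an
independent straight-from-the-equations oracle."""

import numpy as np
import pytest

from somnexit.efem import (
    CBAM,
    EFEM,
    ChannelAttention,
    EfemConfig,
    SpatialAttention,
    apply_channel_attention,
    apply_spatial_attention,
    receptive_seconds,
)
from somnexit.nn import Tensor

from conftest import tiny_model_config


def test_receptive_windows_at_100hz():
    assert receptive_seconds(64, 100.0) == pytest.approx(0.64)
    assert receptive_seconds(512, 100.0) == pytest.approx(5.12)


def test_first_conv_output_positions():
    # valid padding, length 3000, kernel 64, stride 8
    assert (3000 - 64) // 8 + 1 == 368
    cfg = tiny_model_config()
    efem = EFEM(cfg.efem["EEG"], np.random.default_rng(0))
    out = efem.small.mods[0](Tensor(np.zeros((1, 1, 3000))))
    assert out.shape[-1] == 368


def test_signal_shorter_than_kernel_names_branch():
    cfg = tiny_model_config()
    efem = EFEM(cfg.efem["EEG"], np.random.default_rng(0))
    # 1208 samples: the small branch fits, the 512-kernel branch cannot
    # complete its pooling stack
    with pytest.raises(ValueError, match="large branch"):
        efem.multi_scale(Tensor(np.zeros((1, 1, 1208))))
    with pytest.raises(ValueError, match="small branch"):
        efem.multi_scale(Tensor(np.zeros((1, 1, 300))))


class TestChannelAttention:
    def test_weights_strictly_inside_unit_interval(self, rng):
        ca = ChannelAttention(8, 4, rng)
        f = Tensor(rng.standard_normal((2, 8, 12)))
        w = ca(f).data
        assert (w > 0).all() and (w < 1).all()

    def test_zero_mlp_gives_half_everywhere(self, rng):
        ca = ChannelAttention(8, 4, rng)
        for p in ca.parameters():
            p.data[:] = 0
        w = ca(Tensor(rng.standard_normal((1, 8, 5)))).data
        assert np.allclose(w, 0.5)

    def test_constant_zero_channel_with_identity_mlp(self):
        """Hand evaluation on a 2 x 4 grid, r = 1 identity MLP."""
        ca = ChannelAttention(2, 1, np.random.default_rng(0))
        ca.w0.data = np.eye(2)
        ca.b0.data[:] = 0
        ca.w1.data = np.eye(2)
        ca.b1.data[:] = 0
        f = np.array([[0.0, 0.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0]])
        w = ca(Tensor(f[None])).data[0]
        assert w[0] == pytest.approx(0.5)  # sigma(0 + 0)
        # second channel: avg 2.5, max 4 -> sigma(6.5)
        assert w[1] == pytest.approx(1 / (1 + np.exp(-6.5)))

    def test_apply_is_row_rescaling(self):
        f = Tensor(np.arange(6, dtype=float).reshape(1, 2, 3))
        mc = Tensor(np.array([[0.5, 1.0]]))
        out = apply_channel_attention(f, mc).data
        assert np.allclose(out[0, 0], f.data[0, 0] * 0.5)
        assert np.allclose(out[0, 1], f.data[0, 1])
        assert np.allclose(
            apply_channel_attention(f, Tensor(np.ones((1, 2)))).data, f.data
        )
        assert np.allclose(
            apply_channel_attention(f, Tensor(np.zeros((1, 2)))).data, 0
        )


class TestSpatialAttention:
    def test_same_padding_preserves_length_and_bounds(self, rng):
        sa = SpatialAttention(7, rng)
        f = Tensor(rng.standard_normal((2, 3, 10)))
        w = sa(f).data
        assert w.shape == (2, 1, 10)
        assert (w > 0).all() and (w < 1).all()

    def test_zero_conv_gives_half(self, rng):
        sa = SpatialAttention(7, rng)
        for p in sa.parameters():
            p.data[:] = 0
        assert np.allclose(sa(Tensor(rng.standard_normal((1, 2, 8)))).data, 0.5)

    def test_constant_input_interior_is_constant(self, rng):
        """Constant F' makes avg map = max map; away from the padded edges
        the attention map is constant."""
        sa = SpatialAttention(7, rng)
        f = Tensor(np.full((1, 2, 12), 3.0))
        w = sa(f).data[0, 0]
        assert np.allclose(w[3:-3], w[5], atol=1e-12)

    def test_apply_is_column_rescaling(self):
        f = Tensor(np.ones((1, 2, 4)))
        ms = Tensor(np.array([[[1.0, 0.0, 1.0, 0.0]]]))
        out = apply_spatial_attention(f, ms).data
        assert np.allclose(out[0, :, 0], 1) and np.allclose(out[0, :, 1], 0)


def cbam_oracle(f, ca, sa):
    """Scalar-loop evaluation of the attention equations on one C x d grid."""
    C, d = f.shape
    w0, b0 = ca.w0.data, ca.b0.data
    w1, b1 = ca.w1.data, ca.b1.data

    def mlp(v):
        h = np.maximum(v @ w0 + b0, 0.0)
        return h @ w1 + b1

    avg = np.array([f[c].mean() for c in range(C)])
    mx = np.array([f[c].max() for c in range(C)])
    mc = 1 / (1 + np.exp(-(mlp(avg) + mlp(mx))))
    f1 = np.array([[mc[c] * f[c, j] for j in range(d)] for c in range(C)])

    avg_s = np.array([f1[:, j].mean() for j in range(d)])
    max_s = np.array([f1[:, j].max() for j in range(d)])
    stacked = np.stack([avg_s, max_s])  # (2, d)
    k = sa.conv.kernel
    wconv = sa.conv.weight.data.reshape(2, k)  # (c_in, k)
    bias = sa.conv.bias.data[0]
    left = (k - 1) // 2
    padded = np.pad(stacked, ((0, 0), (left, k - 1 - left)))
    conv = np.array([
        sum(padded[c, j + t] * wconv[c, t] for c in range(2) for t in range(k))
        + bias
        for j in range(d)
    ])
    ms = 1 / (1 + np.exp(-conv))
    return np.array([[ms[j] * f1[c, j] for j in range(d)] for c in range(C)])


def test_cbam_matches_scalar_loop_oracle(rng):
    cbam = CBAM(3, 1, 7, rng)
    f = rng.standard_normal((3, 10)) * 0.3
    expected = cbam_oracle(f, cbam.channel, cbam.spatial)
    got = cbam(Tensor(f[None])).data[0]
    assert np.abs(got - expected).max() < 1e-6


def test_channel_attention_applied_before_spatial(rng):
    """Sentinel wiring check: zeroing the channel MLP must scale the input
    seen by the spatial module by 0.5 exactly."""
    cbam = CBAM(2, 1, 7, rng)
    for p in cbam.channel.parameters():
        p.data[:] = 0
    f = rng.standard_normal((1, 2, 9))
    seen = {}
    orig = cbam.spatial.forward

    def spy(x):
        seen["input"] = x.data.copy()
        return orig(x)

    object.__setattr__(cbam.spatial, "forward", spy)
    try:
        cbam(Tensor(f))
    finally:
        object.__setattr__(cbam.spatial, "forward", orig)
    assert np.allclose(seen["input"], 0.5 * f)


class TestEfemForward:
    def test_output_shape_fixed_by_config(self, tiny_config, rng):
        efem = EFEM(tiny_config.efem["EEG"], rng)
        a = efem(Tensor(rng.standard_normal((2, 3000)))).data
        b = efem(Tensor(rng.standard_normal((2, 3000)) * 5)).data
        assert a.shape == b.shape == (2,) + tiny_config.efem["EEG"].output_shape(3000)

    def test_gradient_reaches_first_conv(self, tiny_config, rng):
        efem = EFEM(tiny_config.efem["EEG"], rng)
        efem.train()
        out = efem(Tensor(rng.standard_normal((2, 3000))))
        (out ** 2.0).sum().backward()
        first_conv = efem.small.mods[0]
        assert first_conv.weight.grad is not None
        assert np.abs(first_conv.weight.grad).max() > 0

    def test_shape_preservation_through_cbam(self, rng):
        cbam = CBAM(4, 4, 7, rng)
        f = Tensor(rng.standard_normal((3, 4, 11)))
        assert cbam(f).shape == f.shape

    def test_reduction_must_divide_channels(self):
        with pytest.raises(ValueError, match="divide"):
            EfemConfig(cbam_reduction=7)
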