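"""Channel/spatial attention and cross-scale sharing."""

import numpy as np
import pytest
from scipy import ndimage

from wattdet import nn
from wattdet.attention import (SOBEL_X, SOBEL_Y, ChannelAttention,
                               ScsaBlockParams, ScsaConfig, ScsaGate,
                               SpatialAttention, channel_attention,
                               scsa_block, sobel_edges, spatial_attention)
from wattdet.errors import ConfigurationError, DimensionError


def zeroed(module):
    for p in module.parameters():
        p.data[:] = 0.0
    return module


class TestChannelAttention:
    def test_zero_mlp_gives_half_gate(self, rng):
        ca = zeroed(ChannelAttention(4))
        x = rng.standard_normal((4, 5, 5)).astype(np.float32)
        mc, out = channel_attention(x, ca)
        assert np.allclose(mc, 0.5)
        assert np.allclose(out, 0.5 * x, atol=1e-6)

    def test_single_channel_descriptors(self):
        # z_avg = 3, z_max = 6 for [[0,2],[4,6]]; with identity-like MLP
        # (relu passthrough) the gate is sigmoid(relu(3) + relu(6))
        ca = ChannelAttention(1, reduction=1)
        ca.fc1.weight.data[:] = 1.0
        ca.fc1.bias.data[:] = 0.0
        ca.fc2.weight.data[:] = 1.0
        ca.fc2.bias.data[:] = 0.0
        x = np.array([[[0.0, 2.0], [4.0, 6.0]]])
        mc, _ = channel_attention(x, ca)
        assert mc.item() == pytest.approx(1 / (1 + np.exp(-9.0)), abs=1e-6)

    def test_constant_channel_descriptors_equal(self):
        ca = ChannelAttention(1, reduction=1)
        ca.fc1.weight.data[:] = 1.0
        ca.fc1.bias.data[:] = 0.0
        ca.fc2.weight.data[:] = 1.0
        ca.fc2.bias.data[:] = 0.0
        c = 2.5
        mc, _ = channel_attention(np.full((1, 3, 3), c, dtype=np.float32), ca)
        # z_avg = z_max = c, shared MLP applied to both and summed
        assert mc.item() == pytest.approx(1 / (1 + np.exp(-2 * c)), abs=1e-6)

    def test_gate_strictly_in_unit_interval(self, rng):
        ca = ChannelAttention(8)
        mc, _ = channel_attention(
            rng.standard_normal((8, 4, 4)).astype(np.float32) * 10, ca)
        assert np.all(mc > 0) and np.all(mc < 1)

    def test_bad_shape(self, rng):
        with pytest.raises(DimensionError):
            channel_attention(rng.standard_normal((4, 4)), ChannelAttention(4))


class TestSobel:
    def test_constant_map_zero(self):
        assert np.allclose(sobel_edges(np.full((5, 7), 2.0)), 0.0)

    def test_vertical_step_response(self):
        # columns 0..2 are 0, columns 3..5 are 1; at the step boundary the
        # horizontal kernel sums to 4x the step height, the vertical to 0
        x = np.zeros((5, 6))
        x[:, 3:] = 1.0
        g = sobel_edges(x)
        gx = ndimage.correlate(x, SOBEL_X.astype(float), mode="mirror")
        gy = ndimage.correlate(x, SOBEL_Y.astype(float), mode="reflect")
        assert gx[2, 2] == pytest.approx(4.0)
        assert gy[2, 2] == pytest.approx(0.0)
        assert g[2, 2] == pytest.approx(4.0)

    def test_nonnegative(self, rng):
        assert (sobel_edges(rng.standard_normal((9, 9))) >= 0).all()

    def test_too_small(self):
        with pytest.raises(DimensionError):
            sobel_edges(np.zeros((2, 5)))


class TestSpatialAttention:
    def test_constant_input_uniform_gate(self):
        sa = SpatialAttention()
        bias = float(sa.conv.bias.data[0])
        x = np.full((3, 6, 6), 1.3, dtype=np.float32)
        ms, _ = spatial_attention(x, sa)
        # interior: mean=max=const, edge=0 -> logits = w.(const maps)+b,
        # uniform away from padding effects
        interior = ms[0, 3, 3]
        assert np.allclose(ms[0, 3:4, 3:4], interior)
        sa_zero = zeroed(SpatialAttention())
        ms0, _ = spatial_attention(x, sa_zero)
        assert np.allclose(ms0, 0.5)
        del bias

    def test_never_amplifies(self, rng):
        sa = SpatialAttention()
        x = rng.standard_normal((4, 8, 8)).astype(np.float32)
        ms, y = spatial_attention(x, sa)
        assert np.all(np.abs(y) <= np.abs(x) + 1e-7)
        assert np.all((np.abs(y) < np.abs(x)) | (x == 0))

    def test_matches_three_map_concat_oracle(self, rng):
        sa = SpatialAttention()
        x = rng.standard_normal((4, 8, 8)).astype(np.float32)
        ms, _ = spatial_attention(x, sa)
        # independent evaluation with scipy on the same weights
        mean_map = x.mean(axis=0)
        max_map = x.max(axis=0)
        edge_map = np.sqrt(
            ndimage.correlate(mean_map.astype(np.float64),
                              SOBEL_X.astype(float), mode="mirror") ** 2
            + ndimage.correlate(mean_map.astype(np.float64),
                                SOBEL_Y.astype(float), mode="mirror") ** 2
            + 1e-12)
        stacked = np.stack([mean_map, max_map, edge_map])
        w = sa.conv.weight.data[0].astype(np.float64)
        logit = sum(
            ndimage.correlate(stacked[c], w[c], mode="constant")
            for c in range(3)) + float(sa.conv.bias.data[0])
        expected = 1 / (1 + np.exp(-logit))
        assert np.abs(ms[0] - expected).max() < 1e-6


class TestScsaBlock:
    def _features(self, rng, stages):
        sizes = {"P2": 16, "P3": 8, "P4": 4, "P5": 2}
        return {s: rng.standard_normal((4, sizes[s], sizes[s]))
                .astype(np.float32) for s in stages}

    def test_single_stage_cross_scale_noop(self, rng):
        feats = self._features(rng, ["P3"])
        cfg_on = ScsaConfig(stages=("P3",), cross_scale=True)
        params = ScsaBlockParams.build({"P3": 4}, cfg_on)
        out_on = scsa_block(feats, cfg_on, params)
        out_off = scsa_block(feats, ScsaConfig(stages=("P3",),
                                               cross_scale=False), params)
        assert np.allclose(out_on["P3"], out_off["P3"])

    def test_identical_resampled_maps_unchanged(self, rng):
        # constant inputs with zeroed parameters -> both stages produce the
        # uniform 0.5 map; averaging equal maps changes nothing
        feats = {s: np.full((2, n, n), 1.0, dtype=np.float32)
                 for s, n in (("P3", 8), ("P4", 4))}
        cfg = ScsaConfig(stages=("P3", "P4"))
        params = ScsaBlockParams.build({"P3": 2, "P4": 2}, cfg)
        for ca, sa in params.gates.values():
            zeroed(ca)
            zeroed(sa)
        out = scsa_block(feats, cfg, params)
        assert np.allclose(out["P3"], 0.25 * feats["P3"])
        assert np.allclose(out["P4"], 0.25 * feats["P4"])

    def test_two_stage_sharing_is_elementwise_mean(self, rng):
        feats = self._features(rng, ["P3", "P4"])
        cfg = ScsaConfig(stages=("P3", "P4"))
        params = ScsaBlockParams.build({"P3": 4, "P4": 4}, cfg)
        out = scsa_block(feats, cfg, params)
        # recompute by hand: own maps without sharing
        from wattdet.attention import _resample_to
        own = {}
        attended = {}
        for s in ("P3", "P4"):
            ca, sa = params.gates[s]
            _, xc = channel_attention(feats[s], ca)
            ms, _ = spatial_attention(xc, sa)
            own[s] = ms
            attended[s] = xc
        exp_p3 = (own["P3"] + _resample_to(own["P4"], (8, 8))) / 2 \
            * attended["P3"]
        assert np.abs(out["P3"] - exp_p3).max() < 1e-6

    def test_non_nested_resolution_rejected(self, rng):
        feats = {"P3": rng.standard_normal((2, 8, 8)).astype(np.float32),
                 "P4": rng.standard_normal((2, 3, 3)).astype(np.float32)}
        with pytest.raises(ConfigurationError):
            scsa_block(feats, ScsaConfig(stages=("P3", "P4")))

    def test_output_shapes_match_inputs(self, rng):
        feats = self._features(rng, ["P2", "P3", "P4", "P5"])
        out = scsa_block(feats, ScsaConfig(stages=("P2", "P3", "P4", "P5")))
        for s, f in feats.items():
            assert out[s].shape == f.shape

    def test_attention_never_increases_magnitude(self, rng):
        feats = self._features(rng, ["P3", "P4"])
        out = scsa_block(feats, ScsaConfig(stages=("P3", "P4")))
        for s in feats:
            assert np.all(np.abs(out[s]) <= np.abs(feats[s]) + 1e-7)


def test_scsa_gate_zeroed_params_quarter_scaling(rng):
    gate = zeroed(ScsaGate(4))
    x = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
    with nn.no_grad():
        out = gate(nn.Tensor(x))
    assert np.allclose(out.data, 0.25 * x, atol=1e-6)


def test_scsa_config_validation():
    with pytest.raises(ConfigurationError):
        ScsaConfig(reduction=0)
    with pytest.raises(ConfigurationError):
        ScsaConfig(stages=("P9",))
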