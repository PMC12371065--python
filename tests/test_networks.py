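from __future__ import annotations

import numpy as np
import pytest

import _references as ref
from handtremor import networks as nw, nn
from handtremor.nn import Tensor


class TestWap:
    @pytest.mark.parametrize(
        "window, gamma, expected",
        [
            ([1, 2, 3, 4], 0.0, 2.5),
            ([1, 2, 3, 4], 0.5, 1.25),
            ([7, 7], 1.0, 0.0),
            ([5, 9, 13], 1.0, 0.0),
        ],
    )
    def test_known_values(self, window, gamma, expected):
        assert nw.wap(np.array(window, dtype=float), gamma) == pytest.approx(expected)

    def test_matches_scalar_reference(self, rng):
        for _ in range(10):
            window = rng.normal(size=rng.integers(1, 20))
            gamma = float(rng.uniform(0, 1))
            assert nw.wap(window, gamma) == pytest.approx(
                ref.wap_ref(window, gamma), abs=1e-12
            )

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            nw.wap(np.array([]), 0.5)


class TestWapBn:
    def test_vector_oracle_gamma_zero(self):
        z = np.array([1.0, 2.0, 3.0, 4.0])
        out = nw.wap_bn(z, gamma=0.0, eps=1e-5)
        assert np.allclose(out, ref.wap_bn_ref(z, 0.0, 1e-5), atol=1e-9)

    def test_random_inputs_match_reference(self, rng):
        for _ in range(10):
            z = rng.normal(size=8)
            gamma = float(rng.uniform(0, 1))
            assert np.allclose(
                nw.wap_bn(z, gamma), ref.wap_bn_ref(z, gamma, 1e-5), atol=1e-9
            )

    def test_forced_unit_statistic_substitution(self, rng):
        z = rng.normal(size=6)
        out = nw.wap_bn(z, s_j=1.0, eps=1e-5)
        expected = (z - z.mean()) / np.sqrt(z.var() + 1 / (1 + np.exp(-1.0)) + 1e-5)
        assert np.allclose(out, expected, atol=1e-12)

    def test_constant_window_gives_zero(self):
        assert np.allclose(nw.wap_bn(np.full(5, 3.3)), 0.0)

    def test_printed_gamma_one_degeneracy(self, rng):
        """With the pooling weight at 1 the statistic and the output vanish."""
        z = rng.normal(size=10)
        assert np.allclose(nw.wap_bn(z, gamma=1.0), 0.0, atol=1e-12)
        layer = nn.WapBN2d(2, gamma=1.0)
        x = Tensor(rng.normal(size=(3, 2, 4, 4)))
        out = layer(x)
        # affine shift is zero-initialized, so the whole output collapses
        assert np.allclose(out.data, 0.0, atol=1e-12)


class TestMixedPool:
    def test_extremes_are_max_and_avg(self, rng):
        x = rng.normal(size=(2, 3, 4, 4))
        blocks = x.reshape(2, 3, 2, 2, 2, 2)
        assert np.allclose(nw.mixed_pool(x, 1.0), blocks.max(axis=(3, 5)))
        assert np.allclose(nw.mixed_pool(x, 0.0), blocks.mean(axis=(3, 5)))

    def test_bounded_between_avg_and_max(self, rng):
        x = rng.normal(size=(1, 2, 6, 6))
        avg, mx = nw.mixed_pool(x, 0.0), nw.mixed_pool(x, 1.0)
        for lam in (0.25, 0.5, 0.75):
            mixed = nw.mixed_pool(x, lam)
            assert (mixed >= avg - 1e-12).all() and (mixed <= mx + 1e-12).all()

    def test_matches_elementwise_reference(self, rng):
        x = rng.normal(size=(2, 2, 4, 4))
        assert np.allclose(nw.mixed_pool(x, 0.3), ref.mixed_pool_ref(x, 0.3), atol=1e-12)


class TestXorFusion:
    def test_soft_mode_is_absolute_difference(self, rng):
        a, b = rng.normal(size=(2, 4, 4))
        expected = np.array(
            [[abs(a[i, j] - b[i, j]) for j in range(4)] for i in range(4)]
        )
        assert np.allclose(nw.xor_fuse(a, b, "soft"), expected, atol=1e-12)

    def test_identical_inputs_vanish_in_both_modes(self, rng):
        a = rng.normal(size=(4, 4))
        assert not nw.xor_fuse(a, a, "soft").any()
        assert not nw.xor_fuse(a, a, "binary").any()

    def test_binary_mode_is_boolean(self, rng):
        a, b = rng.normal(size=(2, 5, 5))
        out = nw.xor_fuse(a, b, "binary")
        assert set(np.unique(out)) <= {0.0, 1.0}


class TestGhostModule:
    def test_channel_split(self, rng):
        spec = nw.GhostModuleSpec(in_channels=8, out_channels=64, ratio=2)
        module = nw.GhostModule(spec, rng)
        out = module(Tensor(rng.normal(size=(2, 8, 8, 8))))
        assert out.data.shape == (2, 64, 8, 8)
        assert module.primary.weight.data.shape[0] == 32  # primary half

    def test_indivisible_split_rejected(self):
        with pytest.raises(ValueError):
            nw.GhostModuleSpec(in_channels=8, out_channels=63, ratio=2)

    def test_parameter_count_below_dense(self):
        spec = nw.GhostModuleSpec(
            in_channels=16, out_channels=64, ratio=2, primary_kernel=3, cheap_kernel=3
        )
        ghost = nw.ghost_module_param_count(spec)
        dense = nw.dense_conv_param_count(16, 64, 3)
        assert ghost < dense
        # approximately 1/s of the dense cost plus a small depthwise term
        assert ghost == 16 * 32 * 9 + 32 * 9
        for s in (2, 4):
            spec_s = nw.GhostModuleSpec(16, 64, ratio=s, primary_kernel=3)
            assert nw.ghost_module_param_count(spec_s) < dense

    def test_stride_two_halves_spatial_ceil(self, rng):
        spec = nw.GhostModuleSpec(in_channels=4, out_channels=8, stride=2)
        module = nw.GhostModule(spec, rng)
        out = module(Tensor(rng.normal(size=(1, 4, 7, 7))))
        assert out.data.shape[-2:] == (4, 4)  # ceil(7/2)


class TestForwardPasses:
    def test_ghostnet_probabilities(self, rng):
        net = nw.GhostNet(nw.GhostNetSpec(seed=3))
        net.eval()
        probs = net(Tensor(rng.normal(size=(3, 1, 32, 32))))
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_stride1_bottleneck_preserves_shape(self, rng):
        block = nw.GhostBottleneck(16, 16, 16, stride=1, rng=rng)
        x = Tensor(rng.normal(size=(2, 16, 8, 8)))
        block.eval()
        for m in block.modules():
            m.training = False
        assert block(x).data.shape == x.data.shape

    def test_linknet_probabilities_and_input_check(self, rng):
        net = nw.ImprovedLinkNet(nw.LinkNetSpec(seed=3))
        net.eval()
        probs = net(Tensor(rng.normal(size=(2, 1, 32, 32))))
        assert probs.shape == (2, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        with pytest.raises(ValueError, match="multiple of 4"):
            net(Tensor(rng.normal(size=(1, 1, 30, 30))))

    def test_inference_is_bit_identical(self, rng):
        x = Tensor(rng.normal(size=(2, 1, 32, 32)))
        for net in (nw.GhostNet(nw.GhostNetSpec(seed=5)),
                    nw.ImprovedLinkNet(nw.LinkNetSpec(seed=5))):
            net.eval()
            assert np.array_equal(net(x), net(x))

    def test_same_seed_same_weights(self):
        a = nw.GhostNet(nw.GhostNetSpec(seed=8))
        b = nw.GhostNet(nw.GhostNetSpec(seed=8))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    @pytest.mark.parametrize("arch", ["ghostnet", "ilinknet"])
    def test_overfit_eight_samples(self, arch, rng):
        """A 50-step optimization drives cross-entropy below 0.1 on 8 samples."""
        y = np.array([0, 1] * 4)
        x = rng.normal(size=(8, 1, 32, 32)) + y[:, None, None, None]
        model = (
            nw.GhostNet(nw.GhostNetSpec(seed=2))
            if arch == "ghostnet"
            else nw.ImprovedLinkNet(nw.LinkNetSpec(seed=2))
        )
        model.train()
        opt = nn.Adam(model.parameters(), lr=5e-3)
        for _ in range(50):
            loss = nn.cross_entropy(model.logits(Tensor(x)), y)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert float(loss.data) < 0.1


class TestMdscm:
    def test_output_channels_are_sum_of_branches(self, rng):
        net = nw.ImprovedLinkNet(nw.LinkNetSpec(seed=0))
        net.eval()
        x = Tensor(rng.normal(size=(1, 1, 32, 32)))
        c1, c2, c3 = net.spec.encoder_channels
        e1 = Tensor(rng.normal(size=(1, c1, 16, 16)))
        e2 = Tensor(rng.normal(size=(1, c2, 8, 8)))
        e3 = Tensor(rng.normal(size=(1, c3, 8, 8)))
        for m in net.mdscm.modules():
            m.training = False
        out = net.mdscm(x, [e1, e2, e3])
        assert out.data.shape == (1, c1 + c2 + c3, 8, 8)

    def test_wrong_encoder_count_rejected(self, rng):
        net = nw.ImprovedLinkNet(nw.LinkNetSpec(seed=0))
        with pytest.raises(ValueError):
            net.mdscm(Tensor(rng.normal(size=(1, 1, 32, 32))), [])

    def test_gabor_kernel_zero_dc_and_shape(self):
        k = nw.gabor_kernel(np.pi / 4)
        assert k.shape == (7, 7)
        assert k.mean() == pytest.approx(0.0, abs=1e-12)
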