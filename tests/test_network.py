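"""Architecture construction, forward/backward correctness, parameter counts."""

import itertools

import numpy as np
import pytest

from dualpath3d.layers import BatchNorm3D, Conv3D, PReLU, softmax
from dualpath3d.network import (ConstructionError, DualPathNetwork,
                                NetworkConfig, build_network)
from dualpath3d.patch_sampler import PatchPair
from dualpath3d.training import cross_entropy


def mini_cfg(**kw):
    base = dict(n_blocks_per_path=2, feature_maps=(4, 6), residual_pairs=((1, 2),),
                fc_widths=(8,), n_classes=3, dual_path=True, dropout=0.0, seed=7)
    base.update(kw)
    return NetworkConfig(**base)


class TestConstruction:
    def test_default_has_sixteen_path_blocks(self):
        net = build_network(NetworkConfig())
        n_blocks = len(net.local_path.blocks) + len(net.global_path.blocks)
        assert n_blocks == 16
        assert net.cfg.channels == (30, 30, 30, 30, 40, 40, 40, 40)

    def test_single_path_halves_path_parameters(self):
        dual = build_network(mini_cfg(dual_path=True))
        single = build_network(mini_cfg(dual_path=False))
        dual_path_params = sum(p.value.size for p in dual.local_path.params()) + \
            sum(p.value.size for p in dual.global_path.params())
        single_path_params = sum(p.value.size for p in single.local_path.params())
        assert dual_path_params == 2 * single_path_params

    def test_fm_multiplier_doubles_channels(self):
        net = build_network(mini_cfg(fm_multiplier=2.0, dual_path=False))
        assert net.cfg.channels == (8, 12)

    def test_invalid_residual_pair(self):
        with pytest.raises(ConstructionError):
            mini_cfg(residual_pairs=((1, 5),))

    def test_config_json_roundtrip(self):
        cfg = mini_cfg()
        assert NetworkConfig.from_json(cfg.to_json()) == cfg


class TestParameterCounts:
    def test_single_conv_kernel_counts(self):
        rng = np.random.default_rng(0)
        c3 = Conv3D(1, 1, kernel=3, rng=rng, bias=False)
        c5 = Conv3D(1, 1, kernel=5, rng=rng, bias=False)
        assert c3.W.value.size == 27
        assert c5.W.value.size == 125
        assert round(125 / 27, 1) == 4.6

    def test_kernel5_vs_kernel3_conv_weight_ratio(self):
        n3 = build_network(mini_cfg(kernel=3, residual_pairs=(), fc_widths=()))
        n5 = build_network(mini_cfg(kernel=5, residual_pairs=(), fc_widths=()))
        # compare path conv kernels only (head kernels are 1x1x1 in both)
        w3 = sum(b.conv.W.value.size for b in n3.local_path.blocks)
        w5 = sum(b.conv.W.value.size for b in n5.local_path.blocks)
        assert w5 / w3 == pytest.approx(125 / 27)

    def test_count_parameters_consistency(self):
        net = build_network(mini_cfg())
        total = net.count_parameters()
        manual = sum(p.value.size for p in net.params())
        assert total == manual
        assert net.count_parameters("conv_weight") < total


class TestForward:
    def test_receptive_field_matches_patch_sampler(self):
        net = build_network(NetworkConfig())
        assert net.path_receptive_field() == (17, 17, 17)

    def test_scores_shape_and_softmax_sums(self, rng):
        net = build_network(mini_cfg())
        x = rng.normal(size=(7, 7, 7)).astype(np.float32)
        scores = net.forward(x, x)
        assert scores.shape == (1, 3, 7, 7, 7)
        probs = softmax(scores, axis=1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_constant_input_gives_uniform_scores(self, rng):
        # translation invariance away from borders: interior scores equal
        net = build_network(mini_cfg(residual_pairs=()))
        x = np.zeros((9, 9, 9), dtype=np.float32)
        scores = net.forward(x, x)[0]
        interior = scores[:, 2:-2, 2:-2, 2:-2]
        ref = np.broadcast_to(interior[:, :1, :1, :1], interior.shape)
        np.testing.assert_allclose(interior, ref, atol=1e-5)

    def test_inference_deterministic(self, rng):
        net = build_network(mini_cfg(dropout=0.5))
        x = rng.normal(size=(7, 7, 7)).astype(np.float32)
        a = net.forward(x, x)
        b = net.forward(x, x)
        assert a.tobytes() == b.tobytes()

    def test_wrong_edge_rejected(self, rng):
        net = build_network(mini_cfg())
        with pytest.raises(ValueError):
            net.forward(rng.normal(size=(7, 7, 7)), rng.normal(size=(9, 9, 9)))

    def test_fusion_additivity(self, rng):
        # with identical paths and equal inputs, fused pre-head features are
        # twice one path's output
        cfg = mini_cfg(residual_pairs=(), dual_path=True)
        net = build_network(cfg)
        for pl, pg in zip(net.local_path.params(), net.global_path.params()):
            pg.value[...] = pl.value
        for bl, bg in zip(net.local_path.blocks, net.global_path.blocks):
            bg.bn.running_mean[...] = bl.bn.running_mean
            bg.bn.running_var[...] = bl.bn.running_var
        x = rng.normal(size=(1, 1, 7, 7, 7)).astype(np.float32)
        hl = net.local_path.forward(x)
        hg = net.global_path.forward(x)
        np.testing.assert_allclose(hl + hg, 2 * hl, atol=1e-5)


class TestConvOracle:
    def test_forward_matches_direct_summation(self, rng):
        conv = Conv3D(2, 3, kernel=3, rng=rng)
        x = rng.normal(size=(2, 2, 5, 5, 5)).astype(np.float32)
        y = conv.forward(x)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        oracle = np.zeros_like(y)
        for o in range(3):
            for c in range(2):
                for a, b, g in itertools.product(range(3), repeat=3):
                    oracle[:, o] += conv.W.value[o, c, a, b, g] * \
                        xp[:, c, a:a + 5, b:b + 5, g:g + 5]
        oracle += conv.b.value[None, :, None, None, None]
        np.testing.assert_allclose(y, oracle, atol=1e-4)

    def test_one_block_equals_bn_prelu_of_convolution(self, rng):
        cfg = mini_cfg(n_blocks_per_path=1, feature_maps=(2,), residual_pairs=(),
                       dual_path=False)
        net = build_network(cfg)
        block = net.local_path.blocks[0]
        x = rng.normal(size=(1, 1, 5, 5, 5)).astype(np.float32)
        y = block.forward(x)
        h = block.conv.forward(x)
        h = block.bn.forward(h)
        a = block.act.a.value[None, :, None, None, None]
        expected = np.where(h > 0, h, a * h)
        np.testing.assert_allclose(y, expected, atol=1e-6)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        net = build_network(mini_cfg(seed=3))
        xl = rng.normal(size=(2, 1, 5, 5, 5)).astype(np.float32)
        xg = rng.normal(size=(2, 1, 5, 5, 5)).astype(np.float32)
        yt = rng.integers(0, 3, size=(2, 5, 5, 5))

        def loss():
            s = net.forward(xl, xg, train=True)
            return cross_entropy(s.astype(np.float64), yt, 3)

        net.zero_grad()
        _, g = loss()
        net.backward(g)
        eps = 1e-3
        for p in net.params():
            if p.name.endswith("conv.b"):
                continue  # conv bias before BN: true gradient is exactly 0
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + eps
            c1, _ = loss()
            p.value[idx] = orig - eps
            c2, _ = loss()
            p.value[idx] = orig
            num = (c1 - c2) / (2 * eps)
            ana = p.grad[idx]
            # relative check with an absolute floor: float32 forward noise
            # dominates central differences when the true gradient is tiny
            assert (abs(num - ana) / max(1e-6, abs(num) + abs(ana)) < 2e-2
                    or abs(num - ana) < 2e-3), p.name


def test_checkpoint_roundtrip(tmp_path, rng):
    net = build_network(mini_cfg(seed=5))
    x = rng.normal(size=(7, 7, 7)).astype(np.float32)
    before = net.forward(x, x)
    path = str(tmp_path / "ckpt.npz")
    net.save(path)
    loaded = DualPathNetwork.load(path)
    after = loaded.forward(x, x)
    np.testing.assert_array_equal(before, after)


def test_forward_pair_accepts_patchpair(rng):
    net = build_network(mini_cfg())
    p = rng.normal(size=(7, 7, 7)).astype(np.float32)
    pp = PatchPair(local=p, global_=p.copy(), center=(3, 3, 3))
    scores = net.forward_pair(pp)
    assert scores.shape == (1, 3, 7, 7, 7)
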