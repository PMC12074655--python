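"""Backbone: orthogonal projection attention, channel shuffle, blocks."""

import numpy as np
import pytest

from orthodetr import autodiff as ad
from orthodetr.autodiff import Tensor
from orthodetr.ortho_filters import build_filter_bank
from orthodetr.backbone import (
    AttentionMLP,
    Backbone,
    BackboneConfig,
    OrthoShuffleBlock,
    OrthoShuffleBlockConfig,
    channel_shuffle,
    orthogonal_projection,
    shuffle_permutation,
)


class TestOrthogonalProjection:
    def test_filter_as_input_gives_frobenius_norm(self):
        # F[b, i] = W_i  =>  f[b, i] = <W_i, W_i> = trace(W^T W) = n
        bank = build_filter_bank(3, 5, seed=0)
        F = np.broadcast_to(bank.stack[None], (2, 3, 5, 5)).copy()
        f = orthogonal_projection(F, bank)
        assert f == pytest.approx(np.full((2, 3), 5.0), abs=1e-9)

    def test_zero_input_gives_zero(self):
        bank = build_filter_bank(2, 4, seed=1)
        assert orthogonal_projection(np.zeros((1, 2, 4, 4)), bank) == pytest.approx(
            np.zeros((1, 2)))

    def test_matches_double_loop_oracle(self, rng):
        bank = build_filter_bank(2, 3, seed=2)
        F = rng.normal(size=(2, 2, 3, 3))
        f = orthogonal_projection(F, bank)
        oracle = np.zeros((2, 2))
        for b in range(2):
            for c in range(2):
                for i in range(3):
                    for j in range(3):
                        oracle[b, c] += F[b, c, i, j] * bank.stack[c, i, j]
        assert f == pytest.approx(oracle, abs=1e-6)

    def test_linearity(self, rng):
        bank = build_filter_bank(3, 4, seed=3)
        F1 = rng.normal(size=(1, 3, 4, 4))
        F2 = rng.normal(size=(1, 3, 4, 4))
        a, b = 2.5, -1.25
        lhs = orthogonal_projection(a * F1 + b * F2, bank)
        rhs = a * orthogonal_projection(F1, bank) + b * orthogonal_projection(F2, bank)
        assert np.abs(lhs - rhs).max() <= 1e-5

    def test_shape_mismatches_rejected(self, rng):
        bank = build_filter_bank(2, 3, seed=0)
        with pytest.raises(ValueError):
            orthogonal_projection(np.zeros((1, 2, 3, 4)), bank)   # not square
        with pytest.raises(ValueError):
            orthogonal_projection(np.zeros((1, 2, 4, 4)), bank)   # wrong side
        with pytest.raises(ValueError):
            orthogonal_projection(np.zeros((1, 3, 3, 3)), bank)   # wrong channels

    def test_tensor_path_matches_array_path(self, rng):
        bank = build_filter_bank(2, 3, seed=4)
        F = rng.normal(size=(2, 2, 3, 3))
        t = orthogonal_projection(Tensor(F), bank)
        assert t.data == pytest.approx(orthogonal_projection(F, bank))


class TestAttentionWeights:
    def test_output_strictly_in_open_unit_interval(self, rng):
        mlp = AttentionMLP(rng, 8, 2)
        alpha = mlp(Tensor(rng.normal(size=(4, 8)) * 10))
        assert (alpha.data > 0).all() and (alpha.data < 1).all()

    def test_zero_input_zero_bias_gives_half(self, rng):
        mlp = AttentionMLP(rng, 6, 3)
        alpha = mlp(Tensor(np.zeros((2, 6))))
        assert alpha.data == pytest.approx(np.full((2, 6), 0.5))

    def test_matches_dense_algebra_oracle(self, rng):
        mlp = AttentionMLP(rng, 5, 2)
        x = rng.normal(size=(3, 5))
        got = mlp(Tensor(x)).data
        h = np.maximum(x @ mlp.fc1.w.data + mlp.fc1.b.data, 0)
        expect = 1 / (1 + np.exp(-(h @ mlp.fc2.w.data + mlp.fc2.b.data)))
        assert got == pytest.approx(expect, abs=1e-6)


class TestChannelShuffle:
    def test_single_group_is_identity(self, rng):
        x = rng.normal(size=(1, 6, 2, 2))
        assert np.array_equal(channel_shuffle(x, 1), x)

    def test_four_channels_two_groups_permutation(self, rng):
        x = rng.normal(size=(1, 4, 3, 3))
        y = channel_shuffle(x, 2)
        # reshape(2, 2) -> transpose -> flatten maps (0, 1, 2, 3) to (0, 2, 1, 3)
        assert np.array_equal(y, x[:, [0, 2, 1, 3]])

    def test_pure_permutation_preserves_channel_multiset(self, rng):
        x = rng.normal(size=(2, 12, 2, 2))
        y = channel_shuffle(x, 3)
        sx = np.sort(x.reshape(2, 12, -1), axis=1)
        sy = np.sort(y.reshape(2, 12, -1), axis=1)
        assert np.array_equal(sx, sy)

    def test_indivisible_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            channel_shuffle(rng.normal(size=(1, 5, 2, 2)), 2)

    @pytest.mark.parametrize("c,groups", [(4, 2), (12, 3), (64, 8), (64, 2)])
    def test_inverse_permutation_roundtrip(self, rng, c, groups):
        x = rng.normal(size=(1, c, 2, 2))
        y = channel_shuffle(x, groups)
        perm = shuffle_permutation(c, groups)
        inv = np.argsort(perm)
        assert np.array_equal(y[:, inv], x)

    def test_relu_commutes_with_shuffle(self, rng):
        # a permutation commutes with any elementwise map, so one ReLU
        # after the shuffle is equivalent to ReLU both sides
        x = rng.normal(size=(2, 8, 3, 3))
        a = np.maximum(channel_shuffle(np.maximum(x, 0), 2), 0)
        b = channel_shuffle(np.maximum(x, 0), 2)
        assert np.array_equal(a, b)


class TestOrthoShuffleBlock:
    def test_stride_two_output_shape(self, rng):
        cfg = OrthoShuffleBlockConfig(in_channels=8, out_channels=16, stride=2,
                               shuffle_groups=2, attention_reduction=4, seed=0)
        blk = OrthoShuffleBlock(cfg, rng)
        y = blk(Tensor(rng.normal(size=(2, 8, 16, 16))))
        assert y.shape == (2, 16, 8, 8)

    def test_output_nonnegative(self, rng):
        cfg = OrthoShuffleBlockConfig(in_channels=4, out_channels=4, stride=1,
                               shuffle_groups=2, seed=1)
        blk = OrthoShuffleBlock(cfg, rng)
        y = blk(Tensor(rng.normal(size=(1, 4, 6, 6))))
        assert (y.data >= 0).all()

    def test_unit_attention_equals_residual_composition_oracle(self, rng):
        # with alpha forced to 1 and a single shuffle group the block must
        # equal the plain residual composition of its named sub-operations
        cfg = OrthoShuffleBlockConfig(in_channels=4, out_channels=4, stride=1,
                               shuffle_groups=1, seed=2, use_norm=False)
        blk = OrthoShuffleBlock(cfg, rng)
        x = rng.normal(size=(2, 4, 5, 5))
        ones = Tensor(np.ones((2, 4)))
        got = blk(Tensor(x), alpha_override=ones).data

        def conv(v, cn):
            return ad.conv2d(Tensor(v), cn.w, cn.b, stride=cn.stride, pad=cn.pad).data

        F = conv(np.maximum(conv(x, blk.conv1), 0), blk.conv2)
        expect = np.maximum(F + x, 0)       # shuffle with 1 group = identity
        assert np.abs(got - expect).max() <= 1e-6

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            OrthoShuffleBlockConfig(in_channels=4, out_channels=5, shuffle_groups=2)
        with pytest.raises(ValueError):
            OrthoShuffleBlockConfig(in_channels=4, out_channels=4, stride=3)


class TestBackbone:
    @pytest.mark.parametrize("side,expected", [(160, (20, 10, 5)), (64, (8, 4, 2))])
    def test_stage_strides_8_16_32(self, side, expected):
        cfg = BackboneConfig(input_side=side, stem_channels=4,
                             stage_channels=(4, 4, 4), stage_depths=(1, 1, 1),
                             seed=0)
        bb = Backbone(cfg)
        s3, s4, s5 = bb(Tensor(np.zeros((1, 1, side, side))))
        assert (s3.shape[2], s4.shape[2], s5.shape[2]) == expected

    def test_indivisible_side_rejected(self):
        with pytest.raises(ValueError):
            BackboneConfig(input_side=100)

    def test_nonsquare_input_rejected_without_padding(self, rng):
        cfg = BackboneConfig(input_side=64, stem_channels=4,
                             stage_channels=(4, 4, 4), stage_depths=(1, 1, 1))
        bb = Backbone(cfg)
        with pytest.raises(ValueError):
            bb(Tensor(rng.normal(size=(1, 1, 64, 32))))

    def test_seeded_outputs_bitwise_reproducible(self, rng):
        x = rng.normal(size=(1, 1, 64, 64))
        outs = []
        for _ in range(2):
            cfg = BackboneConfig(input_side=64, stem_channels=4,
                                 stage_channels=(4, 8, 8), stage_depths=(1, 1, 1),
                                 seed=42)
            bb = Backbone(cfg)
            outs.append(bb(Tensor(x.copy()))[2].data)
        assert np.array_equal(outs[0], outs[1])


def test_toy_backbone_classifier_overfits():
    """A 3-stage shuffle backbone + linear head reaches 100% train accuracy
    on 32 synthetic two-class images within 200 steps."""
    from orthodetr.synthetic import SyntheticDatasetConfig, small_classification_variant

    data_cfg = SyntheticDatasetConfig(n_images=32, image_side=32,
                                      semi_axis_min=3.0, semi_axis_max=7.0,
                                      skull_ring=False, seed=5)
    images, labels = small_classification_variant(data_cfg)
    cfg = BackboneConfig(input_side=32, stem_channels=4,
                         stage_channels=(8, 8, 8), stage_depths=(1, 1, 1),
                         attention_reduction=2, seed=9)
    bb = Backbone(cfg)
    rng = np.random.default_rng(9)
    head = ad.Linear(rng, 8, 2)
    params = bb.parameters() + [head.w, head.b]
    opt = ad.Adam(params, lr=3e-3)
    x = images[:, None]
    acc = 0.0
    for step in range(200):
        _, _, s5 = bb(Tensor(x))
        logits = head(s5.mean(axis=(2, 3)))
        p = ad.softmax(logits, axis=-1)
        picked = p[np.arange(len(labels)), labels]
        loss = -(picked.clip_min(1e-12).log()).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        acc = float((logits.data.argmax(-1) == labels).mean())
        if acc == 1.0:
            break
    assert acc == 1.0
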