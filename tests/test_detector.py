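"""Query selection, denoising, matching, decoder contracts, training step."""

import numpy as np
import pytest

from orthodetr import autodiff as ad
from orthodetr.autodiff import Tensor
from orthodetr.detector import (
    DenoisingConfig,
    Detector,
    DetectionSet,
    add_denoising_noise,
    brute_force_match,
    build_attention_mask,
    detect,
    hungarian_match,
    iou_aware_query_select,
    scenes_to_gts,
    toy_config,
    train_step,
)
from orthodetr.detector import _match_cost
from scipy.optimize import linear_sum_assignment


def micro_config(seed=0):
    """Smallest config that exercises every code path (quick tests)."""
    from orthodetr.hybrid_encoder import EncoderConfig
    from orthodetr.backbone import BackboneConfig
    from orthodetr.detector import DetectorConfig

    return DetectorConfig(
        image_side=64, hidden_dim=16, n_queries=10, n_decoder_layers=2,
        heads=2, n_sample_points=2,
        backbone=BackboneConfig(input_side=64, stem_channels=4,
                                stage_channels=(4, 8, 16), stage_depths=(1, 1, 1),
                                attention_reduction=2, seed=seed),
        encoder=EncoderConfig(in_channels=(4, 8, 16), hidden_dim=16, heads=2,
                              n_rep=1, bias_table_side=5, seed=seed + 1),
        denoise=DenoisingConfig(n_groups=2),
        seed=seed,
    )


@pytest.fixture(scope="module")
def micro_batch(tiny_scenes):
    _, scenes = tiny_scenes
    imgs = np.stack([s.image for s in scenes])
    gts = scenes_to_gts(scenes, 64.0)
    return imgs, gts


class TestQuerySelection:
    def test_k_clipped_to_token_count(self, rng):
        mem = Tensor(rng.normal(size=(10, 4)))
        logits = Tensor(rng.normal(size=(10, 2)))
        boxes = Tensor(rng.uniform(0.1, 0.9, size=(10, 4)))
        qs = iou_aware_query_select(mem, logits, boxes, k=300)
        assert qs.content.shape == (10, 4)

    def test_top_k_matches_full_sort_oracle(self, rng):
        # sigmoid is monotone, so logits ordering = confidence ordering
        logits = Tensor(np.log(np.array([[0.9], [0.1], [0.5]])
                               / (1 - np.array([[0.9], [0.1], [0.5]]))))
        mem = Tensor(rng.normal(size=(3, 4)))
        boxes = Tensor(rng.uniform(0.1, 0.9, size=(3, 4)))
        qs = iou_aware_query_select(mem, logits, boxes, k=2)
        assert list(qs.token_indices) == [0, 2]

    def test_ties_break_by_ascending_token_index(self, rng):
        logits = Tensor(np.zeros((5, 1)))
        mem = Tensor(rng.normal(size=(5, 3)))
        boxes = Tensor(rng.uniform(0.2, 0.8, size=(5, 4)))
        qs = iou_aware_query_select(mem, logits, boxes, k=3)
        assert list(qs.token_indices) == [0, 1, 2]


class TestDenoising:
    GT_BOXES = np.array([[0.5, 0.5, 0.2, 0.3], [0.3, 0.7, 0.1, 0.1]])
    GT_LABELS = np.array([0, 1])

    def test_zero_noise_returns_exact_copies(self):
        cfg = DenoisingConfig(label_flip_p=0.0, box_noise_scale=0.0, n_groups=3)
        groups = add_denoising_noise(self.GT_BOXES, self.GT_LABELS, cfg, 2, seed=0)
        assert len(groups) == 3
        for g in groups:
            assert np.array_equal(g.labels, self.GT_LABELS)
            assert np.allclose(g.boxes, self.GT_BOXES)

    def test_jitter_bounded_by_scale_times_side(self):
        cfg = DenoisingConfig(label_flip_p=0.0, box_noise_scale=0.4, n_groups=20)
        groups = add_denoising_noise(self.GT_BOXES, self.GT_LABELS, cfg, 2, seed=1)
        for g in groups:
            delta = np.abs(g.boxes - self.GT_BOXES)
            span = np.stack([self.GT_BOXES[:, 2], self.GT_BOXES[:, 3],
                             self.GT_BOXES[:, 2], self.GT_BOXES[:, 3]], axis=1)
            assert (delta <= 0.4 * span + 1e-12).all()

    def test_seeded_determinism(self):
        cfg = DenoisingConfig(n_groups=4)
        a = add_denoising_noise(self.GT_BOXES, self.GT_LABELS, cfg, 3, seed=7)
        b = add_denoising_noise(self.GT_BOXES, self.GT_LABELS, cfg, 3, seed=7)
        for ga, gb in zip(a, b):
            assert np.array_equal(ga.labels, gb.labels)
            assert np.array_equal(ga.boxes, gb.boxes)

    def test_mask_isolates_denoising_from_matching(self):
        mask = build_attention_mask([2, 2], 3)
        # matching rows: no attention into any denoising column
        assert mask[4:, :4].all()
        # denoising rows: no attention into matching columns or other groups
        assert mask[:4, 4:].all()
        assert mask[0:2, 2:4].all() and mask[2:4, 0:2].all()
        # within-partition attention open
        assert not mask[0:2, 0:2].any()
        assert not mask[4:, 4:].any()


class TestHungarianMatching:
    def test_single_pair_matches(self):
        pi, gi = hungarian_match(np.array([[0.9]]), np.array([[0.5, 0.5, 0.2, 0.2]]),
                                 np.array([[0.5, 0.5, 0.2, 0.2]]), np.array([0]))
        assert list(pi) == [0] and list(gi) == [0]

    def test_antidiagonal_cost_prefers_diagonal(self):
        cost = np.array([[0.0, 1.0], [1.0, 0.0]])
        rows, cols = linear_sum_assignment(cost)
        total = cost[rows, cols].sum()
        assert total == 0.0

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            n_gt = int(rng.integers(1, 6))
            n_pred = int(rng.integers(n_gt, 8))
            probs = rng.uniform(0.01, 0.99, size=(n_pred, 2))
            boxes = rng.uniform(0.2, 0.8, size=(n_pred, 4))
            gt_boxes = rng.uniform(0.2, 0.8, size=(n_gt, 4))
            gt_labels = rng.integers(0, 2, size=n_gt)
            C = _match_cost(probs, boxes, gt_boxes, gt_labels,
                            (2.0, 5.0, 2.0), 0.7, "scaled")
            pi, gi = hungarian_match(probs, boxes, gt_boxes, gt_labels)
            got = C[pi, gi].sum()
            best, _ = brute_force_match(C)
            assert got == pytest.approx(best, abs=1e-9)

    def test_empty_gt_returns_empty_assignment(self):
        pi, gi = hungarian_match(np.zeros((3, 1)), np.zeros((3, 4)),
                                 np.zeros((0, 4)), np.zeros(0, dtype=int))
        assert len(pi) == 0 and len(gi) == 0


@pytest.fixture(scope="module")
def decoder_forward_result(micro_batch):
    imgs, gts = micro_batch
    model = Detector(micro_config(seed=3))
    res = model.forward_train(imgs[:2], gts[:2], seed=0)
    return model, res


class TestDecoderContracts:
    @pytest.fixture
    def forward(self, decoder_forward_result):
        return decoder_forward_result

    def test_boxes_squashed_into_unit_interval(self, forward):
        _, res = forward
        for _, boxes in res["layers"]:
            assert (boxes.data > 0).all() and (boxes.data < 1).all()

    def test_auxiliary_outputs_per_layer(self, forward):
        model, res = forward
        assert len(res["layers"]) == model.cfg.n_decoder_layers

    def test_seeded_forward_is_reproducible(self, micro_batch):
        imgs, gts = micro_batch
        outs = []
        for _ in range(2):
            model = Detector(micro_config(seed=11))
            res = model.forward_train(imgs[:2], gts[:2], seed=5)
            outs.append(res["layers"][-1][1].data)
        assert np.array_equal(outs[0], outs[1])


class TestTrainStep:
    def test_empty_batch_rejected(self):
        model = Detector(micro_config())
        opt = ad.Adam(model.parameters())
        with pytest.raises(ValueError):
            train_step(model, opt, np.zeros((0, 64, 64)), [])

    def test_one_step_decreases_loss_on_fixed_batch(self, micro_batch):
        imgs, gts = micro_batch
        model = Detector(micro_config(seed=21))
        opt = ad.Adam(model.parameters(), lr=1e-4, clip_norm=5.0)
        first = train_step(model, opt, imgs[:2], gts[:2], seed=9)
        # re-evaluate the same batch (same denoising seed) after the update
        from orthodetr.detector import compute_losses
        res = model.forward_train(imgs[:2], gts[:2], seed=9)
        losses = compute_losses(model, res, gts[:2])
        after = sum(v.item() for v in losses.values())
        assert after < first["total"]

    def test_perfectly_predicted_boxes_have_zero_box_terms(self):
        from orthodetr.detector import DetectorConfig, _set_loss
        cfg = micro_config()
        gt_boxes = np.array([[0.5, 0.5, 0.2, 0.2]])
        gt_labels = np.array([0])
        logits = Tensor(np.full((3, 1), -4.0))
        boxes = Tensor(np.array([[0.5, 0.5, 0.2, 0.2],
                                 [0.3, 0.3, 0.1, 0.1],
                                 [0.7, 0.7, 0.1, 0.1]]))
        loss_perfect = _set_loss(logits, boxes, gt_boxes, gt_labels,
                                 np.array([0]), np.array([0]), cfg)
        # classification-only reference: same call with box weights zeroed
        cfg0 = DetectorConfig(**{**cfg.__dict__, "loss_weights": (2.0, 0.0, 0.0)})
        loss_cls = _set_loss(logits, boxes, gt_boxes, gt_labels,
                             np.array([0]), np.array([0]), cfg0)
        assert loss_perfect.item() == pytest.approx(loss_cls.item(), abs=1e-9)

    def test_detect_with_unit_threshold_returns_empty(self, micro_batch):
        imgs, _ = micro_batch
        model = Detector(micro_config(seed=2))
        det = detect(imgs[0], model, score_thr=1.0)
        assert len(det) == 0
        assert isinstance(det, DetectionSet)


def test_detection_set_validates_lengths_and_scores():
    with pytest.raises(ValueError):
        DetectionSet(np.zeros((2, 4)), np.zeros(2, dtype=int), np.zeros(1))
    with pytest.raises(ValueError):
        DetectionSet(np.zeros((1, 4)), np.zeros(1, dtype=int), np.array([1.5]))
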