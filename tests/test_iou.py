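"""Box geometry: Inner-IoU, corner penalties, IACD-IoU and its loss."""

import numpy as np
import pytest

from orthodetr.autodiff import Tensor
from orthodetr.iou import (
    BoxCorners,
    BoxCXCYWH,
    ImageExtent,
    corner_penalty,
    giou,
    iacd_iou,
    iacd_iou_arrays,
    iacd_loss,
    inner_iou,
    pairwise_iou,
    rasterized_iou_oracle,
    scale_box,
)

IMG = ImageExtent(100, 100)
GT = BoxCXCYWH(50, 50, 20, 20)
ANCHOR = BoxCXCYWH(55, 55, 20, 20)


def random_boxes(rng, n, lo=0.1, hi=0.9, smin=0.05, smax=0.4):
    cx = rng.uniform(lo, hi, n)
    cy = rng.uniform(lo, hi, n)
    w = rng.uniform(smin, smax, n)
    h = rng.uniform(smin, smax, n)
    return np.stack([cx, cy, w, h], axis=1)


class TestScaleBox:
    def test_unit_ratio_recovers_plain_corners(self):
        assert scale_box(GT, 1.0) == BoxCorners(40, 40, 60, 60)

    def test_ratio_07_worked_example(self):
        # centre 50, side 20, ratio 0.7: 50 -+ 20*0.7/2 = 43 / 57
        assert scale_box(GT, 0.7) == BoxCorners(43, 43, 57, 57)
        assert scale_box(ANCHOR, 0.7) == BoxCorners(48, 48, 62, 62)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            scale_box(GT, 0.0)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoxCXCYWH(10, 10, 0.0, 5.0)


class TestInnerIoU:
    def test_identical_boxes_score_one(self):
        assert inner_iou(GT, GT, 0.7) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_scaled_boxes_score_zero(self):
        far = BoxCXCYWH(150, 150, 10, 10)
        near = BoxCXCYWH(50, 50, 10, 10)
        assert inner_iou(near, far, 0.7) == 0.0

    def test_worked_example_81_over_311(self):
        # scaled boxes (43..57) vs (48..62): inter 9^2=81, union 2*196-81=311
        assert inner_iou(GT, ANCHOR, 0.7) == pytest.approx(81 / 311, abs=1e-9)

    def test_agrees_with_rasterized_oracle(self):
        got = inner_iou(GT, ANCHOR, 0.7)
        oracle = rasterized_iou_oracle(scale_box(GT, 0.7), scale_box(ANCHOR, 0.7),
                                       step=0.01)
        assert got == pytest.approx(oracle, abs=1e-3)

    def test_symmetry(self, rng):
        a = random_boxes(rng, 50)
        b = random_boxes(rng, 50)
        for ai, bi in zip(a, b):
            x = inner_iou(BoxCXCYWH(*ai), BoxCXCYWH(*bi), 0.7)
            y = inner_iou(BoxCXCYWH(*bi), BoxCXCYWH(*ai), 0.7)
            assert x == y

    def test_scale_invariance(self, rng):
        for lam in (0.5, 3.0, 17.0):
            a = BoxCXCYWH(0.4, 0.5, 0.2, 0.3)
            b = BoxCXCYWH(0.5, 0.45, 0.25, 0.2)
            s1 = inner_iou(a, b, 0.7)
            a2 = BoxCXCYWH(a.xc * lam, a.yc * lam, a.w * lam, a.h * lam)
            b2 = BoxCXCYWH(b.xc * lam, b.yc * lam, b.w * lam, b.h * lam)
            assert inner_iou(a2, b2, 0.7) == pytest.approx(s1, abs=1e-9)


class TestCornerPenalty:
    def test_identical_corners_zero(self):
        c = scale_box(GT, 0.7)
        assert corner_penalty(c, c, IMG) == (0.0, 0.0)

    def test_worked_example(self):
        p1, p2 = corner_penalty(BoxCorners(43, 43, 57, 57),
                                BoxCorners(48, 48, 62, 62), IMG)
        assert p1 == pytest.approx(50 / 20000)
        assert p2 == pytest.approx(50 / 20000)

    def test_opposite_image_corners_saturate_at_one(self):
        a = BoxCorners(0, 0, 0, 0)
        b = BoxCorners(100, 100, 100, 100)
        p1, p2 = corner_penalty(a, b, IMG)
        assert p1 == pytest.approx(1.0)
        assert p2 == pytest.approx(1.0)


class TestIACD:
    def test_identical_boxes_score_exactly_one(self):
        assert iacd_iou(GT, GT, 0.7, IMG) == pytest.approx(1.0, abs=1e-9)

    def test_worked_example(self):
        expected = 81 / 311 - 0.005
        assert iacd_iou(GT, ANCHOR, 0.7, IMG) == pytest.approx(expected, abs=1e-9)

    def test_disjoint_boxes_strictly_negative(self):
        far = BoxCXCYWH(90, 90, 10, 10)
        near = BoxCXCYWH(10, 10, 10, 10)
        assert iacd_iou(near, far, 0.7, IMG) < 0.0

    def test_one_iff_identical(self, rng):
        boxes = random_boxes(rng, 100)
        for b in boxes:
            other = b + rng.normal(0, 0.02, 4)
            other[2:] = np.abs(other[2:]) + 1e-3
            v = iacd_iou(BoxCXCYWH(*b), BoxCXCYWH(*other), 0.7, ImageExtent(1, 1))
            if np.allclose(b, other):
                continue
            assert v < 1.0

    def test_equal_size_penalty_is_ratio_independent(self):
        # for equal sides the scaled-corner distance equals the centre
        # distance, so the penalty term does not depend on the ratio
        for ratio in (0.4, 0.7, 1.0):
            ii = inner_iou(GT, ANCHOR, ratio)
            v = iacd_iou(GT, ANCHOR, ratio, IMG)
            assert v - ii == pytest.approx(-0.005, abs=1e-12)

    def test_corner_mode_original_differs_for_unequal_sizes(self):
        a = BoxCXCYWH(50, 50, 30, 10)
        b = BoxCXCYWH(55, 52, 10, 30)
        s = iacd_iou(a, b, 0.7, IMG, corner_mode="scaled")
        o = iacd_iou(a, b, 0.7, IMG, corner_mode="original")
        assert s != pytest.approx(o)

    def test_unknown_corner_mode_rejected(self):
        with pytest.raises(ValueError):
            iacd_iou_arrays(np.ones((1, 4)), np.ones((1, 4)), corner_mode="weird")


class TestIACDLoss:
    def test_identical_batches_zero(self, rng):
        b = random_boxes(rng, 8)
        assert iacd_loss(b, b) == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            iacd_loss(random_boxes(rng, 3), random_boxes(rng, 4))

    def test_monotone_under_translation_toward_target(self):
        # slide the anchor centre toward the gt centre along x: the loss
        # must never increase
        gt = np.array([[0.5, 0.5, 0.2, 0.2]])
        vals = []
        for t in np.linspace(0.3, 0.0, 50):
            pred = np.array([[0.5 + t, 0.5, 0.2, 0.2]])
            vals.append(iacd_loss(pred, gt))
        diffs = np.diff(vals)
        assert (diffs <= 1e-12).all()

    def test_gradient_matches_finite_differences(self, rng):
        pred = Tensor(random_boxes(rng, 6), requires_grad=True)
        gt = random_boxes(rng, 6)
        loss = iacd_loss(pred, gt)
        loss.backward()
        eps = 1e-6
        num = np.zeros_like(pred.data)
        for idx in np.ndindex(pred.shape):
            orig = pred.data[idx]
            pred.data[idx] = orig + eps
            fp = iacd_loss(pred.data.copy(), gt)
            pred.data[idx] = orig - eps
            fm = iacd_loss(pred.data.copy(), gt)
            pred.data[idx] = orig
            num[idx] = (fp - fm) / (2 * eps)
        assert np.abs(num - pred.grad).max() <= 1e-4

    def test_tensor_and_array_paths_agree(self, rng):
        p = random_boxes(rng, 5)
        g = random_boxes(rng, 5)
        assert iacd_loss(Tensor(p), g).item() == pytest.approx(iacd_loss(p, g))


class TestRasterizedOracle:
    def test_identical_unit_boxes(self):
        b = BoxCorners(0, 0, 1, 1)
        assert rasterized_iou_oracle(b, b, 0.01) == pytest.approx(1.0)

    def test_half_overlapping_unit_squares(self):
        a = BoxCorners(0, 0, 1, 1)
        b = BoxCorners(0.5, 0, 1.5, 1)
        # analytic IoU = 0.5 / 1.5 = 1/3
        assert rasterized_iou_oracle(a, b, 0.01) == pytest.approx(1 / 3, abs=0.02)

    @pytest.mark.parametrize("step,n", [(0.1, 300), (0.01, 60)])
    def test_converges_to_closed_form(self, rng, step, n):
        for _ in range(n):
            a = random_boxes(rng, 1)[0]
            b = random_boxes(rng, 1)[0]
            ac = np.array([a[0] - a[2] / 2, a[1] - a[3] / 2,
                           a[0] + a[2] / 2, a[1] + a[3] / 2])
            bc = np.array([b[0] - b[2] / 2, b[1] - b[3] / 2,
                           b[0] + b[2] / 2, b[1] + b[3] / 2])
            closed = pairwise_iou(ac[None], bc[None])[0, 0]
            oracle = rasterized_iou_oracle(BoxCorners(*ac), BoxCorners(*bc), step)
            assert abs(oracle - closed) <= 5 * step

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            rasterized_iou_oracle(BoxCorners(0, 0, 1, 1), BoxCorners(0, 0, 1, 1), 0)


def test_giou_baseline_bounds(rng):
    a = random_boxes(rng, 50)
    ac = np.stack([a[:, 0] - a[:, 2] / 2, a[:, 1] - a[:, 3] / 2,
                   a[:, 0] + a[:, 2] / 2, a[:, 1] + a[:, 3] / 2], axis=1)
    b = random_boxes(rng, 50)
    bc = np.stack([b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2,
                   b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2], axis=1)
    g = giou(ac, bc)
    assert (g <= 1.0 + 1e-9).all() and (g >= -1.0 - 1e-9).all()
    assert giou(ac, ac).max() == pytest.approx(1.0)
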