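"""Box geometry: Inner-IoU, corner-distance penalties, and IACD-IoU.

IACD-IoU scores the agreement of two axis-aligned boxes by

    IACD = IoU_inner(gt, anchor; ratio) - d1^2/(w^2+h^2) - d2^2/(w^2+h^2)

where IoU_inner is the ordinary IoU of both boxes *shrunk about their
centres* by ``ratio`` (default 0.7, emphasising interior overlap), d1/d2 are
the Euclidean distances between the corresponding top-left and bottom-right
corners, and (w, h) is the image extent normalising the penalties. Identical
boxes score exactly 1; disjoint boxes score strictly below 0.

Everything here is exact continuous-coordinate algebra; the rasterized
oracle at the bottom is the independent check used by the tests, counting
lattice cells instead of intersecting intervals.

Two corner conventions exist in the field: penalising the *scaled* corners
(the literal reading of the defining equations, default here) or the
*original* corners (the corner-distance precedent). ``corner_mode`` selects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "BoxCXCYWH",
    "BoxCorners",
    "ImageExtent",
    "scale_box",
    "inner_iou",
    "corner_penalty",
    "iacd_iou",
    "iacd_iou_arrays",
    "iacd_iou_tensor",
    "iacd_loss",
    "box_iou_corners",
    "pairwise_iou",
    "giou",
    "rasterized_iou_oracle",
]

EPS = 1e-9


@dataclass(frozen=True)
class BoxCXCYWH:
    """Box in centre-size form; continuous pixel coordinates, w/h > 0."""

    xc: float
    yc: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box sides must be positive, got w={self.w}, h={self.h}")

    def to_array(self) -> np.ndarray:
        return np.array([self.xc, self.yc, self.w, self.h], dtype=np.float64)


@dataclass(frozen=True)
class BoxCorners:
    """Box in corner form (left, top, right, bottom)."""

    bl: float
    bt: float
    br: float
    bb: float

    def __post_init__(self) -> None:
        if self.bl > self.br or self.bt > self.bb:
            raise ValueError("corners must satisfy left <= right, top <= bottom")


@dataclass(frozen=True)
class ImageExtent:
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("image extent must be positive")


def scale_box(box: BoxCXCYWH, ratio: float) -> BoxCorners:
    """Corners of ``box`` shrunk (ratio < 1) or grown about its centre."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    hw = box.w * ratio / 2.0
    hh = box.h * ratio / 2.0
    return BoxCorners(box.xc - hw, box.yc - hh, box.xc + hw, box.yc + hh)


# -- vectorised core (cxcywh arrays of shape (..., 4)) -----------------------

def _scaled_corners(boxes: np.ndarray, ratio: float) -> tuple[np.ndarray, ...]:
    xc, yc, w, h = boxes[..., 0], boxes[..., 1], boxes[..., 2], boxes[..., 3]
    hw, hh = w * ratio / 2.0, h * ratio / 2.0
    return xc - hw, yc - hh, xc + hw, yc + hh


def _inner_iou_arrays(gt: np.ndarray, anchor: np.ndarray, ratio: float) -> np.ndarray:
    gl, gt_, gr, gb = _scaled_corners(gt, ratio)
    al, at, ar, ab = _scaled_corners(anchor, ratio)
    # per-axis overlap clamped at zero before multiplying: disjoint boxes
    # have zero intersection, not a signed product
    iw = np.maximum(np.minimum(gr, ar) - np.maximum(gl, al), 0.0)
    ih = np.maximum(np.minimum(gb, ab) - np.maximum(gt_, at), 0.0)
    inter = iw * ih
    union = (ratio * gt[..., 2]) * (ratio * gt[..., 3]) + \
            (ratio * anchor[..., 2]) * (ratio * anchor[..., 3]) - inter
    # floor (not additive) guard: keeps IoU of identical boxes exactly 1
    return inter / np.maximum(union, EPS)


def inner_iou(gt: BoxCXCYWH, anchor: BoxCXCYWH, ratio: float = 0.7) -> float:
    """Interior-focused IoU: ordinary IoU of the centre-scaled boxes."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    return float(_inner_iou_arrays(gt.to_array(), anchor.to_array(), ratio))


def corner_penalty(gt_c: BoxCorners, anchor_c: BoxCorners,
                   img: ImageExtent) -> tuple[float, float]:
    """Squared top-left / bottom-right corner distances over w^2 + h^2."""
    norm = img.w ** 2 + img.h ** 2
    d1sq = (anchor_c.bl - gt_c.bl) ** 2 + (anchor_c.bt - gt_c.bt) ** 2
    d2sq = (anchor_c.br - gt_c.br) ** 2 + (anchor_c.bb - gt_c.bb) ** 2
    return d1sq / norm, d2sq / norm


def iacd_iou(gt: BoxCXCYWH, anchor: BoxCXCYWH, ratio: float = 0.7,
             img: ImageExtent = ImageExtent(640, 640),
             corner_mode: str = "scaled") -> float:
    """Interior-aware corner-distance IoU of two boxes (scalar form)."""
    return float(iacd_iou_arrays(gt.to_array(), anchor.to_array(), ratio, img, corner_mode))


def iacd_iou_arrays(gt: np.ndarray, anchor: np.ndarray, ratio: float = 0.7,
                    img: ImageExtent = ImageExtent(640, 640),
                    corner_mode: str = "scaled") -> np.ndarray:
    """Vectorised IACD-IoU on cxcywh arrays of matching shape (..., 4)."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    if corner_mode not in ("scaled", "original"):
        raise ValueError(f"unknown corner_mode {corner_mode!r}")
    gt = np.asarray(gt, dtype=np.float64)
    anchor = np.asarray(anchor, dtype=np.float64)
    iiou = _inner_iou_arrays(gt, anchor, ratio)
    pr = ratio if corner_mode == "scaled" else 1.0
    gl, gtp, gr, gb = _scaled_corners(gt, pr)
    al, at, ar, ab = _scaled_corners(anchor, pr)
    norm = img.w ** 2 + img.h ** 2
    d1sq = (al - gl) ** 2 + (at - gtp) ** 2
    d2sq = (ar - gr) ** 2 + (ab - gb) ** 2
    return iiou - d1sq / norm - d2sq / norm


# -- differentiable form -----------------------------------------------------

def _tmax(a: Tensor, b: Tensor) -> Tensor:
    return a + (b - a).relu()


def _tmin(a: Tensor, b: Tensor) -> Tensor:
    return a - (a - b).relu()


def iacd_iou_tensor(pred: Tensor, gt: np.ndarray, ratio: float = 0.7,
                    img: ImageExtent = ImageExtent(640, 640),
                    corner_mode: str = "scaled") -> Tensor:
    """IACD-IoU of predicted boxes against fixed targets, on the autodiff
    graph. ``pred`` is an (n, 4) cxcywh tensor, ``gt`` a matching constant
    array, both in the same (pixel or normalised) frame as ``img``."""
    g = np.asarray(gt, dtype=np.float64)
    px, py, pw, ph = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    r2 = ratio / 2.0
    pl, pt_ = px - pw * r2, py - ph * r2
    pr_, pb = px + pw * r2, py + ph * r2
    gl, gtp = g[:, 0] - g[:, 2] * r2, g[:, 1] - g[:, 3] * r2
    gr, gb = g[:, 0] + g[:, 2] * r2, g[:, 1] + g[:, 3] * r2

    iw = (_tmin(pr_, Tensor(gr)) - _tmax(pl, Tensor(gl))).relu()
    ih = (_tmin(pb, Tensor(gb)) - _tmax(pt_, Tensor(gtp))).relu()
    inter = iw * ih
    union = (pw * ratio) * (ph * ratio) + Tensor((ratio * g[:, 2]) * (ratio * g[:, 3])) - inter
    iiou = inter / union.clip_min(EPS)

    cr = r2 if corner_mode == "scaled" else 0.5
    cl, ct = px - pw * cr, py - ph * cr
    cr_, cb = px + pw * cr, py + ph * cr
    kl, kt = g[:, 0] - g[:, 2] * cr, g[:, 1] - g[:, 3] * cr
    kr, kb = g[:, 0] + g[:, 2] * cr, g[:, 1] + g[:, 3] * cr
    norm = img.w ** 2 + img.h ** 2
    d1 = (cl - Tensor(kl)) ** 2 + (ct - Tensor(kt)) ** 2
    d2 = (cr_ - Tensor(kr)) ** 2 + (cb - Tensor(kb)) ** 2
    return iiou - d1 * (1.0 / norm) - d2 * (1.0 / norm)


def iacd_loss(pred_boxes, gt_boxes, ratio: float = 0.7,
              img: ImageExtent = ImageExtent(1.0, 1.0),
              reduction: str = "mean",
              corner_mode: str = "scaled"):
    """Regression loss ``1 - IACD-IoU`` over aligned box batches.

    ``pred_boxes`` may be an autodiff :class:`Tensor` (returning a Tensor on
    the graph) or a plain array (returning a float). Boxes are cxcywh in the
    frame of ``img`` — the default unit extent suits normalised coordinates.
    Zero iff every pair is identical.
    """
    g = np.asarray(gt_boxes, dtype=np.float64)
    if isinstance(pred_boxes, Tensor):
        if pred_boxes.shape[0] != g.shape[0]:
            raise ValueError("pred and gt batches must be the same length")
        vals = 1.0 - iacd_iou_tensor(pred_boxes, g, ratio, img, corner_mode)
        return vals.mean() if reduction == "mean" else vals.sum()
    p = np.asarray(pred_boxes, dtype=np.float64)
    if p.shape[0] != g.shape[0]:
        raise ValueError("pred and gt batches must be the same length")
    vals = 1.0 - iacd_iou_arrays(g, p, ratio, img, corner_mode)
    return float(vals.mean() if reduction == "mean" else vals.sum())


# -- plain IoU / GIoU (evaluation + baselines) -------------------------------

def box_iou_corners(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise IoU of corner-form boxes with matching shape (..., 4)."""
    iw = np.maximum(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]), 0.0)
    ih = np.maximum(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]), 0.0)
    inter = iw * ih
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    return inter / (area_a + area_b - inter + EPS)


def pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs IoU matrix of corner-form boxes a (n, 4) and b (m, 4)."""
    return box_iou_corners(a[:, None, :], b[None, :, :])


def giou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Generalised IoU (comparison baseline), corner-form (..., 4)."""
    iou = box_iou_corners(a, b)
    cl = np.minimum(a[..., 0], b[..., 0])
    ct = np.minimum(a[..., 1], b[..., 1])
    cr = np.maximum(a[..., 2], b[..., 2])
    cb = np.maximum(a[..., 3], b[..., 3])
    hull = (cr - cl) * (cb - ct)
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    iw = np.maximum(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]), 0.0)
    ih = np.maximum(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]), 0.0)
    union = area_a + area_b - iw * ih
    return iou - (hull - union) / (hull + EPS)


# -- independent oracle ------------------------------------------------------

def rasterized_iou_oracle(a: BoxCorners, b: BoxCorners, step: float = 0.01) -> float:
    """Brute-force IoU by counting lattice cells of pitch ``step`` whose
    centres fall inside each box. Deliberately free of interval algebra so it
    can stand against the closed-form implementations."""
    if step <= 0:
        raise ValueError("step must be positive")
    lo_x = min(a.bl, b.bl)
    hi_x = max(a.br, b.br)
    lo_y = min(a.bt, b.bt)
    hi_y = max(a.bb, b.bb)
    xs = np.arange(lo_x + step / 2.0, hi_x, step)
    ys = np.arange(lo_y + step / 2.0, hi_y, step)
    if xs.size == 0 or ys.size == 0:
        return 0.0
    in_ax = (xs >= a.bl) & (xs <= a.br)
    in_bx = (xs >= b.bl) & (xs <= b.br)
    in_ay = (ys >= a.bt) & (ys <= a.bb)
    in_by = (ys >= b.bt) & (ys <= b.bb)
    # the 2-D cell count factorises for axis-aligned boxes: counting the
    # outer product grid equals multiplying the per-axis counts
    inter = int((in_ay & in_by).sum()) * int((in_ax & in_bx).sum())
    union = (int(in_ay.sum()) * int(in_ax.sum())
             + int(in_by.sum()) * int(in_bx.sum()) - inter)
    if union == 0:
        return 0.0
    return float(inter) / float(union)
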