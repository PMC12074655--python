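"""End-to-end set-prediction detector.

Assembly: orthogonal channel-shuffle backbone -> hybrid encoder -> DETR-style
decoder. The decoder is initialised with the top-k encoder tokens by class
confidence (IoU-aware query selection: during training the encoder score
head is supervised toward the IoU between its predicted box and the matched
ground truth), augmented with denoising groups built from noised ground
truth, and refined over L layers of masked self-attention + deformable
cross-attention into the multi-scale memory. Prediction is end-to-end: a
score threshold, no non-maximum suppression.

Losses follow the DETR family: per-layer bipartite (Hungarian) matching with
cost lambda_cls * (-p) + lambda_L1 * ||b - g||_1 + lambda_iou * (1 - IACD),
then binary cross-entropy classification + L1 + (1 - IACD-IoU) box terms on
the matched pairs, plus the same box/class terms on the denoising queries
whose assignment is known by construction.

Implementation note: the decoder runs batched; because images carry
different numbers of ground-truth boxes, denoising groups are padded to the
batch maximum and the padded slots are excluded from every loss term (they
still self-attend within their group, which is inert).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import autodiff as ad
from .autodiff import Tensor
from .hybrid_encoder import EncoderConfig, HybridEncoder, FFN
from .iou import ImageExtent, iacd_iou_arrays, iacd_iou_tensor, pairwise_iou
from .backbone import Backbone, BackboneConfig
from .synthetic import SyntheticScene

__all__ = [
    "DetectorConfig",
    "DenoisingConfig",
    "DetectionSet",
    "QuerySet",
    "DenoisingGroup",
    "Detector",
    "iou_aware_query_select",
    "add_denoising_noise",
    "build_attention_mask",
    "hungarian_match",
    "brute_force_match",
    "train_step",
    "detect",
    "toy_config",
    "scenes_to_gts",
]


def inverse_sigmoid(x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    x = np.clip(x, eps, 1 - eps)
    return np.log(x / (1 - x))


def cxcywh_to_corners(b: np.ndarray) -> np.ndarray:
    out = np.empty_like(b)
    out[..., 0] = b[..., 0] - b[..., 2] / 2
    out[..., 1] = b[..., 1] - b[..., 3] / 2
    out[..., 2] = b[..., 0] + b[..., 2] / 2
    out[..., 3] = b[..., 1] + b[..., 3] / 2
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DetectionSet:
    """Scored, labelled boxes for one image (absolute pixels, cxcywh)."""

    boxes: np.ndarray                  # (n, 4)
    labels: np.ndarray                 # (n,)
    scores: np.ndarray                 # (n,) in [0, 1]

    def __post_init__(self) -> None:
        if not (len(self.boxes) == len(self.labels) == len(self.scores)):
            raise ValueError("boxes, labels and scores must have equal length")
        if len(self.scores) and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class QuerySet:
    """Decoder initialisation: content embeddings + anchor coords."""

    content: Tensor                    # (k, dim)
    coords: np.ndarray                 # (k, 4) normalised cxcywh in (0, 1)
    token_indices: np.ndarray          # which memory tokens were selected


@dataclass
class DenoisingGroup:
    labels: np.ndarray                 # (n_gt,) possibly flipped
    boxes: np.ndarray                  # (n_gt, 4) jittered, normalised
    group_index: int


@dataclass(frozen=True)
class DenoisingConfig:
    label_flip_p: float = 0.5
    box_noise_scale: float = 0.4
    n_groups: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.label_flip_p <= 1.0):
            raise ValueError("label_flip_p must be a probability")


@dataclass(frozen=True)
class DetectorConfig:
    image_side: int = 640
    n_classes: int = 1
    hidden_dim: int = 256
    n_queries: int = 300
    n_decoder_layers: int = 6
    heads: int = 8
    n_sample_points: int = 4           # deformable samples per scale per query
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    denoise: DenoisingConfig = field(default_factory=DenoisingConfig)
    loss_weights: tuple[float, float, float] = (2.0, 5.0, 2.0)   # cls, L1, iou
    cls_pos_weight: float = 8.0        # up-weight matched queries in the BCE
    anchor_base_scale: float = 0.1     # prior box side at stride 8, doubling per level
    iou_ratio: float = 0.7
    corner_mode: str = "scaled"
    seed: int = 0


def toy_config(seed: int = 0) -> DetectorConfig:
    """Desk-scale configuration: 160 px images, hidden dim 64, 2 decoder
    layers, 50 queries — small enough to overfit a handful of synthetic
    scenes on one CPU in minutes."""
    return DetectorConfig(
        image_side=160,
        hidden_dim=64,
        n_queries=50,
        n_decoder_layers=2,
        heads=8,
        backbone=BackboneConfig(input_side=160, stem_channels=8,
                                stage_channels=(16, 32, 64),
                                stage_depths=(1, 1, 1),
                                attention_reduction=4, seed=seed),
        encoder=EncoderConfig(in_channels=(16, 32, 64), hidden_dim=64,
                              heads=8, n_rep=1, bias_table_side=9,
                              seed=seed + 1),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# query selection and denoising
# ---------------------------------------------------------------------------

def iou_aware_query_select(memory: Tensor, class_logits: Tensor, box_pred: Tensor,
                           k: int = 300) -> QuerySet:
    """Top-k memory tokens by max class confidence, for one image.

    ``memory`` (N, dim), ``class_logits`` (N, n_classes), ``box_pred``
    (N, 4) normalised. k is clipped to the token count; ties break by
    ascending token index (stable sort on descending score).
    """
    n = memory.shape[0]
    k = min(k, n)
    scores = (1.0 / (1.0 + np.exp(-class_logits.data))).max(axis=-1)
    idx = np.argsort(-scores, kind="stable")[:k]
    return QuerySet(content=memory[idx], coords=box_pred.data[idx].copy(),
                    token_indices=idx)


def add_denoising_noise(gt_boxes: np.ndarray, gt_labels: np.ndarray,
                        cfg: DenoisingConfig, n_classes: int,
                        seed: int) -> list[DenoisingGroup]:
    """Noised copies of the ground truth, one per group.

    Labels flip to a uniformly random *other* class with probability
    ``label_flip_p`` (a no-op when only one class exists); each coordinate
    is jittered uniformly within +-scale * (w or h of its box), clipped back
    to the unit frame with a positive-size floor.
    """
    rng = np.random.default_rng(seed)
    groups = []
    n = len(gt_labels)
    for g in range(cfg.n_groups):
        labels = gt_labels.copy()
        if n_classes > 1:
            flip = rng.random(n) < cfg.label_flip_p
            offs = rng.integers(1, n_classes, size=n)
            labels = np.where(flip, (labels + offs) % n_classes, labels)
        boxes = gt_boxes.copy()
        if n:
            span = np.stack([boxes[:, 2], boxes[:, 3], boxes[:, 2], boxes[:, 3]], axis=1)
            jitter = rng.uniform(-1.0, 1.0, size=boxes.shape) * cfg.box_noise_scale * span
            boxes = boxes + jitter
            boxes[:, 2:] = np.clip(boxes[:, 2:], 1e-3, 1.0)
            boxes[:, :2] = np.clip(boxes[:, :2], 1e-3, 1.0 - 1e-3)
        groups.append(DenoisingGroup(labels, boxes, g))
    return groups


def build_attention_mask(group_sizes: list[int], n_matching: int) -> np.ndarray:
    """Boolean self-attention mask, True = attention blocked.

    Layout: [group_0 | group_1 | ... | matching]. Each denoising group
    attends only within itself; matching queries attend only to each other.
    No information can leak from ground-truth-derived queries into the
    matching slots (and vice versa).
    """
    total = sum(group_sizes) + n_matching
    mask = np.ones((total, total), dtype=bool)
    off = 0
    for gs in group_sizes:
        mask[off:off + gs, off:off + gs] = False
        off += gs
    mask[off:off + n_matching, off:off + n_matching] = False
    return mask


# ---------------------------------------------------------------------------
# bipartite matching
# ---------------------------------------------------------------------------

def _match_cost(class_prob: np.ndarray, boxes: np.ndarray, gt_boxes: np.ndarray,
                gt_labels: np.ndarray, weights: tuple[float, float, float],
                ratio: float, corner_mode: str) -> np.ndarray:
    lc, ll, li = weights
    n, m = boxes.shape[0], gt_boxes.shape[0]
    cost_cls = -class_prob[:, gt_labels]                       # (n, m)
    cost_l1 = np.abs(boxes[:, None, :] - gt_boxes[None, :, :]).sum(-1)
    iacd = iacd_iou_arrays(np.broadcast_to(gt_boxes[None], (n, m, 4)),
                           np.broadcast_to(boxes[:, None], (n, m, 4)),
                           ratio, ImageExtent(1.0, 1.0), corner_mode)
    return lc * cost_cls + ll * cost_l1 + li * (1.0 - iacd)


def hungarian_match(class_prob: np.ndarray, boxes: np.ndarray,
                    gt_boxes: np.ndarray, gt_labels: np.ndarray,
                    weights: tuple[float, float, float] = (2.0, 5.0, 2.0),
                    ratio: float = 0.7, corner_mode: str = "scaled",
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-cost one-to-one assignment (pred indices, gt indices)."""
    if len(gt_labels) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    C = _match_cost(class_prob, boxes, gt_boxes, gt_labels, weights, ratio, corner_mode)
    if not np.isfinite(C).all():
        raise ValueError("matching cost must be finite")
    rows, cols = linear_sum_assignment(C)
    return rows, cols


def brute_force_match(cost: np.ndarray) -> tuple[float, tuple[int, ...]]:
    """Exhaustive permutation enumeration (test oracle for small instances)."""
    n, m = cost.shape
    best_cost, best_perm = math.inf, None
    for perm in itertools.permutations(range(n), m):
        c = sum(cost[p, j] for j, p in enumerate(perm))
        if c < best_cost:
            best_cost, best_perm = c, perm
    return best_cost, best_perm


# ---------------------------------------------------------------------------
# decoder layers (batched over images)
# ---------------------------------------------------------------------------

class MultiHeadSelfAttention(ad.Module):
    def __init__(self, rng: np.random.Generator, d: int, heads: int):
        if d % heads != 0:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.wq = ad.Linear(rng, d, d)
        self.wk = ad.Linear(rng, d, d)
        self.wv = ad.Linear(rng, d, d)
        self.wo = ad.Linear(rng, d, d)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b, n, d = x.shape
        h, dh = self.heads, d // self.heads
        q = self.wq(x).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        k = self.wk(x).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        v = self.wv(x).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        if mask is not None:
            logits = logits + Tensor(np.where(mask, -1e9, 0.0)[None, None])
        attn = ad.softmax(logits, axis=-1)
        z = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.wo(z)


class DeformableCrossAttention(ad.Module):
    """Per-query deformable sampling into the multi-scale memory.

    For each query, K points per scale are sampled around the query's
    current box centre, with offsets tanh-bounded by the box half-size;
    attention weights over all scales x points are predicted directly from
    the query and softmaxed jointly, which doubles as a learned scale
    weighting. Single value head; sampled values are combined and
    output-projected.
    """

    def __init__(self, rng: np.random.Generator, d: int, n_scales: int, k_points: int):
        self.k = k_points
        self.n_scales = n_scales
        self.offset = ad.Linear(rng, d, n_scales * k_points * 2)
        self.weight = ad.Linear(rng, d, n_scales * k_points)
        self.wv = ad.Linear(rng, d, d)
        self.wo = ad.Linear(rng, d, d)

    def __call__(self, queries: Tensor, boxes: np.ndarray,
                 memory_maps: list[Tensor]) -> Tensor:
        b, nq, d = queries.shape
        S, K = self.n_scales, self.k
        centres = boxes[..., :2] * 2.0 - 1.0                   # (b, nq, 2) in [-1, 1]
        half = boxes[..., 2:4]                                 # box size in (0, 1):
        # one tanh unit spans half the box width/height in normalised coords
        dp = self.offset(queries).tanh().reshape(b, nq, S, K, 2)
        span = Tensor(np.broadcast_to(half[:, :, None, None, :], (b, nq, S, K, 2)).copy())
        base = Tensor(np.broadcast_to(centres[:, :, None, None, :], (b, nq, S, K, 2)).copy())
        coords = dp * span + base
        w = ad.softmax(self.weight(queries).reshape(b, nq, S * K), axis=-1)
        gathered = []
        for s, fmap in enumerate(memory_maps):
            cs = coords[:, :, s].reshape(b, nq * K, 2)
            gathered.append(ad.grid_sample(fmap, cs).reshape(b, nq, K, d))
        vals = self.wv(ad.concat(gathered, axis=2))            # (b, nq, S*K, d)
        mixed = (vals * w.reshape(b, nq, S * K, 1)).sum(axis=2)
        return self.wo(mixed)


class DecoderLayer(ad.Module):
    def __init__(self, rng: np.random.Generator, d: int, heads: int,
                 n_scales: int, k_points: int):
        self.self_attn = MultiHeadSelfAttention(rng, d, heads)
        self.cross_attn = DeformableCrossAttention(rng, d, n_scales, k_points)
        self.ffn = FFN(rng, d)
        self.ln = [(ad.ones_param(d), ad.zeros_param(d)) for _ in range(3)]

    def __call__(self, q: Tensor, boxes: np.ndarray, memory_maps: list[Tensor],
                 mask: np.ndarray | None) -> Tensor:
        g1, b1 = self.ln[0]
        q = ad.layer_norm(q + self.self_attn(q, mask), g1, b1)
        g2, b2 = self.ln[1]
        q = ad.layer_norm(q + self.cross_attn(q, boxes, memory_maps), g2, b2)
        g3, b3 = self.ln[2]
        return ad.layer_norm(q + self.ffn(q), g3, b3)


# ---------------------------------------------------------------------------
# the detector
# ---------------------------------------------------------------------------

class Detector(ad.Module):
    def __init__(self, cfg: DetectorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed + 100)
        d = cfg.hidden_dim
        nc = cfg.n_classes
        self.backbone = Backbone(cfg.backbone)
        self.encoder = HybridEncoder(cfg.encoder)
        # encoder-side heads for IoU-aware query selection
        self.enc_class = ad.Linear(rng, d, nc)
        self.enc_box = ad.Linear(rng, d, 4)
        self.enc_content = ad.Linear(rng, d, d)
        # decoder
        self.layers = [DecoderLayer(rng, d, cfg.heads, 3, cfg.n_sample_points)
                       for _ in range(cfg.n_decoder_layers)]
        self.dec_class = ad.Linear(rng, d, nc)
        self.dec_delta = ad.Linear(rng, d, 4)
        self.label_embed = ad.param(rng, nc, d, scale=0.02)

    # -- forward pieces ------------------------------------------------------

    def encode(self, images: np.ndarray) -> tuple[list[Tensor], Tensor]:
        """Backbone + hybrid encoder. Returns ([S3', S4', S5'], tokens)."""
        x = Tensor(np.asarray(images, dtype=np.float64))
        if x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        s3, s4, s5 = self.backbone(x)
        m3, m4, m5 = self.encoder(s3, s4, s5)
        b, d = m3.shape[0], m3.shape[1]
        toks = ad.concat(
            [m.reshape(b, d, m.shape[2] * m.shape[3]).transpose(0, 2, 1)
             for m in (m3, m4, m5)], axis=1)
        self._anchor_logits = self._token_anchors([m.shape for m in (m3, m4, m5)])
        return [m3, m4, m5], toks

    def _token_anchors(self, shapes: list[tuple]) -> np.ndarray:
        """Per-token box priors in inverse-sigmoid space.

        Each memory token sits at a known grid cell; its prior box is
        centred there with a side of anchor_base_scale doubling per level,
        so the encoder box head only refines spatially diverse anchors
        instead of regressing every box from scratch.
        """
        priors = []
        for lvl, (_, _, h, w) in enumerate(shapes):
            ys, xs = np.meshgrid((np.arange(h) + 0.5) / h, (np.arange(w) + 0.5) / w,
                                 indexing="ij")
            side = self.cfg.anchor_base_scale * (2 ** lvl)
            p = np.stack([xs.ravel(), ys.ravel(),
                          np.full(h * w, side), np.full(h * w, side)], axis=1)
            priors.append(p)
        return inverse_sigmoid(np.concatenate(priors, axis=0))

    def _select_queries(self, toks: Tensor) -> tuple[Tensor, Tensor, Tensor, np.ndarray]:
        """Encoder heads + per-image top-k selection, batch-stacked."""
        enc_logits = self.enc_class(toks)                     # (b, N, nc)
        enc_boxes = (self.enc_box(toks)
                     + Tensor(self._anchor_logits[None])).sigmoid()   # (b, N, 4)
        b = toks.shape[0]
        contents, coords = [], []
        for bi in range(b):
            qs = iou_aware_query_select(toks[bi], enc_logits[bi], enc_boxes[bi],
                                        self.cfg.n_queries)
            contents.append(qs.content)
            coords.append(qs.coords)
        content = self.enc_content(ad.stack(contents, axis=0))  # (b, k, d)
        return enc_logits, enc_boxes, content, np.stack(coords)

    def decode(self, content: Tensor, coords: np.ndarray,
               memory_maps: list[Tensor], mask: np.ndarray | None,
               ) -> list[tuple[Tensor, Tensor]]:
        """Run all decoder layers; returns per-layer (class logits, boxes).

        Boxes are refined additively in logit (inverse-sigmoid) space and
        squashed back to (0, 1) after every layer; every layer's outputs are
        kept for auxiliary supervision.
        """
        q = content
        box_logit = Tensor(inverse_sigmoid(coords))
        outputs = []
        for layer in self.layers:
            boxes_np = 1.0 / (1.0 + np.exp(-box_logit.data))
            q = layer(q, boxes_np, memory_maps, mask)
            box_logit = box_logit + self.dec_delta(q)
            boxes = box_logit.sigmoid()
            outputs.append((self.dec_class(q), boxes))
        return outputs

    def forward_train(self, images: np.ndarray,
                      gts: list[tuple[np.ndarray, np.ndarray]],
                      seed: int = 0) -> dict:
        """Full training forward for a batch.

        ``gts`` is one (boxes_normalised, labels) pair per image. Denoising
        groups are padded to the largest ground-truth count in the batch;
        ``dn_valid`` marks the real slots.
        """
        memory_maps, toks = self.encode(images)
        b = toks.shape[0]
        enc_logits, enc_boxes, content_m, coords_m = self._select_queries(toks)

        g_max = max((len(g[1]) for g in gts), default=0)
        n_groups = self.cfg.denoise.n_groups
        n_dn = g_max * n_groups
        all_groups: list[list[DenoisingGroup]] = []
        if n_dn:
            dn_labels = np.zeros((b, n_dn), dtype=int)
            dn_boxes = np.tile(np.array([0.5, 0.5, 0.1, 0.1]), (b, n_dn, 1))
            dn_valid = np.zeros((b, n_dn), dtype=bool)
            for bi, (gt_boxes, gt_labels) in enumerate(gts):
                groups = add_denoising_noise(gt_boxes, gt_labels, self.cfg.denoise,
                                             self.cfg.n_classes, seed + 31 * bi)
                all_groups.append(groups)
                ng = len(gt_labels)
                for g in groups:
                    lo = g.group_index * g_max
                    dn_labels[bi, lo:lo + ng] = g.labels
                    dn_boxes[bi, lo:lo + ng] = g.boxes
                    dn_valid[bi, lo:lo + ng] = True
            dn_content = self.label_embed[dn_labels.reshape(-1)].reshape(
                b, n_dn, self.cfg.hidden_dim)
            content = ad.concat([dn_content, content_m], axis=1)
            coords = np.concatenate([dn_boxes, coords_m], axis=1)
            mask = build_attention_mask([g_max] * n_groups, content_m.shape[1])
        else:
            dn_valid = np.zeros((b, 0), dtype=bool)
            content, coords, mask = content_m, coords_m, None

        layer_outputs = self.decode(content, coords, memory_maps, mask)
        return {
            "enc_logits": enc_logits, "enc_boxes": enc_boxes,
            "layers": layer_outputs, "groups": all_groups,
            "n_dn": n_dn, "g_max": g_max, "dn_valid": dn_valid,
            "n_match": content_m.shape[1],
        }

    def predict(self, images: np.ndarray, score_thr: float = 0.5) -> list[DetectionSet]:
        """Inference: no denoising, final layer only, threshold, no NMS."""
        memory_maps, toks = self.encode(images)
        _, _, content, coords = self._select_queries(toks)
        logits, boxes = self.decode(content, coords, memory_maps, None)[-1]
        side = float(self.cfg.image_side)
        out = []
        for bi in range(toks.shape[0]):
            probs = 1.0 / (1.0 + np.exp(-logits.data[bi]))
            labels = probs.argmax(axis=-1)
            scores = probs.max(axis=-1)
            keep = scores >= score_thr
            out.append(DetectionSet(boxes.data[bi][keep] * side, labels[keep],
                                    scores[keep]))
        return out


# ---------------------------------------------------------------------------
# losses and training
# ---------------------------------------------------------------------------

def _set_loss(logits: Tensor, boxes: Tensor, gt_boxes: np.ndarray,
              gt_labels: np.ndarray, pred_idx: np.ndarray, gt_idx: np.ndarray,
              cfg: DetectorConfig, class_targets: np.ndarray | None = None,
              loss_mask: np.ndarray | None = None) -> Tensor:
    """Classification BCE over all queries + box terms on matched pairs.

    ``loss_mask`` (same length as the query axis) excludes padded slots
    from the classification term.
    """
    lc, ll, li = cfg.loss_weights
    n, nc = logits.shape
    targets = np.zeros((n, nc))
    if class_targets is None:
        targets[pred_idx, gt_labels[gt_idx]] = 1.0
    else:
        targets[pred_idx, gt_labels[gt_idx]] = class_targets
    # positive slots are up-weighted: a few matched queries must not drown
    # in the background of hundreds of negatives
    w = np.ones((n, nc))
    w[pred_idx, gt_labels[gt_idx]] = cfg.cls_pos_weight
    if loss_mask is not None:
        w *= loss_mask.astype(float)[:, None]
    per = ad.softplus(logits) - logits * Tensor(targets)
    denom = max(float((w > 0).sum()), 1.0)
    loss = (per * Tensor(w / denom)).sum() * lc
    if len(pred_idx):
        pb = boxes[pred_idx]
        gb = gt_boxes[gt_idx]
        l1 = (pb - Tensor(gb)).relu() + (Tensor(gb) - pb).relu()
        loss = loss + l1.sum() * (ll / max(len(pred_idx), 1))
        iacd = iacd_iou_tensor(pb, gb, cfg.iou_ratio, ImageExtent(1.0, 1.0),
                               cfg.corner_mode)
        loss = loss + (1.0 - iacd).sum() * (li / max(len(pred_idx), 1))
    return loss


def _plain_iou_targets(boxes: np.ndarray, gt_boxes: np.ndarray,
                       pi: np.ndarray, gi: np.ndarray) -> np.ndarray:
    """Plain IoU of each matched predicted box with its gt (score target)."""
    if len(pi) == 0:
        return np.empty(0)
    ious = pairwise_iou(cxcywh_to_corners(boxes[pi]), cxcywh_to_corners(gt_boxes[gi]))
    return np.clip(np.diag(ious), 0.0, 1.0)


def compute_losses(model: Detector, res: dict,
                   gts: list[tuple[np.ndarray, np.ndarray]]) -> dict[str, Tensor]:
    cfg = model.cfg
    zero = Tensor(0.0)
    enc_loss, match_loss, dn_loss = zero, zero, zero
    n_dn, g_max = res["n_dn"], res["g_max"]
    nb = len(gts)
    for bi, (gt_boxes, gt_labels) in enumerate(gts):
        enc_logits_i = res["enc_logits"][bi]
        enc_boxes_i = res["enc_boxes"][bi]
        probs = 1.0 / (1.0 + np.exp(-enc_logits_i.data))
        pi, gi = hungarian_match(probs, enc_boxes_i.data, gt_boxes, gt_labels,
                                 cfg.loss_weights, cfg.iou_ratio, cfg.corner_mode)
        iou_t = _plain_iou_targets(enc_boxes_i.data, gt_boxes, pi, gi)
        enc_loss = enc_loss + _set_loss(enc_logits_i, enc_boxes_i, gt_boxes,
                                        gt_labels, pi, gi, cfg, class_targets=iou_t)
        ng = len(gt_labels)
        for logits, boxes in res["layers"]:
            m_logits, m_boxes = logits[bi][n_dn:], boxes[bi][n_dn:]
            probs = 1.0 / (1.0 + np.exp(-m_logits.data))
            pi, gi = hungarian_match(probs, m_boxes.data, gt_boxes, gt_labels,
                                     cfg.loss_weights, cfg.iou_ratio, cfg.corner_mode)
            match_loss = match_loss + _set_loss(m_logits, m_boxes, gt_boxes,
                                                gt_labels, pi, gi, cfg)
            if n_dn and ng:
                d_logits, d_boxes = logits[bi][:n_dn], boxes[bi][:n_dn]
                valid = np.nonzero(res["dn_valid"][bi])[0]
                # assignment known by construction: slot g*g_max+j <-> gt j
                gt_rep = valid % g_max
                dn_loss = dn_loss + _set_loss(d_logits, d_boxes, gt_boxes,
                                              gt_labels, valid, gt_rep, cfg,
                                              loss_mask=res["dn_valid"][bi])
    nl = max(len(res["layers"]), 1)
    return {
        "encoder": enc_loss * (1.0 / nb),
        "matching": match_loss * (1.0 / (nb * nl)),
        "denoising": dn_loss * (1.0 / (nb * nl)),
    }


def train_step(model: Detector, opt: ad.Adam, images: np.ndarray,
               gts: list[tuple[np.ndarray, np.ndarray]], seed: int = 0,
               ) -> dict[str, float]:
    """One optimisation step on a batch; returns the scalar loss parts."""
    if len(images) == 0:
        raise ValueError("empty batch")
    res = model.forward_train(images, gts, seed=seed)
    losses = compute_losses(model, res, gts)
    total = losses["encoder"] + losses["matching"] + losses["denoising"]
    opt.zero_grad()
    total.backward()
    opt.step()
    out = {k: v.item() for k, v in losses.items()}
    out["total"] = total.item()
    return out


def fit_detector(model: Detector, images: np.ndarray,
                 gts: list[tuple[np.ndarray, np.ndarray]], steps: int = 300,
                 lr: float = 1e-3, warmup: int = 20, lr_floor: float = 0.2,
                 ema_decay: float | None = 0.95, ema_start: float = 0.75,
                 seed: int = 0, log_every: int = 0) -> list[dict[str, float]]:
    """Full-batch training with linear warmup and cosine learning-rate decay
    to ``lr_floor``-fraction of the peak (decaying fully to zero stalls the
    last phase of box refinement at these step counts). Over the last
    (1 - ``ema_start``) fraction of training an exponential moving average
    of the parameters (decay ``ema_decay``) is accumulated and written back
    into the model at the end: per-layer bipartite matching makes late
    training oscillate, and the averaged weights sit near the oscillation
    centre instead of wherever the final step happened to land.

    Returns the per-step loss records. This is the recipe the toy detector
    uses to overfit a small scene set; it is deterministic in ``seed``.
    """
    params = model.parameters()
    opt = ad.Adam(params, lr=lr, clip_norm=5.0)
    history = []
    ema: list[np.ndarray] | None = None
    for step in range(steps):
        if step < warmup:
            opt.lr = lr * (step + 1) / warmup
        else:
            c = 0.5 * (1 + math.cos(math.pi * (step - warmup)
                                    / max(steps - warmup, 1)))
            opt.lr = lr * (lr_floor + (1 - lr_floor) * c)
        losses = train_step(model, opt, images, gts, seed=seed + step)
        history.append(losses)
        if ema_decay is not None and step >= int(ema_start * steps):
            if ema is None:
                ema = [p.data.copy() for p in params]
            else:
                for e, p in zip(ema, params):
                    e += (1.0 - ema_decay) * (p.data - e)
        if log_every and (step + 1) % log_every == 0:
            print(f"step {step + 1}/{steps} total={losses['total']:.3f}")
    if ema is not None:
        for e, p in zip(ema, params):
            p.data = e
    return history


def detect(image: np.ndarray, model: Detector, score_thr: float = 0.5) -> DetectionSet:
    """Detect lesions in one grayscale image (side x side, values in [0, 1])."""
    return model.predict(image[None], score_thr=score_thr)[0]


def scenes_to_gts(scenes: list[SyntheticScene], side: float,
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Tight xywh pixel boxes -> normalised cxcywh (the training frame)."""
    gts = []
    for sc in scenes:
        b = sc.boxes.copy()
        cx = (b[:, 0] + b[:, 2] / 2) / side
        cy = (b[:, 1] + b[:, 3] / 2) / side
        gts.append((np.stack([cx, cy, b[:, 2] / side, b[:, 3] / side], axis=1),
                    sc.labels.astype(int)))
    return gts
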