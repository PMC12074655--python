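"""Detection metrics and the orthogonality ablation.

Precision and recall are the usual confusion-count ratios; average
precision follows the COCO convention — detections matched to ground truth
greedily in descending score order at a fixed IoU threshold (each gt
usable once, matching by plain IoU, never the training-time score), and AP
is the 101-point interpolated area under the precision-recall curve.
mAP@50 averages AP over classes at IoU 0.5; mAP@50:95 additionally averages
over thresholds 0.50, 0.55, ..., 0.95.

The ablation trains two matched small classifiers — identical except that
the channel-attention filter bank is within-filter special-orthogonal in
one and between-filter Gram-Schmidt in the other — on shrinking fractions
of a synthetic two-class set, reporting train/validation losses, accuracies
and the train-validation loss gap per fraction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .detector import DetectionSet, cxcywh_to_corners
from .iou import pairwise_iou
from .ortho_filters import build_filter_bank
from .backbone import AttentionMLP, orthogonal_projection
from .synthetic import SyntheticDatasetConfig, small_classification_variant, subset_fraction

__all__ = [
    "ConfusionCounts",
    "precision_recall",
    "average_precision",
    "map_range",
    "fps_from_timings",
    "match_detections",
    "OrthoClassifier",
    "orthogonality_ablation",
]

IOU_GRID = np.arange(0.50, 0.96, 0.05).round(2)
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); zero denominators give 0."""
    p = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    r = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    return p, r


def fps_from_timings(t_pre: float, t_inf: float, t_post: float) -> float:
    """Frames per second from per-stage millisecond timings."""
    if min(t_pre, t_inf, t_post) < 0:
        raise ValueError("timings must be nonnegative")
    total = t_pre + t_inf + t_post
    if total == 0:
        raise ValueError("total time must be positive")
    return 1000.0 / total


def match_detections(dets: list[DetectionSet], gts: list[tuple[np.ndarray, np.ndarray]],
                     iou_threshold: float, class_id: int,
                     ) -> tuple[np.ndarray, np.ndarray, int]:
    """Greedy score-descending matching of one class across all images.

    Returns (scores, is_tp flags) over all detections of the class, plus the
    total gt count. gts carry (cxcywh boxes, labels) in the same pixel frame
    as the detections.
    """
    all_scores, all_tp = [], []
    n_gt = 0
    for det, (gt_boxes, gt_labels) in zip(dets, gts):
        gmask = gt_labels == class_id
        g = cxcywh_to_corners(gt_boxes[gmask]) if gmask.any() else np.zeros((0, 4))
        n_gt += g.shape[0]
        dmask = det.labels == class_id
        boxes = cxcywh_to_corners(det.boxes[dmask])
        scores = det.scores[dmask]
        order = np.argsort(-scores, kind="stable")
        used = np.zeros(g.shape[0], dtype=bool)
        iou = pairwise_iou(boxes, g) if len(boxes) and len(g) else np.zeros((len(boxes), len(g)))
        for i in order:
            tp = False
            if g.shape[0]:
                cand = np.where(~used & (iou[i] >= iou_threshold))[0]
                if cand.size:
                    used[cand[np.argmax(iou[i][cand])]] = True
                    tp = True
            all_scores.append(scores[i])
            all_tp.append(tp)
    return np.array(all_scores), np.array(all_tp, dtype=bool), n_gt


def average_precision(dets: list[DetectionSet], gts: list[tuple[np.ndarray, np.ndarray]],
                      iou_threshold: float = 0.5, class_id: int = 0) -> float:
    """101-point interpolated AP at one IoU threshold for one class."""
    scores, tp, n_gt = match_detections(dets, gts, iou_threshold, class_id)
    if n_gt == 0:
        return 0.0
    if scores.size == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = tp[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # interpolated precision: max precision at recall >= r
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    for r in RECALL_GRID:
        idx = np.searchsorted(recall, r, side="left")
        ap += p_interp[idx] if idx < len(p_interp) else 0.0
    return ap / len(RECALL_GRID)


def map_range(dets: list[DetectionSet], gts: list[tuple[np.ndarray, np.ndarray]],
              n_classes: int = 1) -> tuple[float, float]:
    """(mAP@50, mAP@50:95) averaged over classes (and the IoU grid)."""
    ap50 = np.mean([average_precision(dets, gts, 0.5, c) for c in range(n_classes)])
    aps = [np.mean([average_precision(dets, gts, t, c) for c in range(n_classes)])
           for t in IOU_GRID]
    return float(ap50), float(np.mean(aps))


# ---------------------------------------------------------------------------
# orthogonality ablation
# ---------------------------------------------------------------------------

class OrthoClassifier(ad.Module):
    """Small convnet with one orthogonal-projection channel-attention stage.

    conv(stride 2) -> relu -> conv(stride 2) -> relu -> [projection onto the
    frozen filter bank -> MLP -> sigmoid channel reweighting] -> global mean
    pool -> linear logits. The bank mode (within-filter special-orthogonal
    vs between-filter Gram-Schmidt) is the only thing that differs between
    the two ablation arms; all trainable parameters start identical.
    """

    def __init__(self, side: int, n_classes: int, mode: str, seed: int,
                 channels: int = 8):
        rng = np.random.default_rng(seed)          # same seed => same shared init
        self.w1 = ad.param(rng, channels, 1, 3, 3)
        self.b1 = ad.zeros_param(channels)
        self.w2 = ad.param(rng, channels, channels, 3, 3)
        self.b2 = ad.zeros_param(channels)
        self.attn = AttentionMLP(rng, channels, max(1, channels // 4))
        self.head = ad.Linear(rng, channels, n_classes)
        feat_side = side // 4
        self.bank = build_filter_bank(channels, feat_side, mode, seed + 999)

    def shared_checksum(self) -> float:
        """Sum over every trainable parameter (bank excluded)."""
        return float(sum(p.data.sum() for p in self.parameters()))

    def __call__(self, images: np.ndarray) -> Tensor:
        x = Tensor(np.asarray(images, dtype=np.float64)[:, None])
        y = ad.conv2d(x, self.w1, self.b1, stride=2, pad=1).relu()
        y = ad.conv2d(y, self.w2, self.b2, stride=2, pad=1).relu()
        f = orthogonal_projection(y, self.bank)
        alpha = self.attn(f)
        b, c = alpha.shape
        y = y * alpha.reshape(b, c, 1, 1)
        pooled = y.mean(axis=(2, 3))
        return self.head(pooled)


def _xent(logits: Tensor, labels: np.ndarray) -> Tensor:
    p = ad.softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = p[np.arange(n), labels]
    return -(picked.clip_min(1e-12).log()).mean()


def _accuracy(logits: Tensor, labels: np.ndarray) -> float:
    return float((logits.data.argmax(axis=-1) == labels).mean())


def orthogonality_ablation(fractions: tuple[float, ...] = (1.0, 0.5, 0.2, 0.1),
                           seeds: tuple[int, ...] = (0,), epochs: int = 30,
                           n_images: int = 80, image_side: int = 32,
                           lr: float = 3e-3, out_dir: str | Path | None = None,
                           ) -> list[dict]:
    """Matched-pair comparison of filter-orthogonality schemes under
    shrinking training fractions.

    For each (fraction, seed): train the within-filter and between-filter
    classifiers from identical shared initialisation on the same subset,
    evaluate on a held-out validation half, and record final train/val
    losses, accuracies, and the train-val loss gap. Returns one row per
    model per fraction per seed; optionally writes CSV + loss-curve plots.
    """
    rows: list[dict] = []
    for seed in seeds:
        cfg = SyntheticDatasetConfig(n_images=n_images * 2, image_side=image_side,
                                     semi_axis_min=0.10 * image_side,
                                     semi_axis_max=0.20 * image_side,
                                     skull_ring=False, seed=seed)
        images, labels = small_classification_variant(cfg)
        train_idx = np.arange(0, len(labels), 2)
        val_idx = np.arange(1, len(labels), 2)
        for fraction in fractions:
            sub = subset_fraction(labels[train_idx], fraction, seed=seed)
            tr = train_idx[sub]
            for mode in ("special_orthogonal", "gram_schmidt"):
                model = OrthoClassifier(image_side, 2, mode, seed=seed + 12345)
                opt = ad.Adam(model.parameters(), lr=lr)
                curve = []
                for _ in range(epochs):
                    logits = model(images[tr])
                    loss = _xent(logits, labels[tr])
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    curve.append(loss.item())
                tr_logits = model(images[tr])
                va_logits = model(images[val_idx])
                tr_loss = _xent(tr_logits, labels[tr]).item()
                va_loss = _xent(va_logits, labels[val_idx]).item()
                rows.append({
                    "seed": seed, "fraction": fraction, "mode": mode,
                    "train_loss": tr_loss, "val_loss": va_loss,
                    "gap": va_loss - tr_loss,
                    "train_acc": _accuracy(tr_logits, labels[tr]),
                    "val_acc": _accuracy(va_logits, labels[val_idx]),
                    "shared_checksum": model.shared_checksum(),
                    "curve": curve,
                })
    if out_dir is not None:
        _write_ablation_report(rows, Path(out_dir))
    return rows


def _write_ablation_report(rows: list[dict], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cols = ["seed", "fraction", "mode", "train_loss", "val_loss", "gap",
            "train_acc", "val_acc"]
    with (out / "ablation.csv").open("w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=cols)
        wr.writeheader()
        for r in rows:
            wr.writerow({k: r[k] for k in cols})
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fracs = sorted({r["fraction"] for r in rows}, reverse=True)
        fig, axes = plt.subplots(1, len(fracs), figsize=(4 * len(fracs), 3),
                                 squeeze=False)
        for ax, f in zip(axes[0], fracs):
            for r in rows:
                if r["fraction"] == f:
                    ax.plot(r["curve"], label=r["mode"])
            ax.set_title(f"fraction {f}")
            ax.set_xlabel("epoch")
            ax.set_ylabel("train loss")
            ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / "ablation_curves.png", dpi=100)
        plt.close(fig)
    except Exception:   # plotting is best-effort reporting
        pass
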