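"""Synthetic lesion scenes for desk-scale detector development.

Real lesion-detection corpora (single bright tumour-like masses on noisy
grayscale backgrounds, most boxes under 20% of the image area) are emulated
by the simplest structure that yields a learnable detection signal:
intensity-offset ellipses with blurred edges on a smooth noisy background,
optionally ringed by a bright "skull" annulus. No anatomical realism is
attempted — the generator exists so every stage of the pipeline is testable
without downloads.

Annotations are written as COCO-dialect JSON (x_min, y_min, width, height in
absolute pixels, continuous 0-based coordinates), with an optional YOLO-txt
mirror (class cx cy w h normalised to (0, 1)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "LesionSpec",
    "SyntheticDatasetConfig",
    "SyntheticScene",
    "render_scene",
    "generate_dataset",
    "load_coco",
    "write_coco",
    "small_classification_variant",
    "subset_fraction",
]


@dataclass(frozen=True)
class LesionSpec:
    """One elliptical lesion: centre, semi-axes, rotation, intensity offset."""

    cx: float
    cy: float
    a: float
    b: float
    angle: float
    intensity: float
    class_id: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    """Conditions of the synthetic study.

    Defaults emulate the box statistics of small tumour-detection corpora:
    1-2 lesions per 160 px image with semi-axes 8-28 px, so nearly all tight
    boxes stay under 20% of the image area; background noise sigma 0.05 on a
    unit intensity scale with lesions offset by +0.45 — a clear but noisy
    signal.
    """

    n_images: int = 16
    image_side: int = 160
    lesions_min: int = 1
    lesions_max: int = 2
    semi_axis_min: float = 8.0
    semi_axis_max: float = 28.0
    intensity_offset: float = 0.45
    noise_sigma: float = 0.05
    skull_ring: bool = True
    max_box_area_fraction: float = 0.2
    n_classes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.max_box_area_fraction <= 1.0):
            raise ValueError("max_box_area_fraction must be in (0, 1]")


@dataclass
class SyntheticScene:
    image: np.ndarray                 # (side, side) float in [0, 1]
    lesions: list[LesionSpec]
    boxes: np.ndarray                 # (n, 4) x_min, y_min, w, h (tight)
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


LESION_THRESHOLD_FRACTION = 0.5   # a pixel belongs to a lesion once its
                                  # added intensity exceeds half the offset


def _ellipse_mask(side: int, spec: LesionSpec) -> np.ndarray:
    """Soft-edged ellipse intensity field in [0, 1]."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    dx, dy = xx - spec.cx, yy - spec.cy
    ca, sa = np.cos(spec.angle), np.sin(spec.angle)
    u = (dx * ca + dy * sa) / spec.a
    v = (-dx * sa + dy * ca) / spec.b
    hard = (u * u + v * v <= 1.0).astype(np.float64)
    return gaussian_filter(hard, sigma=1.0)


def render_scene(cfg: SyntheticDatasetConfig, rng: np.random.Generator) -> SyntheticScene:
    """Render one scene: background + noise (+ ring) + lesions + tight boxes.

    Tight boxes bound the pixels where a lesion's rendered (blurred)
    intensity exceeds half its offset; placement is retried until the box
    area constraint and full containment hold.
    """
    side = cfg.image_side
    # smooth background: low-frequency field around 0.35
    bg = gaussian_filter(rng.normal(0.35, 0.15, (side, side)), sigma=side / 8.0)
    img = bg + rng.normal(0.0, cfg.noise_sigma, (side, side))
    if cfg.skull_ring:
        yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
        r = np.hypot(xx - side / 2.0, yy - side / 2.0)
        ring = np.exp(-((r - 0.46 * side) ** 2) / (2.0 * (0.02 * side) ** 2))
        img += 0.35 * ring

    n_lesions = int(rng.integers(cfg.lesions_min, cfg.lesions_max + 1))
    lesions: list[LesionSpec] = []
    boxes: list[list[float]] = []
    labels: list[int] = []
    max_area = cfg.max_box_area_fraction * side * side
    for _ in range(n_lesions):
        for _attempt in range(50):
            a = rng.uniform(cfg.semi_axis_min, cfg.semi_axis_max)
            b = rng.uniform(cfg.semi_axis_min, cfg.semi_axis_max)
            margin = max(a, b) + 4.0
            if 2 * margin >= side:
                continue
            cx = rng.uniform(margin, side - margin)
            cy = rng.uniform(margin, side - margin)
            spec = LesionSpec(cx, cy, a, b, rng.uniform(0.0, np.pi),
                              cfg.intensity_offset, int(rng.integers(cfg.n_classes)))
            field_ = _ellipse_mask(side, spec)
            mask = field_ > LESION_THRESHOLD_FRACTION
            if not mask.any():
                continue
            ys, xs = np.nonzero(mask)
            x0, x1 = xs.min(), xs.max()
            y0, y1 = ys.min(), ys.max()
            bw, bh = float(x1 - x0 + 1), float(y1 - y0 + 1)
            if bw * bh > max_area:
                continue
            img += spec.intensity * field_
            lesions.append(spec)
            boxes.append([float(x0), float(y0), bw, bh])
            labels.append(spec.class_id)
            break
        else:
            raise RuntimeError("could not place a lesion satisfying the area constraint")
    img = np.clip(img, 0.0, 1.0)
    return SyntheticScene(img, lesions,
                          np.array(boxes, dtype=np.float64).reshape(-1, 4),
                          np.array(labels, dtype=int))


# -- dataset I/O -------------------------------------------------------------

def write_coco(records: list[dict], annotations: list[dict], n_classes: int,
               path: Path) -> None:
    doc = {
        "images": records,
        "annotations": annotations,
        "categories": [{"id": i, "name": f"lesion_{i}"} for i in range(n_classes)],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_coco(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def generate_dataset(cfg: SyntheticDatasetConfig, out_dir: str | Path,
                     yolo_mirror: bool = False) -> Path:
    """Write ``cfg.n_images`` PNGs plus COCO-dialect ``annotations.json``
    (and an optional YOLO-txt mirror). Fully reproducible from ``cfg.seed``.
    Returns the annotation path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    records, annotations = [], []
    ann_id = 0
    for i in range(cfg.n_images):
        scene = render_scene(cfg, rng)
        name = f"img_{i:04d}.png"
        Image.fromarray((scene.image * 255).astype(np.uint8)).save(out / name)
        records.append({"id": i, "file_name": name,
                        "width": cfg.image_side, "height": cfg.image_side})
        for box, lab in zip(scene.boxes, scene.labels):
            annotations.append({
                "id": ann_id, "image_id": i, "category_id": int(lab),
                "bbox": [round(float(v), 2) for v in box],
                "area": round(float(box[2] * box[3]), 2), "iscrowd": 0,
            })
            ann_id += 1
        if yolo_mirror:
            s = float(cfg.image_side)
            lines = [
                f"{lab} {(b[0] + b[2] / 2) / s:.6f} {(b[1] + b[3] / 2) / s:.6f} "
                f"{b[2] / s:.6f} {b[3] / s:.6f}"
                for b, lab in zip(scene.boxes, scene.labels)
            ]
            (out / f"img_{i:04d}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
    ann_path = out / "annotations.json"
    write_coco(records, annotations, cfg.n_classes, ann_path)
    return ann_path


def scenes_in_memory(cfg: SyntheticDatasetConfig) -> list[SyntheticScene]:
    """The same scene stream :func:`generate_dataset` writes, kept in memory
    (the form the training loop and tests consume)."""
    rng = np.random.default_rng(cfg.seed)
    return [render_scene(cfg, rng) for _ in range(cfg.n_images)]


# -- classification variant (for the orthogonality ablation) -----------------

def small_classification_variant(cfg: SyntheticDatasetConfig) -> tuple[np.ndarray, np.ndarray]:
    """Two-class image set: lesion present (1) vs absent (0), balanced.

    Returns (images, labels) with images (n, side, side) in [0, 1]. Used by
    the ablation comparing within-filter vs between-filter orthogonal
    attention under shrinking training fractions.
    """
    if cfg.n_images < 2:
        raise ValueError("need at least 2 images for two classes")
    rng = np.random.default_rng(cfg.seed)
    imgs, labels = [], []
    for i in range(cfg.n_images):
        present = i % 2 == 1
        sub = SyntheticDatasetConfig(**{**asdict(cfg),
                                        "lesions_min": 1 if present else 0,
                                        "lesions_max": cfg.lesions_max if present else 0})
        scene = render_scene(sub, rng)
        imgs.append(scene.image)
        labels.append(int(present))
    return np.stack(imgs), np.array(labels, dtype=int)


def subset_fraction(labels: np.ndarray, fraction: float, seed: int = 0) -> np.ndarray:
    """Class-balanced, *nested* subset indices: for fixed seed, the 10%
    subset is contained in the 20% subset, and so on up to 100%."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    picked: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        order = rng.permutation(idx)           # one fixed order per class;
        k = int(round(fraction * idx.size))    # prefixes nest across fractions
        if k < 1:
            raise ValueError(f"fraction {fraction} leaves no samples of class {cls}")
        picked.append(order[:k])
    return np.sort(np.concatenate(picked))
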