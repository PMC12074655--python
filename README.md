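# orthodetr

Components and a desk-scale end-to-end detector for bright-lesion detection
in grayscale medical-style images, built around three ideas:

* **Within-filter orthogonal channel attention** — each feature channel is
  projected onto a frozen filter drawn from the special orthogonal group
  SO(n) = {R : RᵀR = I, det R = +1}. Orthonormal rows/columns give every
  filter unit spectral norm, so stacks of such maps with ReLU cannot expand
  input perturbations (‖f(x)−f(y)‖ ≤ ‖x−y‖) — a capacity control aimed at
  small medical datasets. The between-filter alternative (Gram–Schmidt
  across flattened filters) is included as the ablation baseline.
* **Deformable attention** — queries attend to keys/values bilinearly
  sampled at a reference grid shifted by bounded learned offsets
  Δp = s·tanh(θ(q)), with an interpolated relative-position bias; applied
  intra-scale to the deepest feature map (AIFI) inside a hybrid encoder
  with convolutional cross-scale fusion (CCFM, re-parameterisable
  RepBlocks).
* **IACD-IoU** — box agreement scored as
  `IoU_inner(gt, a; ratio) − d₁²/(w²+h²) − d₂²/(w²+h²)`: the IoU of both
  boxes shrunk about their centres by `ratio` (0.7), penalised by the
  normalised squared distances between corresponding top-left and
  bottom-right corners. The training loss is `1 − IACD-IoU`.

These feed a DETR-style set-prediction detector (orthogonal channel-shuffle
backbone → hybrid encoder → decoder with IoU-aware query selection,
denoising groups, Hungarian matching; no NMS), trained and evaluated
entirely on a bundled synthetic lesion-scene generator — no data downloads.
All trainable modules run on a small in-repo reverse-mode autodiff engine
over float64 numpy; every backward pass is checked against finite
differences in the tests.

## Worked example

```python
import numpy as np
from orthodetr import (BoxCXCYWH, ImageExtent, inner_iou, iacd_iou,
                       sample_special_orthogonal, verify_lipschitz_chain)

# IACD-IoU of two 20x20 boxes whose centres differ by (5, 5), ratio 0.7,
# in a 100x100 image
gt = BoxCXCYWH(50, 50, 20, 20)
anchor = BoxCXCYWH(55, 55, 20, 20)
print(inner_iou(gt, anchor, 0.7))                  # 0.2604501607717042
print(iacd_iou(gt, anchor, 0.7, ImageExtent(100, 100)))
                                                   # 0.2554501607717042

# the non-expansion property of orthogonal ReLU chains
mats = [sample_special_orthogonal(16, s).entries for s in range(4)]
rng = np.random.default_rng(0)
x, y = rng.normal(size=16), rng.normal(size=16)
print(verify_lipschitz_chain(mats, x, y))          # 0.42964... (<= 1)
```

The scaled boxes are (43,43,57,57) and (48,48,62,62): intersection 9² = 81,
union 2·196 − 81 = 311, so IoU_inner = 81/311 ≈ 0.26045; each corner
penalty is 50/20000 = 0.0025, giving IACD-IoU = 81/311 − 0.005 ≈ 0.25545.
The contraction ratio never exceeds 1 for orthogonal layers.

End-to-end from the shell:

```bash
orthodetr synth --out data/ --n-images 16 --image-side 160 --seed 0
orthodetr train --data data/ --out ckpt.bin --steps 300 --seed 0
orthodetr eval --ckpt ckpt.bin --data data/ --score-thr 0.05
orthodetr ablate --out report/ --fractions 1.0,0.5,0.2,0.1
```

`eval` prints `mAP@50` and `mAP@50:95` (COCO convention: greedy matching at
each IoU threshold, 101-point interpolated AP). `ablate` writes a CSV
comparing the within-filter and between-filter attention arms across
training-set fractions, including the train-validation loss gap that the
orthogonality argument predicts should favour the within-filter model as
data shrinks.

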