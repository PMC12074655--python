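# Methods

## What the package computes

`orthodetr` is a component library and desk-scale end-to-end detector for
bright-lesion detection in grayscale images. Its scientific core is three
ideas and the machinery to exercise them:

1. **Within-filter orthogonal channel attention.** Channel attention is
   computed by projecting each channel of a square feature map F (b, c, h, w)
   onto a fixed filter W_i of side n = h = w drawn from SO(n) — the group of
   real n x n matrices with R^T R = I and det R = +1. The projection
   coefficients f[b, i] = sum(F[b, i] * W_i) pass through a two-layer MLP
   with a sigmoid to give channel weights in (0, 1). Because each filter has
   orthonormal rows and columns, it has unit spectral norm: composing such
   maps with 1-Lipschitz activations cannot expand input perturbations
   (`verify_lipschitz_chain` measures this), which is the regularisation
   argument for the design. The contrast case — *between-filter*
   orthogonality, where flattened filters are Gram-Schmidt-orthonormalised
   against each other with no constraint inside a filter — is implemented as
   the second arm of the ablation.

2. **Deformable attention.** Keys and values are sampled at a uniform
   reference grid shifted by learned offsets Delta_p = s * tanh(theta(q)),
   bounded by the amplitude s; attention is ordinary scaled dot product
   between all queries and only the H_G * W_G sampled keys, optionally with
   a relative-position bias interpolated from a learnable table at the
   continuous normalised displacement between query and key. The hybrid
   encoder applies this attention to the deepest scale only (AIFI) and
   fuses scales convolutionally (CCFM with re-parameterisable RepBlocks).

3. **IACD-IoU.** Box agreement is scored as
   `IoU_inner(gt, anchor; ratio) - d1^2/(w^2+h^2) - d2^2/(w^2+h^2)`:
   the IoU of both boxes shrunk about their centres by `ratio` (default
   0.7), minus normalised squared distances between the top-left and
   bottom-right corners. The training loss is `1 - IACD-IoU` on matched
   pairs. The per-axis overlap is clamped at zero before multiplying, since
   a signed product would make disjoint boxes score positive intersection.
   The union denominator is floored at 1e-9 rather than additively
   perturbed, so identical boxes score exactly 1 and the score is exactly
   scale-invariant in its IoU part.

## Numerical substrate

No deep-learning framework is used; all trainable modules run on a small
in-repo reverse-mode autodiff engine (`autodiff.py`) over float64 numpy
arrays: dense algebra, im2col convolution, batch/layer norm, softmax, and a
bilinear grid sampler differentiable in both the feature map and the
sampling coordinates (almost everywhere; border-clamped coordinates get
zero coordinate-gradient). Float64 was chosen so finite-difference gradient
checks discriminate real errors at 1e-4 tolerances; the models here are
small enough that speed is acceptable. Every op's backward pass is verified
against central differences in the test suite.

## Corner convention in the penalty term

The defining equations first introduce plain box corners and then redefine
them as scaled corners before the distance terms; the corner-distance
precedent (MPDIoU) uses unscaled corners. Both readings are implemented
behind `corner_mode={scaled|original}` with `scaled` — the literal reading —
as the default. For equal-sized boxes the two coincide up to the ratio
factor on the centre distance.

## Detector assembly

* **Backbone**: stem (two stride-2 3x3 convs) then three stages of
  shuffle blocks at strides 8/16/32. Each block: conv-norm-relu-conv-norm,
  orthogonal-projection attention, residual shortcut (1x1 conv when shapes
  change), channel shuffle, ReLU. A single ReLU follows the shuffle: a
  channel permutation commutes with any elementwise map, so a second ReLU
  before it would be redundant (asserted as a test property). Filter banks
  are frozen, created lazily per (channels, spatial side) from the run seed
  and cached; non-square maps raise unless `pad_to_square` is set.
* **Encoder**: 1x1 projections to one hidden dim; AIFI on S5; PAN-style
  CCFM (nearest-neighbour x2 upsampling top-down, stride-2 conv bottom-up,
  fusion = concat -> 1x1 reduce -> RepBlocks). Where the bottom-up pathway
  meets a top-down lateral at the same scale the maps are added
  element-wise; the finest scale passes through unchanged.
* **Decoder**: top-k encoder tokens by class confidence initialise the
  queries (IoU-aware: the encoder score head is trained toward the plain
  IoU between its predicted box and the matched ground truth). Each token
  carries a spatial anchor prior — a box centred at the token's grid cell
  whose side doubles per level (`anchor_base_scale`, default 0.1 at stride
  8) — so the box head refines diverse anchors instead of regressing from a
  common point; this mirrors standard practice in real-time detection
  transformers and was decisive for convergence speed at desk scale.
  Denoising groups (noised copies of the ground truth, DN-style) join the
  matching queries under a block-diagonal attention mask: each group
  attends only within itself and matching queries only to each other, so
  no ground-truth information can leak into the matching slots. Decoder
  layers: masked self-attention, deformable cross-attention (per scale, K
  points sampled around the query's current box centre with tanh-bounded
  offsets scaled by the box half-size; jointly softmaxed point weights act
  as a learned scale weighting), FFN; boxes are refined additively in
  inverse-sigmoid space. Inference applies a score threshold and no NMS.

## Losses and matching

Per-layer Hungarian matching with cost
`2 * (-p_class) + 5 * L1 + 2 * (1 - IACD)` (DETR-family weights; IACD-IoU
is used in both the matching cost and the box loss, plain IoU only for the
encoder's score supervision and for evaluation). Classification is binary
cross-entropy per class with matched slots up-weighted by
`cls_pos_weight = 8`: with 50-300 queries and one or two objects, unweighted
BCE drowns the positives and confidence never rises — the weight is the
standard imbalance correction expressed in its simplest form. Denoising
queries use the same loss with their known assignment; padded denoising
slots (batches mix images with different object counts) are excluded from
every term.

## Training recipe

Full-batch Adam (gradient-norm clip 5.0) with 20-step linear warmup and
cosine decay to a 20% floor of the peak rate (`fit_detector`; decaying all
the way to zero stalls late box refinement at these step counts). Over the
final quarter of training an exponential moving average of the parameters
(decay 0.95) is accumulated and becomes the returned model: per-layer
bipartite matching makes late training oscillate, and the averaged weights
sit near the oscillation centre instead of wherever the last step landed.
Evaluation of trained models uses a near-zero score threshold (0.01):
average precision is ranking-based, and the COCO convention scores all
ranked detections rather than pre-thresholding them. The toy configuration — 160 px images,
hidden dim 64, 2 decoder layers, 50 queries, backbone channels
(16, 32, 64) x depth 1, one RepBlock per fusion — overfits 16 synthetic
scenes to mAP@50 >= 0.9 in 300 steps, a few minutes on one CPU. Problem
sizes throughout (16 scenes, 300 steps, 40-image ablation sets, 15 ablation
epochs) were chosen as the smallest instances that exercise every component
and converge reliably.

## Synthetic scenes

The generator emulates the statistics of small lesion-detection corpora:
single bright elliptical masses (Gaussian-blurred edges, intensity offset
+0.45 on a unit scale) on a smooth noisy background (sigma 0.05), an
optional bright ring mimicking a skull outline, 1-2 lesions per image with
semi-axes 8-28 px at side 160, and tight boxes bounding the pixels where
the rendered lesion field exceeds half its offset. Boxes are capped at 20%
of the image area and in practice >= 90% fall below it, matching the small-
object regime of the motivating data. It does **not** model anatomy, MRI
physics, intensity inhomogeneity or multi-class tumour typology: passing
tests show the pipeline learns and evaluates correctly on a clean, learnable
signal, not that it would reach any particular accuracy on clinical data.

## Evaluation

COCO-convention metrics: greedy score-descending matching at a fixed IoU
threshold (plain IoU, one use per ground truth), 101-point interpolated AP,
mAP@50 and the mean over thresholds 0.50-0.95 in 0.05 steps. Zero
denominators in precision/recall return 0. The independent oracles are a
rasterized IoU (counting lattice cells of pitch `step`; the count
factorises per axis for axis-aligned boxes, which makes the 10^4-pair
equivalence check cheap) and an explicit threshold-sweep AP computation.

## Ablation

`orthogonality_ablation` trains matched classifier pairs — identical shared
initialisation, only the frozen attention bank differs (within-filter SO(n)
vs between-filter Gram-Schmidt) — on class-balanced nested subsets (100%,
50%, 20%, 10%) of a synthetic two-class set, and reports final train/val
losses, accuracies and the train-val loss gap per arm. The direction of the
gap difference is reported, never hard-asserted: at these sizes it is a
noisy quantity and single-seed reversals are expected.

## Known limitations

* The full-size configuration (hidden 256, 300 queries, 6 decoder layers)
  is wired but not trained anywhere; only the toy configuration is
  exercised end to end.
* Decoder cross-attention approximates multi-scale deformable attention
  with per-scale sampling plus learned scale weights; a faithful fused
  kernel is out of scope.
* Batch norm always uses batch statistics (no running averages), which is
  correct for the fixed-batch training and probing done here but would need
  an inference mode for variable-batch deployment.
* Bilinear sampling is non-differentiable on the integer lattice and has
  zero coordinate-gradient outside the border; gradient checks sample away
  from these measure-zero sets.
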