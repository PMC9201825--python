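# Methods

Exact definitions, parameter choices, and limitations for each component.
Boxes are axis-aligned `(x_min, y_min, x_max, y_max)` in pixels with
`x_min < x_max` and `y_min < y_max`; images are float arrays in `[0, 1]`
of shape `(H, W, 3)`.

## Box geometry (`wheatkit.boxes`)

For boxes A, B with intersection I and union U:

- `iou = |I| / |U|`.
- `giou = iou − (|E| − |U|) / |E|` where E is the smallest enclosing
  axis-aligned box. GIoU is negative for distant disjoint boxes and equals
  IoU when E = U.
- `ciou_loss = 1 − iou + ρ²/c² + αν`, where ρ is the distance between box
  centers, c the diagonal of E,
  `ν = (4/π²) (arctan(w_A/h_A) − arctan(w_B/h_B))²`, and
  `α = ν / ((1 − iou) + ν)` (α = 0 when ν = 0). The aspect-ratio trade-off
  α is treated as a constant of the current configuration, as in gradient
  implementations that stop gradients through α.

`ciou_params` exposes the intermediate quantities `(iou, ρ², c², ν, α)` for
inspection. Degenerate (zero-area) inputs raise `DegenerateGeometryError`
rather than returning NaN.

**Design decision.** IoU between integer-coordinate boxes is computed as a
ratio of exact integer areas, so it is bit-exact against unit-cell
enumeration; this is what the test oracles rely on.

## Fusion (`wheatkit.fusion`)

| parameter | default | rationale |
|---|---|---|
| `iou_threshold` (NMS) | 0.5 | the conventional suppression cut |
| `iou_threshold` (soft-NMS linear) | 0.5 | decay applies only above it |
| `iou_threshold` (WBF) | 0.55 | slightly stricter clustering than NMS |
| `soft_mode` | `gaussian` | smooth decay, no hard cliff |
| `sigma` | 0.5 | Gaussian decay scale |
| `score_floor` | 1e-3 | boxes decayed below it are dropped |

- **NMS** is greedy descending-score suppression; ties break on
  `(y_min, x_min, x_max)` for determinism.
- **Soft-NMS** iteratively selects the top-scored box and rescales the
  rest: Gaussian mode multiplies every remaining score by
  `exp(−IoU²/σ)`; linear mode multiplies by `(1 − IoU)` only when
  `IoU > iou_threshold`. Gaussian decay is applied unconditionally — that is
  the defining difference between the two modes here.
- **WBF** greedily assigns each box (descending score) to the first
  cluster whose *running fused box* overlaps it above the threshold. The
  fused coordinates are the score-weighted mean of cluster members; the
  fused score is the cluster's mean score rescaled by
  `min(cluster_size, n_models) / n_models`, which penalizes boxes proposed
  by only a subset of an ensemble.
- `ensemble` applies NMS/soft-NMS to the concatenation of all models'
  boxes per image, but keeps models separate for WBF (WBF is the only
  method whose semantics distinguish models).

## Composite detection loss (`wheatkit.losses`)

A grid of K×K cells with M candidate boxes each. The total loss is the sum
of three parts:

1. **Coordinates** (responsible boxes only, mask `obj_mask`):
   `λ_coord · Σ (2 − ŵ·ĥ) [(x−x̂)² + (y−ŷ)² + (w−ŵ)² + (h−ĥ)²]` with
   `λ_coord = 5.0`. The `(2 − w·h)` factor up-weights small boxes (w, h are
   normalized to the image, so the factor lies in (1, 2]). A `coord_mode =
   "ciou"` alternative replaces the squared error with
   `λ_coord · mean CIoU-loss` over responsible boxes.
2. **Objectness**: binary cross-entropy over all K·K·M predictors, with
   background terms scaled by `λ_noobj = 0.5` to counter the foreground/
   background imbalance.
3. **Classification** (responsible cells): per-class binary cross-entropy,
   which remains valid for multi-label cells, rather than softmax CE.

Probabilities are clamped to `[eps, 1 − eps]` with `eps = 1e-7` before
logarithms, so a perfect batch has a small positive floor of order
`eps · n_terms` rather than exactly zero.

**Label smoothing**: `y′ = ε(1 − y) + (1 − ε)y` with ε ∈ [0, 0.5). The
smoothed cross-entropy equals the expectation of the hard cross-entropy
under independent label flips with probability ε — verified by Monte Carlo
in the tests.

## Bicubic interpolation (`wheatkit.bicubic`)

The Keys kernel

```
W(x) = (a+2)|x|³ − (a+3)|x|² + 1          for |x| ≤ 1
       a|x|³ − 5a|x|² + 8a|x| − 4a        for 1 < |x| < 2
       0                                   otherwise
```

with `a = −0.5` (the value making the scheme exact for quadratics).
Resampling is separable: each output coordinate maps to input space through
the align-centers convention `src = (dst + 0.5)/factor − 0.5`, and the four
nearest samples in each axis are weighted by `W(i − 1 − frac)`. Edges use
replicate padding by default, reflect optionally.

`hermite_patch` evaluates the same interpolant via the cubic-Hermite basis
with derivatives from centered finite differences; on interior patches it
coincides with the kernel form (Catmull-Rom) to ~1e-15, which the tests use
as a cross-check between two algebraically distinct implementations.

**Known discrepancy with Pillow**: Pillow renormalizes truncated kernel
windows at image borders, whereas this implementation pads. Interiors agree
to <1e-6; borders differ by design. The authoritative oracle in the tests is
a non-separable direct convolution sum (agreement 1e-9 on full grids).

## Augmentation (`wheatkit.augment`)

| parameter | default | rationale |
|---|---|---|
| `crop_count` | 5 | corners + center sub-windows |
| `crop_fraction` | 0.6 | sub-window side as a fraction of the source |
| `hsv_shift` | (0.02, 0.15, 0.15) | max hue/saturation/value jitter |
| `cutout_holes`, `cutout_size` | (1, 4), (0.08, 0.2) | holes per image, hole side fraction |
| `cutout_fill` | 114/255 | the conventional gray fill |
| `cutmix_ratio` | 0.5 | pasted-patch area fraction |
| `mosaic_tiles` | 4 | 2×2 mosaic |
| `min_box_visibility` | 0.3 | drop boxes with less area surviving a crop |

`simple_amplify` yields **15 outputs per source**: 5 anchored sub-windows
(four corners + center, each grown just enough to absorb boxes that straddle
its border), and for each window the crop itself plus its horizontal and
vertical flips; every output also receives an HSV jitter. Box coordinates
are remapped through every transform, and each output carries a `lineage`
list describing the operations applied.

`cutmix_with_background` requires a box-free donor image so no annotations
are silently destroyed; boxes overlapping the pasted patch are clipped to a
rectangular remnant or dropped below `min_box_visibility`. `mosaic` places
four samples on a double-size canvas with the shared corner jittered within
the central 50%.

## Semi-supervised workflow (`wheatkit.semisup`)

**Schedules.** `lr_at` ramps linearly from
`warmup_start_factor · base_lr` to `base_lr` over `warmup_iters`, then
applies either multistep decay (multiply by `gamma` at each post-warmup
milestone) or cosine decay to `eta_min` over `t_max` post-warmup iterations
(clamped at the floor beyond `t_max`).

**Pseudo-labeling.** `filter_pseudo_labels` keeps boxes with
`score ≥ threshold` (default **0.15**), strips scores, and relabels the set
`source="pseudo_label"`; images emptied by the filter are retained as
background. `sweep_threshold` scores every grid point (default
0.05:0.05:0.95) against a validation split, breaking ties toward the
*lower* threshold (more recall at equal metric); `refine=True` re-sweeps 21
points within ±1 coarse step of the winner.

Three strategies in `run_pseudo_label`:

- **A** — one prediction round; accepted pseudo labels join the trusted
  training pool.
- **B** — iterated: every round re-predicts *all* unlabeled images and the
  latest accepted labels replace earlier ones per image; the merged pool
  grows round over round. An audit record per round logs image and box
  counts and the threshold used.
- **C** — pseudo labels are merged for training but the trusted pool is
  never written; a rerun starts from the original labeled set.

## Evaluation (`wheatkit.evaluation`)

- **GWHD style** (default): per image, predictions are matched to ground
  truth greedily by descending score, each prediction taking the
  highest-IoU unmatched truth above the threshold; the image score is
  `TP/(TP+FP+FN)`, with an empty-prediction/empty-truth image scoring 1.
  Image scores are averaged first within a threshold, then across
  thresholds 0.50:0.05:0.75 (step 0.05). The inner/outer averaging order
  matters and is fixed to images-inner.
- **COCO AP style**: global descending-score ranking across images,
  monotone precision envelope, 101-point recall interpolation, averaged
  over the same thresholds.

## Synthetic scenes (`wheatkit.synthetic`)

| parameter | default | rationale |
|---|---|---|
| `count_mean`, `count_sd` | 40, 15 | truncated-normal head count |
| `count_max` | 116 | hard cap on heads per image |
| `empty_image_prob` | 49/3000 | atom at zero heads |
| `spike_length`, `spike_width` | (0.055, 0.11), (0.02, 0.042) | fractions of image side |
| `occlusion_overlap` | 0.35 | max allowed center proximity when placing |
| `blur_sigma`, `illum_gain`, `illum_offset` | (0, 1.5), (0.75, 1.25), (−0.06, 0.06) | per-scene nuisance ranges |

Counts are rejection-sampled from the truncated normal with an explicit
zero atom. Spikes are oriented ellipses with a straw color, cosine kernel
texture, and awn pixels, over a low-frequency green-brown noise background;
ground-truth boxes are the tight axis-aligned bounds of each rotated
ellipse. `simulate_predictions` degrades truth with Gaussian localization
jitter (relative to box size), Bernoulli misses, and Poisson decoy boxes;
true-box scores are Beta(8, 2), decoys Beta(2, 8), so score thresholds in
between separate them with high probability. Zero noise reproduces the
truth exactly, giving the pipeline a closed-loop check (GWHD score 1.0).

**What the generator does not emulate**: real canopy geometry, perspective,
leaf occlusion, cross-site phenotype variation, or motion blur. It is a
test harness for the surrounding machinery, not a stand-in for field data —
no claim is made that scores on synthetic scenes predict scores on real
imagery.

## Numerical and sizing choices

- Heavy distributional tests (count distribution at n = 2,000; miss-rate
  calibration over ≥10,000 boxes) run on the sampler and layout stages with
  rendering disabled, keeping the suite fast while testing the statistics
  that matter; full rendering is exercised separately on smaller batches.
- Statistical assertions use 3 CLT standard errors (Monte Carlo
  equivalences) or 99% binomial confidence intervals (rate calibration), so
  expected false-failure rates are below ~1% per assertion at fixed seeds.
- All random state flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give bit-identical images and annotations.
- Floating-point comparisons in the library avoid exact equality except
  where exactness is guaranteed (integer-area IoU ratios).

## Limitations

- No training code: losses and schedules are evaluated as pure functions;
  gradient behavior (e.g. of the CIoU α convention) is not tested.
- The GWHD matcher is greedy, not optimal assignment; on adversarial
  overlap patterns greedy and Hungarian matching can differ. Tests cover
  the disjoint cases where they provably coincide.
- WBF uses running-mean cluster matching; results can depend on score
  order in ways exhaustive pairwise clustering would not.
- The synthetic renderer is procedural and low-fidelity by design (see
  above).
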