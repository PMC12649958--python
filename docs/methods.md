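# Methods

`fundus_xai` re-implements, as a reusable library, an interpretability
evaluation protocol for diabetic-retinopathy (DR) grading networks: generate
saliency maps with several attribution families, test their *faithfulness*
with a pixel-masking perturbation protocol, score their *quality* with
entropy and lesion-overlap metrics, and probe their *clinical plausibility*
with a controlled lesion-insertion trend experiment.  Because the clinical
dataset and trained networks such a study rests on cannot be redistributed,
everything here runs against synthetic fundus scenes and fixture classifiers
with known decision structure; the synthetic stack is first-class, tested
code, not a throwaway.

## The classifier contract

All methods see a classifier only through `ClassifierHandle`:

- `scores(x)` — pre-softmax class scores (logits) for an `(H, W, C)` image
  in `[0, 1]`; `predict_proba` is their softmax.
- `predict_confidence(x, c)` — the softmax probability of class `c`.  This
  is the quantity perturbation curves track, chosen because it is bounded
  in `[0, 1]` like the published curves.
- `input_gradient(x, c)` — gradient of the class-`c` *score* with respect to
  every input intensity.  Attribution methods target the score, not the
  probability, so a linear model's gradient is exactly its weight vector
  and the completeness axioms below have clean closed forms.
- `feature_maps` / `feature_map_gradients` — the last convolutional stage's
  activations (default; any named layer can be requested) and the score
  gradient with respect to them, for the CAM family.
- `without_gradients()` — a view with gradient access disabled; ScoreCAM
  runs entirely through such a view, making its gradient-freeness a
  checked contract rather than a convention.

Concrete networks are a small numpy layer stack (convolution, ReLU, global
average pooling, a fixed affine feature-standardization layer, linear) with
hand-written forward/backward passes.  This keeps every fixture exactly
reproducible bit-for-bit and gives DeepLIFT a layer graph to propagate
multipliers through.  Inference is deterministic; there are no stochastic
layers.

## Attribution methods

Seven methods, each returning a signed `(H, W, C)` attribution `raw` and a
nonnegative 2-D saliency `map2d = Σ_c |raw|` (the absolute-value channel
sum keeps negative evidence visible; nothing in the protocol dictates the
collapse rule, so it is a package choice, applied uniformly).

| method | family | defaults |
|---|---|---|
| `gradient` | input gradient | — |
| `smoothgrad` | noise-averaged gradient | 25 samples, σ = 0.15 of the intensity span, noise unclipped |
| `integrated_gradients` | path integral from baseline | 32 midpoint-rule steps, black baseline |
| `shap` | expected-gradients Shapley estimator | 64 samples, black baseline |
| `deeplift` | Rescale-rule multiplier propagation | black baseline, ε = 1e-7 Δ-guard |
| `gradcam++` | gradient-weighted activation maps | last conv stage, 1e-8-stabilized denominator, bilinear upsampling |
| `scorecam` | mask-and-score activation maps | last conv stage, softmax weights over score increases vs the black image |

Notes on the choices that were genuinely open:

- **Baseline.** The reference input for IG/SHAP/DeepLIFT is the all-black
  image.  For fundus photographs black is the natural "absence" reference
  (the region outside the field of view is black), and it makes the three
  methods mutually comparable.
- **IG quadrature** is the midpoint Riemann rule: with `m` steps the
  completeness error is `O(1/m²)` for smooth scores and exactly zero for
  (piecewise-)linear ones.
- **SHAP estimator.** Expected gradients (a sampled Shapley value along
  interpolation paths) rather than Kernel SHAP over superpixels: superpixel
  segmentation blurs exactly the small, faint lesions that matter in this
  domain.  With a single black baseline the estimator is an unbiased
  Monte-Carlo version of IG, which the tests exploit as an oracle.
- **DeepLIFT** implements the Rescale rule only (RevealCancel is out of
  scope).  Linear layers propagate multipliers like gradients — bias terms
  cancel in activation differences — and ReLUs use Δout/Δin where
  `|Δin| > ε`, else the local gradient.  On the supported layer set the
  summation-to-delta identity `Σ raw = f(x) − f(baseline)` is exact to
  rounding, and the test suite asserts it at 1e-5.
- **Grad-CAM++** uses the standard closed-form weights built from the
  first/second/third powers of the activation gradients,
  `α = g² / (2g² + Σ A·g³ + 1e-8)`, weight `Σ α·relu(g)`; the map is the
  ReLU of the weighted activation sum, bilinearly upsampled.
- **ScoreCAM** min-max normalizes each activation map, upsamples it, masks
  the image with it, and weights maps by the softmax (over maps) of the
  target-score increase relative to the black image.  Degenerate cases are
  defined, not accidental: a constant activation map contributes an all-zero
  mask (its weight comes from the score of the black baseline and adds no
  spatial structure), and if *no* mask changes the score (constant-output
  model, all-zero stack) the method returns the all-zero map.
- Stochastic methods (SmoothGrad, SHAP) draw from `numpy`'s PCG64 generator
  seeded from `AttributionConfig.rng_seed` and are bit-reproducible.

## Saliency quality metrics

**Entropy.** A saliency map is min-max normalized, sum-normalized into a
per-pixel probability distribution, and scored with Shannon entropy in bits,
`H = −Σ p_i log₂ p_i`.  The two-stage normalization is deliberate: min-max
values alone do not form a distribution.  Base 2 on a 224×224 grid puts the
uniform map at `log₂ 50176 = 15.615` bits, strictly above the largest
entropy reported for real models in the source protocol (15.03) — the
consistency check behind the convention, recomputed by the acceptance
script.  Degenerate inputs are policy, not errors: a constant map normalizes
to a flat 0.5 map (with a warning) and a zero-mass map becomes the uniform
distribution.

**Perturbation curves and AOPC.** Pixels are ranked by saliency, highest
first, ties broken by row-major order so curves are deterministic.  At each
ratio `r ∈ {0, 0.02, …, 1}` the top `⌈r·n⌉` pixels are cumulatively replaced
by black (the mask value is configurable; black matches the attribution
baseline) and the target-class confidence is recorded — a 51-point curve.
The pixel count uses exact integer arithmetic (`⌈k·n/K⌉`), since computing
`⌈k·0.02·n⌉` in floating point is off by one pixel for some `k`.
`AOPC = (1/K) Σ_k (f(x) − f(x⁽ᵏ⁾))` over the `K = 50` nonzero steps.

**Recall and Dice.** The normalized map is thresholded at its 0.9
linear-interpolation quantile, retaining strictly-greater pixels (so a
constant map retains nothing), and compared with the ground-truth lesion
mask: `Recall = TP/(TP+FN)`, `Dice = 2|A∩B|/(|A|+|B|)`.  The ground truth is
the union of all lesion-class masks.  Lesion-free (grade-0) images have an
empty truth mask; both metrics are *undefined* there and reported as
missing, never as zero.

**Batch evaluation** produces one record per (image, method) and per-grade
mean tables with columns `Model, Label, Entropy, Recall, Dice, AOPC_Score`.
The CAM pair is excluded from the averaged quality tables by default —
their perturbation curves are too unstable to average, mirroring the source
protocol's exclusion — but the exclusion set is configurable and their
per-image records are always kept.

## Lesion insertion and trend analysis

Polygon annotations (`{lesion_class, vertices}`, 0-based `(row, col)`,
pixel centers at half-integers) are rasterized with an even-odd
crossing-number test on pixel centers — hand-rolled because the convention
is part of the contract, and cross-checked against an independent
geometric oracle in the tests.  `extract_patch` crops the padded bounding
box and feathers the polygon mask with a Gaussian (σ = 1, i.e. a 2-px
feather radius), forcing the outer ring to zero; compositing is plain alpha
blending, so pixels outside the lesion supports equal the base image
exactly.

`compose_sequence` places the requested number of patches uniformly at
random inside the circular field of view, rejection-sampling for
non-overlap and an optional optic-disc exclusion zone.  A wedged greedy
layout is discarded and resampled whole (up to 20 layouts of 500 tries),
so an unlucky early placement cannot make a feasible count fail; a count
that cannot be packed raises a composition error.  Everything is
deterministic given the seed.

The trend experiment composes the canonical insertion sequences — 14, 12,
10, 8, 6 microaneurysms and 13, 11, 9, 7, 5 hemorrhagic points — onto a
lesion-free fundus and computes a ScoreCAM map per image.  The source
protocol reads the resulting panels qualitatively; this package adds a
clearly-labeled quantitative surrogate, the **trend overlap score**: the
fraction of sum-normalized saliency mass inside the union lesion mask
dilated by 5 px.  Its natural reference is the *uniform baseline* — the
dilated-mask area fraction, which is what a structureless map would score.
On the planted spot-detector model the overlap beats the uniform baseline
at every count (typical margins 0.08–0.3), which is the testable core of
the trend claim.

## Synthetic scenes and fixture models

`generate_fundus` renders a stylized scene: warm radial background inside a
circular field of view (radius 0.48 × size), a bright optic disc, a few
dark vessel-like random-curvature walks, and hard-edged dark lesions —
microaneurysms as single discs (radius 2–5 px at 224), hemorrhages as
three-lobed blotches (4–10 px) — with pixel-exact masks, 16-gon bounding
annotations, and a documented count-based grade surrogate (no lesions → 0;
microaneurysms only → 1; 1–3 / 4–9 / ≥10 hemorrhages → 2 / 3 / 4, loosely
following the clinical convention that mild NPDR is defined by
microaneurysms alone).  The RNG stream is consumed in fixed order, so the
zero-lesion render of the same seed is pixel-identical outside the lesion
masks.  These scenes are geometric stand-ins: passing tests demonstrate
that the *pipeline* behaves correctly on images with known lesion geometry,
not that any conclusion transfers to clinical photographs — real fundus
images have texture, illumination gradients, camera artifacts and lesion
appearance none of which are modeled.

Four planted classifiers serve as oracles:

- `region_fraction` — class-1 probability is the mean intensity inside a
  planted region; perturbation curves have a closed form (linear decay to
  the floor), which the tests compare pointwise at 1e-6.
- `intensity_linear` — softmax over per-pixel linear functionals; gradients
  equal the stored weights exactly.
- `tiny_cnn` — conv(stride 2) → ReLU → conv(stride 2) → ReLU → global
  average pool → feature standardization → linear head.  Hosts the
  finite-difference, completeness, and CAM tests, and is the trainable
  fixture.
- `spot_detector` — a gradient-free hand-built detector (darkness =
  ReLU(blurred intensity − intensity) inside the field of view, one pooled
  feature map, class-1 score proportional to mean darkness).  It is the
  planted "attention follows lesions" model for the trend experiment.

**Training.** `train_tiny_cnn` runs per-sample cross-entropy Adam
(lr 3e-3) with seeded shuffling for 5 epochs over 200 scenes (100
lesion-free, 100 moderate), entirely in numpy and bit-deterministic.  Two
details matter and were arrived at by diagnosing failures, not by tuning
toward a threshold: (1) the pooled features carry a large common-mode
component that buries the small discriminative direction, so the
feature-standardization layer is calibrated once from the initial feature
distribution (std floored at 5% of its maximum so dead features are not
amplified into noise) and then frozen — at inference it is a fixed affine
map, inside DeepLIFT's supported set; (2) the returned weights are the
Polyak average of the final epoch's iterates, removing single-step gradient
noise from the endpoint.  Training scenes are 48×48 with lesion radii kept
at a visible floor (microaneurysms 2–3 px, hemorrhages 3–4 px) rather than
scaled down proportionally from 224, where they would shrink to ~1 px and
vanish under the network's stride-4 downsampling.  Training accuracy on
this separable-by-construction task is around 0.9 or above (measured
0.89–1.0 across a spread of seeds; ≥ 0.9 at the fixed seeds the test suite
pins).

## Numerical and degenerate-input policy (summary)

- Quantile convention: linear interpolation between order statistics.
- Ranking ties: stable row-major; placement and training RNG: PCG64.
- Masked-pixel counts: exact integer ceiling.
- Constant saliency maps: uniform normalization with a warning; empty
  highlight under strict-inequality thresholding.
- Empty truth masks: overlap metrics undefined (grade-0 convention).
- Infeasible lesion layouts: whole-layout resampling, then a typed error.
- Batch evaluation records per-row failures and continues; a report row is
  emitted for every input.

## Problem sizes

Unit tests run fixture networks at 8×8 (where brute-force finite
differences over every pixel are cheap) and scenes at 32–96 px; the
acceptance script and the end-to-end tests run the full protocol at the
native 224×224 on 25 scenes × 5 methods, the 200-scene training task at
48×48, and both insertion sequences at 224.  These sizes were chosen so the
whole suite re-derives every result from scratch in a few minutes on one
CPU core.

## Known limitations

- No adapter for serialized deep-learning checkpoints ships with the
  package; wrapping an externally trained network means implementing the
  handle contract (the CAM default layer, gradient access and
  determinism requirements are all that is needed).
- DeepLIFT supports the package's own layer vocabulary (linear,
  convolution, ReLU, pooling, flatten, fixed affine normalization); other
  nonlinearities raise a capability error naming the layer.
- The synthetic grade rule is a counting surrogate, not a clinical grader;
  Recall/Dice magnitudes on synthetic scenes are not comparable to values
  measured on clinical data.
- ScoreCAM's per-map forward passes make it linear in the number of
  feature maps; the fixtures keep that number small by design.
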