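# Methods

## Problem setting

Medical image segmentation models need many annotated scans, but a new
(target) tissue type often comes with only a handful.  Domain adaptation by
optimization-based meta-learning addresses this: learn an *initialization*
of the segmentation network from several well-annotated source tissues, so
that a few gradient steps on the few target examples suffice.  The package
implements the interpolation meta-update at the core of this approach,
with MAML and Reptile as baselines, a compact U-Net, a class-weighted Dice
metric, a staged layer-freezing transfer schedule, and a synthetic task
generator that reproduces the statistical structure the method exploits.

## The meta-update

Let θ be the flat parameter vector of the network and L_τ the loss on a
sampled batch τ.  One meta-iteration of the interpolation method:

1. sample a support batch τ_s from the whole example pool;
2. take k inner SGD steps, θ′_i = θ′_{i−1} − α ∇L_{τ_s}(θ′_{i−1});
3. sample an independent query batch τ_q from the *same* pool and take one
   more step at the same rate: θ′ = θ′_k − α ∇L_{τ_q}(θ′_k);
4. interpolate: θ ← θ + β (θ′ − θ).

Reptile is the same interpolation but with every inner step on one batch
(no query step); MAML draws support and query batches from disjoint example
partitions and follows the gradient of the query loss through the inner
adaptation (implemented both exactly, using inner-trajectory Hessians on
objectives that provide them, and in the common first-order approximation).
A "task" is one class-equipartitioned batch, so each episode mixes all
source tissue classes; support and query batches being drawn from the whole
pool — rather than from a fixed support/query split — is what lets the
update learn from the full diversity of each tissue's appearance.

Defaults follow the reported settings: α = 1e-3, β = 0.4, k = 3 (so each
meta-iteration costs four gradient evaluations), batch size 6 with
equipartition over three source classes, and four inner steps for Reptile
(its reported sweet spot, giving the same per-iteration gradient budget).
The query step reuses α and MAML's inner step count defaults to k = 3
(neither is separately reported).  MAML's outer update is a plain gradient
step rather than an interpolation, so its rate lives on the learning-rate
scale: the default is α (an interpolation-scale value like 0.4 multiplies a
raw pixel-summed gradient and demonstrably diverges); any other value can
be passed explicitly.

## Why the update works: executable analysis

Writing two support steps and one query step from φ0 gives

    φ1 = φ0 − α L_s′(φ0),   φ2 = φ1 − α L_q′(φ1),

so the update's *effective gradient* is (φ0 − φ2)/α = L_s′(φ0) + L_q′(φ1).
Expanding L_q′ around φ0:

    g = L_s′(φ0) + L_q′(φ0) − α L_q″(φ0) L_s′(φ0) + O(α²).

The first two terms minimize the expected loss over batches; the third
rewards gradient alignment between independently sampled batches — the
fast-adaptation signal.  `gradient_analysis` makes this executable: the
truncation is exact for quadratics (asserted to 1e-10), the gap scales as
O(α²) for smooth non-quadratic losses (quartering α shrinks it ≈16×), and
a Monte-Carlo estimator exposes the three expectation terms separately.
One printed-form inconsistency had to be resolved: the source derivation
divides the effective gradient by the outer step size in one line and
carries α/β factors in the next, while its own trajectory equations use α
for every step.  We define the effective gradient as (φ0 − φ2)/α, under
which the identity g = L_s′(φ0) + L_q′(φ1) holds exactly and β remains the
separate outer interpolation factor.  The cross term follows the
L_q″·L_s′ ordering of the derivation's expansion line (the expectation
line swaps the subscripts; the two differ only by batch-role relabelling).

## The U-Net

Encoder of four down-sampling blocks — two padded 3×3 convolutions, each
followed by batch normalization and ReLU, then 2×2 max-pooling — a two-
convolution bottleneck, and a mirrored decoder in which pooling is replaced
by 2×2 stride-2 transposed convolutions, with skip concatenations at
matching depth.  The network and its backpropagation are implemented
directly in numpy (im2col GEMM convolutions, channels-last activations);
gradients are verified against finite differences.

The full-scale configuration has 4,320,609 trainable parameters.  The
figure defining the channel widths gives no numbers in its extracted form,
so the widths here are a reconstruction: a systematic search over integer
width ladders under the stated topology (including whether the bottleneck
doubles and whether up-convolutions halve widths) found encoder widths
(28, 59, 114, 226) with a same-width bottleneck, width-preserving 2×2
up-convolutions and a single-logit sigmoid head to be the only
quasi-doubling ladder that reproduces the printed total exactly.  The
parameter count (convolution kernels, biases, BN scale/shift; running
statistics excluded) is what the package guarantees; the widths themselves
are a conjecture and are configurable.  Binary probability maps are exposed
in two-class form (1−p, p) so the K-class weighted Dice applies uniformly.
A `tiny` preset (two blocks, base width 8, 32×32 inputs) is used by tests
and the synthetic benchmark; the algorithms are size-agnostic.

### Loss reduction

Training minimizes per-pixel cross-entropy summed over pixels and averaged
over the batch.  The reduction is a numerical design choice: with a
per-pixel *mean*, the stated learning rates (1e-3 inner/early, 1e-4 final)
move plain SGD so little on a desk-scale model that training never leaves
the all-background solution; with the pixel-summed form the same rates take
steps of a useful size.  The monitoring metric `pixel_cross_entropy`
remains a per-pixel mean.  Cross-entropy is unweighted by default; the
0.9/0.1 class ratio enters the Dice metric as the weights ω_k.  (A flag on
the metric controls the zero-denominator convention for a class absent from
both maps: it contributes 0 by default, or its full weight ω_k.)

## Layer-freezing transfer

Transfer to the target task runs in depth+1 stages.  Stage 1 freezes
encoder blocks {1..depth} at learning rate 1e-3; each subsequent stage
unfreezes the deepest still-frozen block; the final stage trains everything
at 1e-4.  For depths ≥ 2 the penultimate stage applies inverse-time decay,
lr/(1 + 0.0077·epoch) — the reported decay value; the law itself is not
stated and is isolated in `effective_lr` so alternatives are one-line
swaps.  Freezing a block pins its convolution weights, its BN affine
parameters *and* its BN running statistics (otherwise the "frozen" feature
extractor would drift).  The decoder and bottleneck are never frozen.
Metrics reported from evaluation binarize predictions by per-pixel argmax.

## Synthetic tasks

Each tissue class pairs a signal-intensity regime (low 0.20, intermediate
0.55, high 0.85; spread 0.05, on a background of mean 0.40 with smooth
texture of amplitude 0.08 and pixel noise σ 0.05) with a shape family
(ellipse, lobed blob, ring).  Every drawn example randomizes location
(±22% of the extent), size (4–20% of the area), orientation and intensity
level — the same location/size/shape/intensity diversity that motivates
learning from the whole task distribution.  The default source family is
low/ellipse, intermediate/lobed-blob, high/ring; the held-out target is
intermediate/ellipse, a regime-shape combination absent from the sources.
Augmentation applies random rotation (0–180°), translation (±10%), shear
(±0.2) and anisotropic scaling (0.8–1.25); the continuous "0–180° angle
flipping" of the original description is read as rotation, with discrete
axis flips available behind a flag.  Shear and scale magnitudes are
configuration knobs since no values are reported.

What the generator does *not* emulate: MRI physics and artefacts, 3-D
anatomy and inter-slice correlation, inter-patient anatomical variability,
and multi-organ context.  Passing benchmarks here show the optimization
machinery behaves as designed on data with the assumed statistical
structure; they do not certify clinical performance.  A NIfTI adapter for
Medical Segmentation Decathlon tasks (axial slices, resized to 256×256,
labels binarized, per-slice min-max normalization, empty-label slices
dropped and counted) connects the same pipelines to real volumes; slices
are pooled across volumes with provenance recorded in the example IDs.

## The scaled-down benchmark

The synthetic transfer benchmark runs at 32×32 with the tiny U-Net: three
source classes × 40 examples, 200 meta-iterations, a 30-example target
training set, a 40-example target test set, five runs from matched seed
streams (data, initialization, meta-training and fine-tuning randomness are
independent named streams derived from (seed, run)).  Every arm receives
the same 30 total target epochs (120 SGD steps) — 10 per stage for the
depth-2 freezing plan of the meta arms and the pre-training arm, plain
supervised training for the random-initialization baseline; supervised
pre-training in the multi-source arm gets 20 source epochs.

The adaptation budget is deliberately limited: the benchmark measures
initialization quality, and on this synthetic target a from-scratch model
saturates (DSC ≈ 0.8) given roughly three times this budget, at which point
every arm converges and the comparison degenerates to seed noise.  At 30
epochs the baseline still learns substantially (DSC ≈ 0.6–0.7) while the
meta-initialized arm retains a clear lead — the few-gradient-steps regime
the method targets.  All other sizes are the package's desk-scale choice;
the full-scale protocol (256×256, 300 epochs, thousands of source slices)
is reachable with the same code and the reference model.

## Numerical choices and degenerate inputs

- Interpolation is computed as θ + β(θ′−θ) with the β = 0 and β = 1
  endpoints returned exactly, so the no-op and full-step identities hold
  bit-for-bit.
- Cross-entropy probabilities are clipped at 1e-7 before the log.
- Weighted Dice: a class with zero denominator contributes 0 (flag above);
  precision/recall return NaN on an empty denominator and evaluation
  averages over the defined values.
- Confidence intervals use the t distribution with n−1 degrees of freedom
  and the sample standard deviation (ddof = 1); at least two runs required.
- The mask generator rejection-resamples until the rendered area lands in
  the class's size range (bounded retries); augmentation re-draws any
  transform that would empty the mask.
- BN uses batch statistics during training and adaptation; running
  statistics advance only during supervised training, so meta-objectives
  are pure functions of (θ, batch) and meta-runs are exactly reproducible.
  Because of that purity, a meta-learned initialization carries stale
  running statistics; `calibrate_bn_stats` re-estimates them on the source
  pool after meta-training (pipelines do this automatically).  Skipping the
  calibration leaves eval-mode inference and frozen-BN fine-tuning
  normalizing with initialization-time moments, which demonstrably destroys
  the transferred features.

## Known limitations

- Second-order MAML requires an objective exposing Hessian products; the
  numpy U-Net objective provides gradients only, so MAML on images runs
  first-order (the standard practical choice).  Exact second-order MAML is
  verified on analytic objectives against finite differences.
- The reconstructed full-scale widths reproduce the parameter total, not
  necessarily the original network.
- Plain SGD without momentum mirrors the described optimizer; convergence
  on hard real tasks would likely benefit from momentum or Adam, which are
  deliberately out of scope.
- Single CPU, float32; no data-parallel or GPU path.
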