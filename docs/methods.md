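# Methods

`renalswin` couples explicit intensity statistics with attention-based
networks for kidney CT lesion analysis on 2-D slices.  This note records the
models, the defaults and why they are what they are, what the synthetic
phantoms do and do not emulate, and the numerical choices that matter.

## The three-parameter Gamma intensity model

Region pixel intensities are modeled by a location-shifted Gamma law with
shape α > 0, scale β > 0 and location γ (support y > γ):

    f(y) = (y − γ)^(α−1) exp(−(y − γ)/β) / (Γ(α) β^α),   y > γ

with mean μ = γ + αβ, variance σ² = αβ², and skewness 2/√α.  The positive
skew and hard lower threshold suit CT tissue intensities better than a
Gaussian: attenuation values have physical floors and heavy right tails.

An image is a K-component mixture of such laws, one per tissue region, with
weights w_i ∈ [0, 1], Σw_i = 1.  The mixture's expected intensity is
Σ w_i (γ_i + α_i β_i).

**Component count and initialization.** K and the starting parameters come
from agglomerative clustering of an intensity subsample (default 3,000
pixels, seeded).  Ward linkage is used: on 1-D intensity data its
between-cluster merge heights dwarf within-cluster ones, so the dendrogram
gap criterion is sharp.  With h_j the height of the merge that reduces j+1
clusters to j, the cut is placed at the deepest gap whose ratio
h_j / h_{j+1} exceeds 3.0 (K = j+2); if no gap is significant, K = 1.  The
threshold 3.0 separates the unimodal regime (observed max ratios ≈ 1.7–2.3)
from genuinely multimodal data (ratios ≥ 6) with a wide margin.  Average
and complete linkage were evaluated on the same synthetic mixtures and do
not provide a usable margin; this is why Ward is the default.

**Fitting with a fixed location.** Joint maximum likelihood in a Gamma
location parameter is unbounded (α < 1 components can place infinite
density at the sample minimum), so each component's γ is set at
initialization — the cluster minimum minus 1% of the cluster range, with
the lowest component anchored below the global sample minimum so every
observation lies in the mixture's support — and held fixed.  Given γ, shape
and scale come from inverting the moment identities with Ȳ = mean(y − γ)
and V = var(y − γ):

    β̂ = V / Ȳ,   α̂ = Ȳ² / V

which reproduces the sample mean exactly (γ + α̂β̂ = ȳ).

**EM refinement.** The EM-style loop alternates posterior responsibilities
(computed in log space with log-sum-exp) with a responsibility-weighted
version of the same moment inversion; weights become mean responsibilities.
Because the M-step matches moments rather than maximizing the likelihood
exactly, monotonicity is not guaranteed by EM theory; the loop therefore
rejects any update that would lower the log-likelihood and stops there,
so the recorded trace is nondecreasing by construction.  In practice (100
seeded runs on well-separated mixtures) no update is ever rejected before
the tolerance (|Δ log L| < 1e-6, max 200 iterations) is reached.
Components whose weight falls below 1e-8 are pruned with a warning.
A hook for right-censored observations (multiplicities R_j in the
sufficient statistics) exists in the state object but is not implemented;
all fitting assumes fully observed samples.

**Segmentation and the atypicality map.** Mixture segmentation assigns each
pixel the argmax of its posterior responsibilities (ties to the lowest
component index).  The atypicality map used as an extra network input
channel is 1 − max_i f_i(y)/f_i(mode_i): each component's density is
normalized by its own peak, so a pixel well inside any tissue law scores
≈ 0 and pixels in the gaps between laws — small or low-contrast lesions —
score high.  Posterior responsibilities are deliberately *not* used here:
they renormalize across components and saturate at 1 even for intensities
no law explains, which makes them a boundary-ambiguity score rather than an
outlier score.  For α < 1 the density is unbounded at the support edge; the
peak is then taken at the exponential-case mode (α clamped to 1), and a
component whose peak density overflows float range is treated as a point
mass.  A known limitation: when a lesion law sits only ~1 pooled SD from
the parenchyma law, no pointwise intensity score can rank the lesion above
the parenchyma's own spread (a tight law near the mode is pointwise more
typical than the broad law's tails); the map separates cleanly from ~2
pooled SD upward.

## Synthetic phantoms

Every downstream stage is exercised on synthetic kidney phantoms: an
elliptical parenchyma (semi-axes 0.36/0.24 of the image side, randomized
center and rotation) on background, with one class-specific lesion — a
round hypodense cyst, a small hyperdense stone blob, or a multi-lobed tumor
whose core interleaves two Gamma laws (3–5 overlapping random ellipses) to
mimic heterogeneous tumor cores.  Each region's pixels are i.i.d. draws
from its law, so region moments are exact oracles.

Default laws (intensity units on a byte-like scale), ordered like CT
hypo/hyper-density — background < cyst < parenchyma < tumor core < stone:

| region      | α | β  | γ   | mean | SD   |
|-------------|---|----|-----|------|------|
| background  | 2 | 5  | 10  | 20   | 7.1  |
| cyst        | 3 | 6  | 40  | 58   | 10.4 |
| parenchyma  | 4 | 10 | 100 | 140  | 20.0 |
| tumor core  | 4 | 5  | 185 | 205  | 10.0 |
| tumor alt   | 3 | 5  | 200 | 215  | 8.7  |
| stone       | 4 | 6  | 200 | 224  | 12.0 |

In the "clear" difficulty tier every lesion law sits ≥ 4 pooled SDs from
the parenchyma law, so intensity alone is linearly separating — this is the
regime in which the scaled-down training runs are expected to succeed.  The
"mild" and "low" tiers relocate each lesion law (same shape/scale, shifted
γ) to a 2 and 1 pooled-SD mean gap, emulating progressively ambiguous
cases.  Lesion radii default to 7–11% of the image side (3.5–6% for
stones); splits are assigned 70/15/15 stratified by class.

What the phantoms do **not** emulate: anatomy (no cortex/medulla/pelvis
structure), partial-volume blur at region borders, spatially correlated CT
noise, beam hardening, or scanner-to-scanner calibration differences.
Passing the phantom suite therefore demonstrates that the statistics, the
losses, the optimization and the architecture are implemented correctly and
can learn intensity-plus-shape structure — not that the trained weights
transfer to clinical CT.

## Networks

All network components run on a small reverse-mode automatic-differentiation
core (`renalswin.nn.autodiff`) operating on NumPy float64 arrays: a taped
`Tensor` with broadcast-aware arithmetic, batched matmul, im2col
convolution, stable softmax/log-softmax, and shape ops.  Gradients
accumulate on every tensor in the graph, which is what lets Grad-CAM read
intermediate activations without hooks.  All forward passes are
deterministic in eval mode; dropout streams are seeded per layer.

**Encoder.** Patch embedding (patch 4) with a learned absolute position
grid, then four stages of windowed multi-head self-attention blocks with
the standard two-residual layout (pre-norm attention + residual, pre-norm
feed-forward + residual), alternating plain and shifted windows (shift =
half window, wrap masking at the rolled boundaries), relative position bias
per window, and 2×2 patch merging between stages.  This realizes features
at exactly 1/4, 1/8, 1/16 and 1/32 of input resolution.  The coarse
16-px-patch arithmetic (a 512² slice → 32² = 1024 patches) is exposed by
`count_patches`; the hierarchical encoder itself must use patch 4, since
1/4-resolution stage-1 features are otherwise impossible.  Optional
components: learnable memory tokens appended as extra attention keys/values
(every token can read a global context slot; rows still softmax to 1), and
a convolutional feed-forward (3×3 conv between the two projections) that
keeps spatial layout.  Window size is clamped per stage to the token grid
(a 2×2 deepest grid attends densely).  Attention maps of every block are
retained after each forward pass for overlays and for the skip fusion's
audit trail.

**Gamma channel gating.** At the deepest stage (default; configurable to
all stages or off), per-channel global average pooling feeds two small
shared MLPs whose softplus outputs are a Gamma shape k and scale θ per
channel — a probabilistic summary with mean μ = kθ and variance σ² = kθ².
The gate is sigmoid(u·μ̂ + v·σ̂² + b) with learned scalars u, v, b and μ̂,
σ̂² standardized across channels; each channel is rescaled by its gate.
Initialization u=1, v=−1, b=0 encodes the prior "emphasize strong-mean,
damp high-variance channels" while remaining fully learnable.

**Decoder.** From 1/32 back to 1/4: nearest 2× upsampling, channel
projection, then single-head cross-attention in which the decoder tokens
are queries and the encoder stage provides keys and values —
softmax(QKᵀ/√d)V plus the decoder residual — followed by a small MLP.  An
auxiliary linear head at each intermediate level (1/16, 1/8, 1/4 grids)
provides deep supervision.  A boundary branch (parallel dilated 3×3
convolutions, dilations 1/2/4, fused 1×1, sigmoid) predicts label edges at
the 1/4 grid.  The final head upsamples to full resolution and concatenates
the raw input channels before two 3×3 convolutions: the attention pyramid
bottoms out at 1/4 resolution, and pixel-accurate boundaries need the
original intensities back in view.

**Classifier.** Crops around the segmented region (ground-truth masks in
teacher-forcing mode) are encoded by the same four-stage pyramid; each
stage is pooled to one token, projected to a common width, and a learned
class token attends over the four scale tokens (attention-based multi-scale
fusion); an MLP head with dropout 0.1 emits class probabilities.  The
default head is the 4-class renal task (normal/cyst/stone/tumor); a binary
benign/malignant grouping (tumor vs rest) is available.  Crops are
two-channel: the image window plus the segmented region's binary shape.
The shape channel matters — after a bounding-box zoom a compact calculus
and a lobulated mass can have near-identical texture, and the segmentation
that produced the crop already knows the geometry.  The crop window is
never smaller than 25% of the image side, preserving some absolute-size
context.  Standard crop sizes: 224 px (full profile), 64 px (tiny).

## Training protocol

Two stages, both AdamW with gradient clipping at global norm 1.0 and
seeded, reproducible batch/dropout streams:

- **Stage 1 (segmentation).** Dice + boundary-weighted cross-entropy on
  the final head; the same combination at each deep-supervision head
  against nearest-downsampled targets (weights 0.4/0.3/0.3 shallow→deep);
  binary cross-entropy of the boundary branch against the mask edge map
  (weight 0.5).  The boundary weight map is 1 + 4.0 inside a 3-px band
  around label edges.  Published recipe: lr 1e-4 cosine-annealed, weight
  decay 0.01, batch 8, up to 200 epochs, early stopping on validation
  macro Dice with patience 20.
- **Stage 2 (classification).** Class-weighted cross-entropy (weights ∝
  inverse class frequency), balanced sampling (optionally lesion-aware:
  records whose lesion is under 0.5% of the image area get a 2× boost),
  lr with linear warm-up then cosine decay, weight decay 0.001, batch 16,
  up to 100 epochs, patience 15 on validation macro F1.

**Scaled-down protocol.** The CPU-sized verification runs use the tiny
profile (dims 16/32/64/128, depth 1 per stage, 2 heads, window 4, 2 memory
tokens) on 200 clear-tier 64-px phantoms with shorter schedules: stage 1
lr 3e-3 for 12 epochs, stage 2 lr 1e-3 for 30 epochs with 10% warm-up.
The larger learning rates are the standard adjustment for a ~0.4M-parameter
model trained for a few hundred steps; the published rates are tuned for
full-size models over tens of thousands of steps.  Under this protocol the
segmentation reaches validation macro Dice ≈ 0.97–0.98 and the classifier
≈ 0.9–1.0 validation accuracy across seeds.

Cross-validation: stratified 5-fold splitting operates within the
train+val pool; the 15% test split is held out once and never enters a
fold.

## Metrics

Overlap metrics come from pixel confusion counts (Dice = 2TP/(2TP+FP+FN),
IoU = TP/(TP+FP+FN)).  Conventions for lesion-free cases: both-empty masks
score Dice/IoU 1 (perfect agreement on absence); boundary metrics are
undefined on empty masks and return NaN sentinels that aggregation excludes
(the excluded count is reported).  HD95/ASD use the pooled-directed
convention: surface pixels are the mask minus its erosion, directed
distances are computed both ways via exact Euclidean distance transforms
(anisotropic spacing respected), and HD95/ASD are the 95th percentile/mean
of the pooled set.  Several HD95 conventions circulate; the pooled one is
pinned by a brute-force all-pairs oracle in the tests.  Classification
metrics use one-vs-rest ROC/PR AUC per class (macro averaged), verified
against the Mann–Whitney rank statistic.  Confidence intervals are
percentile bootstrap over records, seeded.  Phantom evaluations default to
1 mm/px spacing.

## Numerical choices

- All density math in log space; responsibilities via log-sum-exp; uniform
  fallback (with a warning) for samples outside every component's support.
- Ties in posterior argmax go to the lowest component index.
- Preprocessing stage order is fixed (resize → Wiener → CLAHE → range
  scale → optional histogram match → optional z-score): denoising precedes
  contrast amplification so CLAHE does not amplify noise.  Tone-mapping
  stages preserve pixel rank order; masks are only ever nearest-neighbour
  resized.  The CLAHE clip limit is expressed in the common contrast-factor
  convention (default 2.0, tile grid 8) and mapped internally to the
  fractional convention of the underlying implementation; the
  "adjacent weighting" variant is an experimental second pass at a coarser
  grid, averaged in, default off.
- Histogram matching is monotone quantile mapping against a reference CDF
  (default reference: mean empirical CDF of the clear-tier training
  phantoms); ties share a mid-rank quantile.
- Weight init: truncated normal (std 0.02) for projections, zeros for
  biases and the relative position bias table, He-scaled normal for
  convolutions.
- Augmentation: one geometric draw applies the identical transform to
  image (bilinear) and mask (nearest); out-of-canvas fills use the image
  minimum and label 0.  Mixup applies to classification pairs only —
  convex combinations of integer masks are ill-defined.  Noise is injected
  before blur.

## Limitations

- Phantom realism is deliberately limited (see above); reported Dice and
  accuracy are properties of the implementation under known-law conditions,
  not clinical performance estimates.
- The autodiff core is built for clarity and testability at small scale;
  it is single-threaded float64 NumPy and not suited to full-resolution
  (512²) training.
- The censored-observation path of the mixture fit is a stub.
- Gamma location parameters are never re-estimated during EM; mixtures
  whose true components differ mainly in location-at-fixed-shape may
  converge to a nearby but biased solution.
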