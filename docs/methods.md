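# Methods

`stablate` studies how the quality of spatial-transcriptomics training data
affects deep-learning prediction of patch-level gene expression from
histology images. Because the question is about *data* quality, the package
is built around a generative benchmark: every modality is sampled from one
known ground truth, so degradations can be applied surgically and their
effect on prediction and interpretability measured without confounds.

## Synthetic scene model

A scene is a rectangle of `width_px × height_px` pixels containing
`n_cell_types` spatially clustered cell types. Cells of type *t* are drawn
i.i.d. from an isotropic Gaussian "niche" centred at `niche_centers[t]` with
standard deviation `niche_sd`, truncated to the scene by rejection sampling.
Expression is governed by a type×gene rate matrix Λ: cell *i* of type *t*
emits `Poisson(Λ[t, g])`-distributed molecules of gene *g* (per unit capture).
A `marker_fraction` share of genes is split evenly across types as markers
(rate 8.0 in the marked type vs 0.8 elsewhere); the remainder are
housekeeping-like (rate ≈ 1, jittered ±20% per gene so genes are not
interchangeable).

The histology-like image renders each cell as an ellipse with type-dependent
colour and size (plus per-cell size/colour jitter) over a pale background.
This is the *minimal* model in which morphology is genuinely informative
about expression — the premise of the prediction task — and deliberately
omits stain variation, slide artifacts, and realistic colour statistics.

Two technology regimes are sampled from the same scene:

* **imaging-like** — per-cell counts `Poisson(η_img · Λ[t, g])` with high
  capture efficiency η_img (default 0.8) and exact coordinates;
* **sequencing-like** — counts pooled on a regular spot grid (pitch =
  patch size) at low capture η_seq (default 0.2, i.e. a 4:1 capture ratio),
  mixed laterally with the four neighbouring spots at weight
  `diffusion_mix` (default 0.2; each spot keeps 1−m and sends m/4 per
  neighbour, so interior mass is conserved and edge mass is lost off-tissue),
  Poisson-sampled, then zeroed entry-wise with probability `dropout_prob`
  (default 0.5).

A *replicate* is a second scene drawn with the same generative parameters
(rates, niches, cell numbers) and an independent seed — the synthetic
analogue of a serial tissue section. Known affine misalignments can be
applied to either modality to create the registration problem the
registration module solves by least-squares landmark fitting (exact for
noiseless affine correspondences).

Every sampler derives its random stream from one root seed plus a string
key, so experiments are exactly reproducible and adding a sampler never
perturbs another's draws.

### Standard benchmark conditions

The standard scene used by the tests and the acceptance script is
416×416 px, patch size 16 px (26×26 grid), 4 cell types on a ring of niches
(`niche_sd` = 110 px), 600 cells per type, and 24 genes (16 markers, 4 per
type). After excluding patches with zero total counts in either modality,
about 620–640 aligned patches remain. These are scaled-down analogues of a
real paired-section benchmark (thousands of ~250 px patches, hundreds of
shared genes); the patch size, gene count and model width were chosen so a
full sweep trains in minutes on one CPU.

## Rasterization

Patch (r, c) covers the half-open square `[c·P, (c+1)·P) × [r·P, (r+1)·P)`;
points on a shared boundary belong to the right/lower patch, so patches
partition the region and pseudobulk aggregation conserves counts exactly.
Partial edge tiles are excluded. Sequencing-like spots map one-to-one onto
the patch containing the spot centre (two spots in a patch is an error).
Counts are transformed as `ln(1 + c)`; patches whose total count across all
genes is zero are excluded. "Zero expression" is read as *total* zero rather
than any-gene zero — the stricter reading would delete nearly every patch of
a sparse modality. For paired comparisons, a patch must be non-zero in
*both* modalities to be retained, so arms share patch ids, splits and seeds.

## Degradation operators

All operators act on raw counts before the log transform, or on the image
before patch extraction:

* **Reference-matched sparsification** `match_sparsity(target, ref, t)`:
  zero `target[p, g]` wherever `ref[p, g] ≤ t`. With the sequencing-like
  matrix as reference this imprints its zero pattern (and more, as *t*
  rises) onto the imaging-like matrix. Idempotent; output ≤ target
  elementwise; per-gene sparsity non-decreasing in *t*. The standard sweep
  is t ∈ {0, 1, 5, 10, 15, 20}.
* **Additive Poisson noise**: add independent `Poisson(λ)` draws to every
  entry (λ ∈ {5, 15, 45}). One realization is drawn per experiment and fixed
  across splits — the degraded matrix *is* the dataset.
* **Gaussian blur**: separable convolution with a normalized 2D Gaussian
  kernel, reflect padding, kernel sizes {1, 5, 25, 125} and σ = size/6 (the
  kernel spans ±3σ; stated because only kernel sizes are conventionally
  reported). Blur is applied to the whole image before patch extraction so
  patch boundaries stay consistent, and to training and evaluation images
  alike.

## Imputation (rescue) methods

* **KNN-smoothing** of raw counts, stepwise: at step *s* the current matrix
  is median-depth-normalized, Freeman–Tukey-transformed (√x + √(x+1)),
  projected onto the top *d* principal components, and each patch's profile
  is replaced by the sum of the *raw* counts of its `k_s = min(2^s, k)`
  nearest neighbours (self included), iterating until `k_s = k`. Defaults
  k = 50, d = 20. Patches with total count < d sit out and are reinserted
  unchanged (they destabilize the PCA projection); this generalizes the
  usual practice of dropping individual ultra-low-count observations.
* **Graph diffusion** of log-expression: kNN graph on patches, adaptive
  Gaussian affinities `exp(−(d_ij/σ_i)²)` with σ_i the distance to the
  ⌈knn/3⌉-th neighbour, symmetrized with self-loops, row-normalized to a
  Markov operator M, returning `M^t·X`. The diffusion power is a fixed,
  configurable `t_steps = 3` rather than any automatic selection, which
  would be irreproducible across implementations. `t_steps = 0` is an
  identity escape hatch.
* Deep generative imputation against an external single-cell reference is an
  adapter seam only (`impute.ExternalImputer`): it requires reference data
  and model training outside this package's scope.

## Predictor

The predictor is featurizer → four-layer MLP head. Each head layer is
linear → batch-normalization → ReLU → dropout 0.2; a final linear layer
emits one value per gene. Training minimizes MSE on log1p expression with
Adam (lr 10⁻³, weight decay 10⁻⁵), batch size 64, random
horizontal/vertical flips and 90° rotations as augmentation, and a
75/10/15 train/val/test split drawn uniformly at patch level
(largest-remainder rounding). Final-epoch weights are used — no early
stopping; the validation split is monitored only. Patch-level random
splitting is kept deliberately, even though spatial autocorrelation can leak
information between splits, because that is the standard protocol being
studied. Per-channel normalization constants are computed from the training
images.

Because no deep-learning runtime is a dependency, the network is implemented
in a compact numpy engine (`stablate.nn`) with hand-written forward/backward
passes (im2col convolution with reflect padding, batchnorm, dropout, average
pooling, Adam). Reflect padding matters: with zero padding, heavily blurred
(near-constant) patches carry spatial signal only at the artificial frame,
which corrupts saliency maps. All layers are float32; training is exactly
reproducible for a fixed (dataset, config, seed) on one device.

Featurizer kinds:

* `small-cnn` (default): three conv–batchnorm–ReLU blocks (one 2× average
  pooling stage, so the final 8×8 feature maps resolve individual cells in a
  16 px patch), global average pooling, embedding width `embed_dim`
  (desk-scale default 32; generic default 128).
* `fixed-random-projection`: frozen seeded Gaussian projection of raw
  pixels; deterministic and fast, no saliency support.
* `pretrained-residual-cnn`: a configuration placeholder for an externally
  supplied pretrained 2048-d backbone; selecting it raises, since no
  pretrained weights ship here.

Desk-scale training uses `embed_dim 32`, head widths (64, 48, 32, 32), and
35–60 epochs: one model trains in ~10 s on one CPU at the standard scene
size, which is what makes 3-seed sweeps tractable.

## Evaluation

Per gene, across evaluation patches: Pearson correlation (population 1/n
normalization — the factor cancels) and normalized rMSE = RMSE divided by
the observed range `y_max − y_min` on the evaluation set. Genes with zero
variance in observed *or* predicted values are excluded from means, flagged
with a reason, and counted. The test split is scored against the (possibly
degraded or imputed) matrix the model was trained on — the degraded matrix
is the dataset — while replicate evaluation scores the *same* trained model
against the replicate section's high-quality imaging-like counts, with no
retraining. Run-to-run variability: mean over genes included in all runs
within each run, then mean ± standard error across runs (3 seeds per
condition in the standard experiments; 5 is the conventional full-scale
choice).

Directional stochastic trend checks (used where a sweep is expected to
degrade or inflate a mean) flag a violation only when an adjacent step moves
the wrong way by more than twice the pooled across-run SE, and additionally
require the explicitly stated end-to-end effect sizes (e.g. a ≥0.05 PCC
drop) literally.

## Saliency

Grad-CAM for gene *g*: gradient of the model's raw output unit for *g* with
respect to the final conv block's feature maps, globally averaged into one
weight per channel; the weighted feature-map sum is rectified and bilinearly
upsampled to patch resolution. Heatmaps are max-normalized to [0, 1] for
storage; the dispersion statistic instead sum-normalizes the map into a
probability distribution and reports Shannon entropy (nats): 0 for a
one-pixel peak, ln(H·W) for a uniform map. Maps that rectify to all-zero
(everywhere-negative gradients) are flagged undefined and skipped in
aggregates. Scaling the output layer for a gene scales the raw map but
leaves the max-normalized map unchanged.

## What passing tests do and do not show

The generator reproduces the *structural* quality gaps between an
imaging-like and a sequencing-like readout — capture efficiency, lateral
diffusion, dropout sparsity — and the benchmark reproduces the qualitative
findings: sparsification, Poisson noise and image blur all degrade test PCC
(and replicate PCC), the imaging-like arm beats the sequencing-like arm on
identical images, and blur diffuses Grad-CAM saliency.

It does **not** model dataset-specific technical structure: platform batch
effects, spatially correlated noise, segmentation errors, off-target probes,
stain variation. One observed consequence: KNN-smoothing of the
sequencing-like matrix raises test-split PCC sharply (as on real data) but
*also* raises replicate PCC, because in a fully generative world with
independent entry-wise noise, neighbour smoothing is genuine denoising
toward the shared ground-truth rates. On real paired sections the analogous
rescue fails to generalize precisely because smoothing entrenches
dataset-specific artifacts that a replicate does not share. The
corresponding acceptance check asserts the real-data direction and therefore
fails on the synthetic benchmark; it is kept failing, with both effect sizes
reported, rather than weakened.

Other numerical choices: half-open patch intervals (unambiguous partition);
affine fitting minimizes forward landmark error; blur on integer images
rounds back to the input dtype; all-zero count matrices are rejected by the
smoothers; batchnorm uses running statistics at inference.
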