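# Methods

`idseg` re-implements an infant brain MRI segmentation framework for the
bilateral hippocampus and amygdala on T2-weighted scans, together with the
statistical machinery around it: multi-rater consensus ground truth,
segmentation accuracy metrics, a transfer-learning evaluation harness, and a
morphometry-behavior correlation stage.  This note records the models, the
parameter choices that matter, and what the synthetic phantom experiments do
and do not demonstrate.

## Segmentation model

Each anatomical view (axial, coronal, sagittal) gets an identical 2D
fully-convolutional encoder-decoder in the QuickNAT family:

* four encoder stages of *dense blocks* — `x1 = conv5x5(PReLU(BN(x)))`,
  `x2 = conv5x5(PReLU(BN([x, x1])))`, output `conv1x1(PReLU(BN([x, x1,
  x2])))` with 64 feature maps; one single-parameter PReLU is shared by the
  three activations of a block;
* 2×2 max pooling that records argmax indices (four stages, hence the
  input-divisible-by-16 rule);
* a dense bottleneck block;
* four decoder stages that unpool with the stored indices, concatenate the
  encoder skip (128 input channels), and apply a dense block;
* a 1×1 classifier head.

The default head has **88 classes**: the pre-training label space is the 87
bilaterally-labelled structures of the automated infant segmentation
pipeline used for pre-training, plus background.  This configuration
carries exactly **3,520,871** trainable parameters per view network
(10,562,613 for the three), which pins down every architectural choice
above — with any other head size, normalization placement, or activation
parameterization the count does not come out.  Fine-tuned segmentation
heads use 5 classes (background + left/right hippocampus + left/right
amygdala).

Per-voxel class probabilities from the three views are fused as
`argmax(0.4 p_axial + 0.4 p_coronal + 0.2 p_sagittal)`; ties go to the
lowest class index (background-favouring).  The weights are configuration,
not constants.

The layers are implemented in NumPy/Numba (NCHW float32, direct-convolution
kernels with hand-written backward passes).  Gradient correctness is
established in the test suite by adjoint identities for the linear
operators and finite-difference checks against an independent float64
reference forward pass of a dense block; max-unpooling is genuinely
discontinuous in its inputs, so whole-network finite differences are not
meaningful and are not used.

## Preprocessing

Volumes are reoriented to a canonical RAS-like axis order at load.  Two
grid operations feed the network:

* `conform_size` — the minimal edit to the divisibility rule: symmetric
  background cropping to the largest smaller multiple of 16 (extra voxel
  from the high side on odd remainders), allowed only when the removed
  slabs carry no label and no intensity deviating ≥ 0.1 from the border
  background level; otherwise symmetric padding with the background value.
  An optional trilinear resampling mode exists for parity with
  field-of-view upsampling, but padding is the default because it keeps
  label geometry exact.
* `tight_conform` — standard pipeline preprocessing that crops to the head
  bounding box rounded up to the next multiple of 16.  This is the default
  inside the training harness: it removes empty background, improves the
  foreground/background class balance, and shrinks the slice grid.

Both return an invertible `ConformRecord`; predictions are mapped back to
the original grid before any scoring.  Intensities are z-scored over the
whole (conformed) volume.

## STAPLE consensus

Binary STAPLE treats the true segmentation as latent and each rater as a
(sensitivity `p_j`, specificity `q_j`) channel; EM alternates posterior
computation (E) with performance re-estimation (M).  Choices:

* prior `"auto"`: the mean foreground fraction across raters — a global,
  spatially constant prior.  A fixed 0.5 prior collapses to the empty
  labelling for small structures on large grids (the classic prior
  sensitivity of STAPLE), so it is not the default.
* initialization `p = q = 0.99999`, all probabilities clamped to
  `[1e-5, 1 - 1e-5]`; the E step runs in log space.
* computation restricted to the union mask's bounding box dilated by 5
  voxels (`roi="union-dilate:5"`), because the all-background exterior
  otherwise dominates the specificity estimates; `roi="full"` disables
  this.  With the auto prior, the full-grid result matches SimpleITK's
  STAPLE filter to ~1e-3 on phantom structures (asserted in the tests).
* the observed-data log-likelihood is recorded every iteration and is
  non-decreasing (asserted); convergence when max |Δp|, |Δq| < 1e-6.

Multi-label consensus runs binary STAPLE per structure; a voxel takes the
label with the highest posterior among those ≥ 0.5 (ties at exactly 0.5
count as foreground), else background.  Inter-rater QC reports mean
pairwise Dice per structure with an inclusive 0.6 pass threshold.

## Evaluation metrics

* **DSC** `2|A∩B|/(|A|+|B|)`; undefined (NaN + reason) when both masks are
  empty.
* **ICC(3,1)** — two-way mixed, consistency, single measure — on paired
  voxel values within the union bounding box dilated by 5 voxels.
  Full-volume ICC is background-dominated and nearly meaningless, hence the
  ROI; it is configurable.  Whether the original analyses computed ICC
  voxelwise or across subjects is not determinable from the source; this
  package's choice is voxelwise within the ROI and is documented as its
  own.
* **ASD** — surfaces are foreground voxels with a 6-connected background
  neighbour; the value is the symmetric mean of the two directed mean
  nearest-surface distances in mm (the average-Hausdorff convention of the
  widely used surface-distance tooling).
* Method comparison: one-way ANOVA per structure × metric across methods,
  Benjamini-Hochberg adjustment across the table.  Undefined per-subject
  values are excluded, never imputed as 0.

## Training harness

Loss: class-frequency-weighted cross-entropy (inverse-square-root
frequency, mean-normalized) plus a soft Dice term over foreground classes,
the standard pairing for this architecture family; both weights are
configuration.  Optimizer: Adam (β = 0.9/0.999).  Pre-training uses a
seeded shuffled 80/20 train/validation split (floor on the training side;
473 subjects split 378/95) and logs per-epoch losses.  Slice sampling keeps
every slice containing foreground plus a 25% random sample of empty slices.

Fine-tuning follows the two-phase transfer schedule: 5 epochs with only the
classifier and final decoder block trainable, then 15 epochs with
everything unfrozen, at learning rate 5e-4 and batch size 8.  During the
frozen phase the backward pass stops after the final decoder block — exact,
because nothing upstream is trainable.  The ablation arm (`init=None`)
skips the frozen phase and trains from random initialization for the same
total epoch budget.  LOOCV fine-tunes on n−1 subjects per fold and predicts
the held-out subject through the full conform → per-view predict → fuse →
restore pipeline; fold construction structurally excludes the held-out
subject from every update, and the tests assert it.

The desk-scale configuration used by the end-to-end tests is 3 feature
maps with 3×3 convolution kernels (kernel size is a searched
hyperparameter in this model family; the architecture — dense blocks, four
index-preserving pooling stages, unpooling decoder — is unchanged).  The
capacity matters for what the ablation can show: a transfer advantage
exists only where the fine-tuning budget cannot fully train the network
from scratch.  With ample capacity the prescribed 20-epoch schedule
saturates both arms on easy phantoms (both ≈ 0.99 Dice, difference in the
noise), and with too little capacity (2 feature maps) fine-tuning cannot
escape the pre-training basin at all and transfer *hurts* — both
well-known regimes.  At 3 feature maps the from-scratch arm is genuinely
budget-limited while the pre-trained arm converges, so on 12 jittered 64³
phantoms the pre-trained arm reaches mean held-out foreground Dice far
above the 0.70 bar and clearly beats random initialization, matching the
published ablation direction.

## Synthetic phantom

The phantom is a minimal skull-stripped infant brain: an ellipsoidal
"brain" (semi-axes 15.5/16.0/15.5 voxels on a 64³, 0.9 mm isotropic grid)
containing four structures per the label scheme 1/2 = left/right
hippocampus, 3/4 = left/right amygdala.  Each hippocampus is a torus
segment (centreline radius 5.5, tube radius 2.2, 200° arc, spherical end
caps) — curved, banana-like; each amygdala is an ellipsoid
(3.5/3.6/3.3) abutting the anterior end of its hippocampus.  Tissue means
are background 0 (exact, as after skull stripping), brain 1.0, hippocampus
1.5, amygdala 1.38, with Gaussian noise (sd 0.08) inside the brain only:
the amygdala-hippocampus contrast (0.12) is deliberately far smaller than
the structure-brain contrast (≥ 0.38).  Structure volumes land in the
150-800 voxel range (hippocampi ≈ 380, amygdalae ≈ 170).  Per-subject
anatomy varies through target structure volumes (linear rescaling) and a
global brain scale.

Simulated raters perturb each structure's signed distance field with a
smooth Gaussian random field (correlation length 2 voxels), flip 5% of the
perturbed surface, and keep the largest connected component.  The default
boundary-field sd of 0.96 voxels is calibrated so that three raters agree
at a mean pairwise Dice of ≈ 0.76 over default phantoms — the level
reported for trained human raters on these structures.  Pairwise agreement
decreases monotonically in the noise sd.

The behavior cohort embeds volume-score associations with a Gaussian
copula.  Covariates: PMA at scan (44 ± 3 weeks), maternal education
(5-level ordinal from a latent normal), EPDS (integer, clipped 0-30).
Outcomes: CBCL-like T scores with population means/sds 48.3/10.6 (total),
47.6/9.12 (internalizing), 48.2/10.9 (externalizing), clipped to [20, 100]
and rounded to 0.1.  Confounding is genuine: PMA raises volumes and lowers
problem scores, education and mood load on the outcomes.  For each targeted
(structure, outcome) pair the *residual* latents (after removing covariate
loadings) are correlated at `2·sin(π·ρ/6)` — the inverse of the Gaussian
rank-correlation map — so the partial Spearman correlation equals the
target ρ in expectation.  The default embeds the right-amygdala
associations (−0.62 / −0.43 / −0.59 with total/internalizing/externalizing
problems).  Untargeted residual correlations default to 0.3 among
structures and 0.5 among outcomes; an infeasible (non-positive-definite)
combination raises.  Cohorts are lazy sequences: subject volumes are
regenerated on demand, so n = 500 never holds more than one volume in
memory.

What the phantom does *not* emulate: MRI physics (bias fields,
partial-volume mixing, scanner differences), preterm anatomy, true
hippocampal subfield geometry, or rater systematic bias (simulated raters
are unbiased around the true boundary).  Passing the desk-scale tests
therefore demonstrates that the pipeline machinery is correct and
well-calibrated under its stated noise model — not that the network
reaches any particular accuracy on real infant scans.

## Morphometry and brain-behavior statistics

Regional volume = voxel count × voxel volume (mm³).  "Adjusted for total
brain volume" is implemented as the ratio volume/TBV by default (TBV from
the above-background voxel count), with residualization on TBV behind a
flag; Spearman's rank invariance makes the two equivalent whenever the
adjustment preserves the subject ordering.

The partial Spearman correlation rank-transforms all variables (average
ranks on ties), residualizes the ranked measure and outcome on the ranked
covariates by least squares, and correlates the residuals; the two-sided p
value uses the t transform with **df = n − 2 − k** covariates.  (The
convention in the source material quotes df = 47 at n = 50 with three
covariates, which is inconsistent with this formula; this package reports
df = 45.)  If the covariates explain a variable completely the partial
correlation is reported as 0 with p = 1.  With zero covariates the
function reduces exactly to plain Spearman correlation.  The
brain-behavior matrix computes all measure × outcome cells with the shared
covariate set (PMA, maternal education, EPDS — sex is never included
because CBCL T scores are already sex-normed), flags cells at unadjusted
p < 0.05 as the primary screen, and always co-reports Benjamini-Hochberg
adjusted flags.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at desk scale, chosen
as the package's own working sizes: 20 phantoms for the rater calibration
and consensus checks, n = 500 subjects for the association recovery,
k = 5 raters on a 32³ grid for STAPLE performance-parameter recovery, and
8 pre-training + 12 LOOCV phantoms (64³) with the 4-filter/3×3 network for
the end-to-end transfer experiment.  Tolerances: EM convergence 1e-6;
metric oracle agreement 1e-8; probability normalization 1e-5; seeded
reruns reproduce training bit-for-bit on the same machine.  All randomness
flows from explicit integer seeds through `numpy.random.Generator`.

## Known limitations

* The NumPy/Numba network trains small configurations quickly but is not
  intended for the full 64-filter model at scale; the default configuration
  is exercised for architecture fidelity (parameter count, shapes), not
  trained in the tests.
* Batch-norm running statistics update during the frozen fine-tuning phase
  (as in standard practice); "frozen" refers to trainable parameters.
* STAPLE is per-structure binary with a global prior; spatially varying
  priors and joint multi-label variants are out of scope, as is manual
  editing of the consensus.
* Shape (spherical-harmonic) descriptors are not implemented; the
  brain-behavior matrix has 4 × 3 volume cells only.
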