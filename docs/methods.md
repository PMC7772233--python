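# Methods

## Problem setting

Ventricular volume is the clinically meaningful readout in hydrocephalus,
brain atrophy and related conditions, and volumetry requires segmentation.
In routine practice most head CT/MR scans are acquired *thick-slice*
(slice spacing > 3 mm) because they are fast; *thin-slice* scans
(≤ 3 mm) resolve the ventricular system far better but are rarer and more
expensive to annotate.  The two acquisition regimes differ statistically —
through-plane partial-volume averaging, noise level and noise texture — so a
segmenter trained on one degrades on the other (domain shift).

`ventseg` implements a thickness-agnostic semi-supervised training scheme:
the model is supervised only on labeled thick-slice images and regularized on
unlabeled thin-slice images, so that a single network serves both regimes.

## Model

The segmenter is a 2-D encoder–decoder applied slice-by-slice.  Grayscale
slices are replicated to three channels (the standard way of feeding
single-channel medical images to encoders designed for RGB input; adjacent-
slice stacking was rejected because thick volumes can have very few slices).

* **Encoder** — a residual convolutional pyramid with conv–BN–ReLU blocks.
  Two variants: `small` (widths 8/16/32, total downsampling 4; the default,
  sized for CPU training on 64×64 slices) and `resnet34` (the 34-layer
  residual topology, downsampling 32).  ImageNet weights are not bundled;
  requesting `pretrained=True` raises with instructions to use random
  initialization.
* **Decoder** — each stage is a convolution expanding to `C·r²` channels
  followed by sub-pixel rearrangement (depth-to-space): the `r²` channels of
  each pixel tile its `r × r` output block in row-major order,

      F_L = SP(W_L * F_{L-1} + b_L),

  upsampling by `r` per stage without transposed convolutions (costly) or
  interpolation (adds no information).  Stage upscale factors compose to
  exactly the encoder's downsampling, so output resolution equals input
  resolution.
* **Skip connections** — encoder features are concatenated at matching
  resolutions by default (`skip_connections=false` disables them); pure
  decoding from the bottleneck loses boundary detail.
* The head is a 1×1 convolution with a terminal softmax over `C ≥ 2`
  classes (softmax even for binary segmentation, since the losses are
  written over class distributions).

The network stack (convolution via im2col matrix products, batch
normalization, pixel shuffle, Adam/SGD) is implemented in numpy with
analytic gradients; every backward pass is itself a convolution or a tensor
contraction.  All backward passes are verified against central differences
in the test suite.

## Objective

With labeled thick-slice pairs `(x_s, y_s)` and unlabeled thin slices `x_t`,

    L(x_s, x_t) = L_S(p_s, y_s) + λ · L_T(p_t)

* `L_S` — pixel-mean cross-entropy, `−(1/HW) Σ_n Σ_c y^{n,c} log p_s^{n,c}`.
* `L_T` — the negated f-divergence between each pixel's predicted class
  distribution and the uniform distribution `U = 1/C`:

      L_T = −D_f(p_t ‖ U) = −(1/C) Σ_c f(C · p_t^{n,c}),

  averaged over pixels.  Minimizing `L_T` pushes unlabeled predictions away
  from uniform, i.e. toward confident class assignments — the
  low-density-separation principle of entropy minimization.  Two generators
  are provided: KL (`f(x) = x log x`, with `f(0) = 0`) and Pearson χ²
  (`f(x) = x² − 1`, needing no clamping).  χ² is the default: its binary
  reference gradient `2 − 4p` is bounded by 2, whereas KL's
  `log(1−p) − log p` diverges at confident pixels and concentrates updates
  on easy samples.

The reference gradients above are the simplex-constrained closed forms and
are exposed as `binary_gradient_reference` for analysis only; training
backpropagates through `L_T` as written (direct differentiation along the
binary simplex gives `4 − 8p` for χ² — the same shape at twice the scale,
which is absorbed by λ).  The tests assert proportionality and the zero
crossing at `p = 0.5`, not a particular constant.

Losses are means over pixels and batch, so λ is independent of image and
batch size.  λ defaults to 0.1 with a linear warm-up over the first 10 % of
steps: divergence-type regularizers applied at full strength from step 0 can
lock in a collapsed solution before the supervised term shapes the features.
Probabilities are clamped at 1e-12 inside logarithms only.

Training alone on `L_T` (no labels) collapses to confident single-class
output — the regularizer's optimum ignores anatomy entirely.  The ablation
harness demonstrates this (near-zero Dice at > 0.95 mean per-pixel
confidence), which is why the term is only ever a *companion* to
supervision.

## Why the unlabeled term helps here

Two mechanisms act on the thin-slice domain during joint training:

1. **Normalization-statistics alignment.**  Batch-norm layers see unlabeled
   thin batches in every step, so both batch statistics during training and
   the running statistics used at inference reflect both domains.  A
   thick-only model's statistics are thick-specific and mis-normalize thin
   activations.  This is the dominant effect in our experiments.
2. **Decision sharpening.**  On thin slices the thick-trained decision
   function is underconfident around structures the thick domain
   underrepresents (fine horns, noise texture); the divergence term commits
   these pixels and the gradients adapt shared features.

The second mechanism cuts both ways: when the target domain is so noisy that
ambiguous pixels are majority-background, sharpening erodes the foreground.
λ = 0.1 with warm-up keeps the term subordinate to supervision.

## Training protocol

Each optimization step draws one labeled batch (8) and one unlabeled batch
(8), evaluates the combined objective on the pair and applies one Adam
update (lr 1e-3); an alternating mode (separate updates per term) exists for
comparison.  One epoch is one pass over the labeled set; the unlabeled set
cycles with reshuffling.  Default 16 epochs — on the default cohort the
supervised loss plateaus well before this, and shorter schedules leave the
run under-converged with visible seed-to-seed variance.  No augmentation
(it would confound the domain-gap experiments), no early stopping (runs are
fixed-length for reproducibility).  All randomness derives from one seed
through named streams; identical config + seed reproduce checkpoints, logs
and reports byte-for-byte.

Inference is slice-wise: each slice through the network, argmax over
classes, restacked into a mask carrying the source volume's header.  Sizes
not divisible by the encoder stride are reflect-padded and cropped back.

## Synthetic cohort

Hospital thick/thin cohorts are not distributable, so the package ships a
phantom generator that reproduces the *statistical structure* the method
assumes, with known ground truth:

* **Geometry** — a head-shaped ellipsoid (radii ≈ 60×85×75 mm, jittered ±5 %
  per subject) of brain tissue containing a bilateral, branched
  ventricle-like cavity: two mirrored curved tubes (anterior horn → body →
  atrium → posterior horn, plus an inferior-horn branch) and a midline
  third-ventricle bridge, built as capsules along jittered polylines.  A
  severity factor scales the tube radii continuously from normal (1.0)
  through atrophy-like (1.4) and NPH-like (1.8) to acquired-hydrocephalus-
  like (2.3) enlargement; cohort severity is drawn uniformly from those four
  levels.  Ventricle volume is monotone in severity, and the cavity is
  capped inside the brain so the nesting ventricle ⊂ head ⊂ volume always
  holds.
* **Grid** — 64×64 in-plane at 3 mm; 48 thin slices at 0.6 mm centred on
  the ventricles.  Intensities are abstract units; only the contrast
  ordering is contractual (CSF dark on both CT and T1: ventricle mean 0.35
  [CT] / 0.20 [MR] vs brain 1.0, background 0).
* **Thick-slice model** — the thick volume is the noiseless thin volume
  block-averaged over `k = 6` consecutive slices (spacing 3.6 mm > 3 mm, so
  it is thick by the clinical definition); masks follow by majority vote
  with ties counting as foreground (any-vote would systematically inflate
  thick masks).  Block means conserve intensity totals exactly, which the
  tests assert.  Trailing slices that do not fill a block are dropped and
  recorded in the metadata.
* **Noise** — additive Gaussian inside the head, spatially correlated
  in-plane (Gaussian-filtered white noise renormalized to sd 0.22,
  correlation length 5 mm) to emulate reconstruction-kernel mottle rather
  than white pixel noise.  The thick volume receives an *independent* draw
  at sd/√k, as averaging k acquisitions would give.  The resulting gap —
  thin slices noisier and texture-rich, thick slices cleaner and
  through-plane blurred — is the domain shift the learner must bridge, and
  the generator's tests assert that it exists (upsampled thick masks
  disagree with thin masks).
* An optional in-plane point-spread blur (`in_plane_psf_mm`, default off)
  softens tissue boundaries before slab averaging; at the default grid the
  3 mm voxel is already the effective resolution limit.

What the phantom does *not* model: gyri/sulci and any internal brain
texture, skull and scalp, bias fields, beam hardening, motion, and
pathology other than ventricular enlargement.  Passing results therefore
demonstrate that the method behaves as designed under the stated
domain-shift physics — not clinical-grade performance on real scans.

The default cohort is 40 labeled thick volumes, 40 unlabeled thin volumes
and 10 held-out phantom pairs (each contributing one thick and one thin test
volume), balanced CT/MR.  Unlabeled and test masks are written to disk but
withheld from the manifest; evaluation reads them from a separate
ground-truth file.  Splitting is per-volume to avoid slice leakage between
train and test.

## Preprocessing

Volumes are z-scored over the head region before slicing.  The head region
is detected by comparing against the background reference value taken from
the volume border (air surrounds the head), which makes normalization
exactly invariant under positive affine intensity maps `a·x + b` and
idempotent; the statistics are stored so the transform is invertible.
Constant volumes are rejected.  CT windowing is not emulated because phantom
intensities are abstract.

## Evaluation

Dice `2|A∩B| / (|A|+|B|)` per volume, with both-empty defined as 1 (the
masks agree there is no ventricle; empty-vs-nonempty is 0).  Reports group
volumes by modality × {thick, thin, mixed}; group means are volume-level
(each volume weighs equally — the clinically meaningful unit), with a
slice-count-weighted (slice-pooled) aggregate logged alongside since either
aggregation is defensible.

The ablation harness trains three models from identical initialization on
the same cohort: Exp 1 thick-only supervised (λ = 0), Exp 2 thin-only
unsupervised (`L_T` alone), Exp 3 the combined objective.  Exp 2's epoch
anchor is the much larger unlabeled set, so its epoch count is rescaled to
run a comparable number of steps.  On the default cohort the expected
qualitative structure is: Exp 1 strong on thick and visibly weaker on thin;
Exp 2 collapsed (near-zero Dice, high confidence); Exp 3 near Exp 1 on thick
and several Dice points above Exp 1 on thin.

## Numerical choices and conventions

* float32 parameters/activations; losses accumulated in float64.
* He-normal initialization, deterministic per seed; Adam (β 0.9/0.999,
  ε 1e-8) or plain SGD.
* Sub-pixel channel order is pinned row-major (`c·r² + (i%r)·r + (j%r)`);
  any consistent convention is learnable, the tests pin this one.
* `f(0)` conventions: 0 for KL (the `x log x` limit), −1 for χ² (direct
  evaluation) — required to evaluate one-hot pixels.
* Dice of two empty masks ≡ 1; thick/thin threshold is strict (> 3 mm);
  exactly 3 mm is thin.
* Checkpoints are single-file `.npz` archives with the model config
  embedded; gzip members of NIfTI files are written with fixed metadata so
  identical volumes are byte-identical.

## Problem sizes

Defaults are sized for a single CPU: 64×64 slices, the `small` encoder
(~0.1 M parameters), 320 labeled slices / 1 920 unlabeled slices per run,
16 epochs (640 steps).  A full ablation (three trainings plus evaluation)
completes in roughly ten minutes; the two headline experiments in about
eight.

## Known limitations

* The phantom's simplicity means absolute Dice values are not comparable to
  clinical benchmarks; only the relative structure (thick vs thin, with vs
  without the unlabeled term) is meaningful.
* Batch statistics are a large part of the semi-supervised gain; a
  normalization-free variant would isolate the pure divergence effect but is
  not implemented.
* The `resnet34` encoder is provided for architectural fidelity but is slow
  in this numpy stack and starts from random weights; the `small` encoder is
  the tested configuration.
* Joint CT+MR training is the default regime; per-modality training is
  available through the cohort config but not separately tuned.
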