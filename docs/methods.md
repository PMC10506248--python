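# Methods

This note documents the models and procedures `bcseg` implements, the
defaults it ships, and the design decisions taken where the design was genuinely open.

## Preprocessing

Three steps, in fixed order: HU windowing → adaptive median filtering →
image-wise z-score.

* **Windowing is clamping, not rescaling.** Intensities are clipped to the
  target's window (liver [−25, 125], abdomen [−219, 190], thigh
  [−198, 189]; skeletal-muscle and spine-bone-marrow targets override with
  [−181, 216]). Clamping preserves HU semantics; any residual scale is
  removed by the z-score anyway. Windowing is idempotent and its output is
  bounded by the window by construction.
* **Adaptive median filter.** The classical growing-aperture variant: per
  pixel the aperture grows from 3×3 up to `amf_max_window` (default 7, odd);
  once the aperture median is strictly between the aperture extremes, the
  pixel is kept if it is itself strictly between the extremes, else replaced
  by the median; if the largest aperture is still degenerate the median of
  that aperture is used. Borders are reflect-padded. This removes
  salt-and-pepper impulses while leaving smooth gradients untouched; the
  implementation is vectorized but is tested pixel-for-pixel against a
  direct per-pixel transcription of the rule.
* **z-score** uses the population (ddof = 0) standard deviation; an image
  whose spread is below `eps` (default 1e−8) maps to all zeros rather than
  dividing by ~0. The choice of population vs. sample sd is immaterial for
  training but must be fixed for exact tests.

## Architectures

All four networks share one contract: single-channel input, sigmoid
probability output of the same spatial size, 2×2 max-pool downsampling,
zero "same" padding, batch normalization before every ReLU, channel widths
`[16, 32, 64, 128, 256]` per level by default, and a 1×1 convolution +
sigmoid head. Weight initialization is Kaiming fan-in normal for
convolutions and scale-1/shift-0 for BN, driven by a single seed
(bit-reproducible builds).

Where a textbook block layout and the reference trainable-parameter
budgets (0.81 M / 2.29 M / 0.35 M for ResUNET / UNET++ / Ghost-UNET++ at
the default widths) could not both be satisfied, the budget won; the
reconciled layouts are:

* **UNET++** (2,293,505 params): the nested topology; node (i, j) applies
  two conv3×3-BN-ReLU layers to the concatenation of all nodes (i, 0..j−1)
  and the bilinearly upsampled node (i+1, j−1). Upsampling is
  parameter-free bilinear interpolation (a learned up-convolution would
  overshoot the 2.29 M budget). Deep supervision is off: one head on node
  (0, 4).
* **ResUNET** (808,241 params): a plain U with residual blocks. That
  budget is only attainable with single-conv residual blocks
  (conv3×3-BN as the residual path, 1×1 projection when channel counts
  change, ReLU after the addition), additive skips, and learned 2×2-stride-2
  transposed-convolution upsampling that projects down to the skip width.
  The standalone `ResidualBlock` still defaults to the textbook two-conv
  path; the ResUNET configuration selects the single-conv variant.
* **Ghost-UNET++** (346,953 params): the UNET++ wiring with one ghost
  bottleneck per node — 15 bottlenecks at 5 levels. A ghost module makes
  ⌈out/s⌉ intrinsic channels with a primary 1×1 convolution and the
  remaining channels with a cheap depthwise 3×3 convolution of intrinsic
  maps (s = 2 by default); its learnable scale/shift are the BN affine
  parameters of each branch. A bottleneck stacks an expanding module
  (hidden width 1.5 × out, the value that lands the 0.35 M budget; the
  original ghost-network expansion ratios are block-specific and were not
  restated) and a projecting module around a residual shortcut (identity,
  or 1×1 projection on channel change). Stride is 1 everywhere; resampling
  is external to the bottlenecks.
* **Ghost-UNET** (286,773 params; no reference budget): the plain U
  topology with the same ghost bottlenecks, concat skips and bilinear
  upsampling. The cited asymmetric-decoder idea is under-described, so the
  decoder is mirror-symmetric by default with a `light_decoder` flag that
  halves decoder widths.

The efficiency ordering ghost_unetpp < resunet < unetpp holds for any
common widths, and a ghost module at s = 2 always has fewer parameters than
the plain convolution of the same in/out channels.

### The numpy engine

No deep-learning framework is part of the dependency set; `bcseg.ndnn` is a
small reverse-mode autodiff engine on numpy arrays (NCHW layout) providing
exactly the ops the nets need: im2col convolution, depthwise convolution,
2×2-stride-2 transposed convolution, batch normalization with running
statistics, 2×2 max pooling, ×2 bilinear upsampling (half-pixel centers),
ReLU/sigmoid, concat/add, and Adam. Every op's gradient is checked against
central finite differences in the test suite. Parameters are float32;
gradient-check tests run the same code in float64.

## Loss and evaluation

Training uses the smoothed soft Dice complement
1 − (2·Σ p·g + s) / (Σ p + Σ g + s) with s = 1, computed per image and
averaged over the batch; for binarized predictions it coincides with the
set form exactly, and the smoothing term makes the empty-vs-empty case a
loss of 0 instead of 0/0. Evaluation uses the plain Dice overlap
2|A∩B|/(|A|+|B|) on predictions binarized at 0.5 (the ≥ convention decides
ties; the evaluation threshold is this package's choice), with 1.0 defined
for two empty masks.

## Bone pipeline

Cortical bone: threshold HU > 400, remove connected components smaller than
`min_object_px` (default 20 px — calcifications), fill enclosed holes
smaller than `max_hole_px` (default 50 px). Bone marrow: fill all cavities
of the cortical shell (background-flood-fill complement) and subtract the
shell, so marrow ∧ cortical = ∅ and marrow ∨ cortical equals the filled
shell exactly. If fewer than two cavities emerge — a hairline cortex break
leaking a cavity — a light 3×3 closing is applied before the fill (the
subtracted shell stays untouched); the closing is off otherwise. QC counts
shells and cavities and flags cavity counts ≠ 2 (missing femur, solid
implant), empty threshold results, marrow touching the image border, and
shell/marrow overlap. Defaults for object/hole sizes and 8-connectivity are
this package's choices; "small" has no canonical pixel count.

## Depot arithmetic

Raw RPAT/DSAT delineations are outer contours that may cover non-adipose
pixels, so they are clipped to the parent depot before subtraction:
RPAT = VAT ∩ raw, IPAT = VAT \ RPAT (and DSAT/SSAT likewise from SAT). The
derived pair therefore partitions the parent exactly (integer conservation
of pixel counts) and re-derivation from derived masks is a fixed point.

## Phantoms

The generator emulates the content of the three protocol slices with
parametric geometry (jittered ellipses, annuli, wobbly blobs):

* **thigh**: two legs, each an SAT rim around a muscle disc, with IMAT
  streaks inside the muscle, a cortical annulus and a marrow core;
* **abdomen**: a body ellipse with an SAT ring split by a wobbled fascia
  level into SSAT/DSAT, an interior VAT blob split at a posterior line into
  IPAT/RPAT, a spine ring with marrow, and abdominal-wall plus paraspinal
  muscle (a `fascia_visible=False` variant omits the DSAT/SSAT masks,
  mirroring scans where the fascia cannot be delineated);
* **liver**: a liver blob (with an eroded copy as the "crude" mask, a
  strict subset) and a disjoint spleen.

Tissue HU means/sds are standard attenuation values (air −1000, adipose
−100±15, muscle 50±10, liver 55±8, spleen 50±8, marrow −40±15, cortical
1200±100) with a global additive Gaussian term, default sd 5 HU; a
noiseless copy of any spec is one call away. Spec invariants guarantee
threshold separability (cortical mean − 3 sd > 400 HU) and adipose/muscle
separation at 3 sd. All mask-consistency identities hold exactly for every
generated sample, and the noise-free thigh phantom is solved exactly by the
bone pipeline.

What the phantoms do **not** model: CT physics (beam hardening, partial
volume, dose modulation), anatomical atlases, pathology, positioning
variation. Passing tests on phantoms therefore demonstrate correctness of
the pipeline mechanics and the learnability of the targets' intensity/shape
structure, not clinical segmentation accuracy on cohort data.

## Experiment protocol

One binary model per target. `make_plan` shuffles deterministically,
reserves floor(0.10·n) samples for testing only when n > 100 (so n = 2677
gives 267 test + 2410 CV-pool samples; n = 51 trains on everything), and
splits the rest into k folds whose sizes differ by at most one. Training
uses Adam (lr 1e−4, batch 2) on the smoothed Dice loss for at most 100
epochs with early stopping on the validation Dice loss; patience is 10
epochs (the protocol fixes early stopping but not its parameters).
The best-validation checkpoint within a fold is kept; the best fold's model
is evaluated on the test split when one exists. Splits, weight
initialization and data order are all seeded; two runs with the same seeds
are identical.

The repeatable end-to-end demonstration is deliberately scaled down to desk
size: a Ghost-UNET++ at widths [8, 16, 32] trained on 60 thigh phantoms of
128×128 with an 80/20 split for at most 30 epochs, which reaches held-out
mean Dice ≥ 0.9 on the SAT target in a few minutes on one CPU. Cohort-scale
Dice tables cannot be reproduced here because the underlying cohort data
are access-restricted; the phantom-based run checks the training mechanics
and convergence behaviour instead.

## File conventions

Slices: NIfTI int16 HU, or 16-bit PNG storing HU + 1024 (PNG cannot store
negatives; the offset is a fixed convention), or single-frame DICOM
(read-only; slope/intercept rescale applied). Masks: 8-bit PNG {0, 255} or
NIfTI {0, 1}; anything else is rejected as non-binary. Grids are row-major,
0-based (row, col), origin top-left. Write-then-read is the identity for
integral slices and all masks. Checkpoints are `.npz` parameter archives
with a JSON sidecar carrying the architecture configuration.

## Known limitations

* The engine is CPU-only and unoptimized for large batches; full-width
  512×512 training is possible but slow, which is why the shipped
  demonstrations use reduced widths and sizes.
* `ResidualBlockCfg` supports one- and two-conv residual paths only.
* DICOM support covers single-frame CT with rescale tags; no series
  assembly.
* The fascia split in the abdomen phantom is radial, which cannot produce
  the re-entrant fascia geometries seen in some subjects.
* Ghost modules require even channel widths at ratio 2 for an exact
  intrinsic/ghost split; odd widths are handled by ghosting fewer channels.
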