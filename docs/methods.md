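# Methods

## Scope and data model

The package segments the elective lymph-node (LN) levels I–V of the neck on
3D CT.  All geometry is physical: a voxel's position is
`origin + index · spacing` (mm), array axes are (x, y, z) =
(left–right, anterior–posterior, caudo–cranial), and every margin, distance
and ROI is specified in millimetres, never in voxels.  Volumes and label
maps are NIfTI-1 on disk; label maps are unsigned integers with
0 = background and 1–5 = levels I–V.  DICOM/DICOM-RT parsing is out of
scope.

Pre-processing interpolates CT and label maps to a common isotropic grid
(default 1.25 mm) with 3rd-order spline and nearest-neighbour interpolation
respectively.  Resampling uses the cell-centred (`grid_mode`) convention so
the physical extent is preserved to within one voxel; nearest-neighbour
interpolation guarantees the output label set is a subset of the input's.
CT intensities are normalized through a linear clamp window (center C_C,
width C_W, default 0/700 HU): values at or below C_C − C_W/2 map to 0, at
or above C_C + C_W/2 to 1, linearly between.  This dialect is a stated
contract so tests are bit-reproducible.

## Networks and compute backend

No deep-learning framework is part of the runtime stack; the networks are
built on an internal numpy layer library (`lnlevelseg.nn`) with
hand-written backward passes, verified against finite differences and
scipy correlation oracles.  The stride-1 "same" convolutions — the
computational bottleneck — are ~100 lines of C embedded in
`lnlevelseg._ckernels`, compiled with the host compiler at first import and
bound via ctypes; each kernel keeps a 4-wide spatial tile of 16-float
vector accumulators in registers.  If no compiler is available the
pure-numpy im2col path produces identical results (to float32 round-off).
The data gradient of a convolution is computed as a full correlation of the
zero-padded output gradient with the spatially flipped, channel-transposed
kernel, so no scatter-add is needed anywhere.

**Residual 3D UNet.**  Encoder/decoder with residual blocks (two
conv–BN–ReLU units, identity shortcut, 1×1×1 projection when channel
counts change), batch normalization after every 3×3×3 convolution before
the activation, 2× max-pooling, nearest-neighbour upsampling, skip
concatenation followed by a 1×1×1 channel-compression convolution, and a
softmax head.  The published description fixes the patch size (64³),
block type and normalization order but not the filter counts; defaults are
depth 4 with 16 base filters doubling per level, exposed in `UNetSpec`
(tests and the phantom study use tiny variants).  M = 6 classes in the
direct configuration, M = 2 for the foreground stage of the sequential
configuration.  Glorot-uniform initialization from a caller seed; dropout
(default 0.1, on the bottleneck) is active only during training.

**Multi-view (2.5D) classifier.**  For a query voxel, three orthogonal
in-plane views of 32×32 samples are extracted at three pyramid scales with
voxel strides 1/2/4 — physical spans 4/8/16 cm at 1.25 mm spacing (the
32-sample width is derived from the printed 4 cm scale-0 span; both are
configurable).  Out-of-volume samples use edge replication.  Each
(scale, view) branch has independent weights (the published figure is
ambiguous on weight sharing): three conv(3×3)–BN–ReLU–pool stages with
16/32/64 filters, flattened, concatenated across all nine branches, then a
128-unit fusion layer, dropout, and a softmax head (M = 6 standalone,
M = 5 in the sequential configuration).

## Sampling and augmentation

Training patches are drawn from two pre-defined unilateral ROIs
(280×200×280 mm, one per side, centred on each lateral half; the original
ROI placement protocol is not published).  Patch centers follow a per-axis
truncated normal law whose mean and standard deviation are the across-case
moments of the center of mass of the combined I–V structure; the standard
deviation estimator is the population form (divide by N) — fixed and
documented so tests are exact.  Sampling uses the inverse CDF on the
truncated interval directly, so patches are guaranteed to lie entirely
inside the ROI without rejection loops.  This concentrates patches on the
structure and keeps the Dice-loss denominator away from zero.

Augmentation (all models, on the fly): left–right flip with p = 0.5;
rotation with p = 0.4 in either the sagittal or the transversal plane (fair
coin; the source states "either … or" without probabilities), angle uniform
in ±5°, image by 3rd-order spline, labels nearest-neighbour; contrast
adaptation with p = 0.4, drawing window center ~ N(0, 21 HU) and width
~ N(700, 21 HU) (21 = 3 % × 700).  Raw HU patches are kept until
augmentation and windowed last, so a sampled window is the effective one.
All random variates are consumed in a fixed order per draw, making every
augmentation reproducible from one seed.  For the multi-view network, flip
and contrast act directly on the extracted views; in-plane rotation is not
applied there, since it would require rotating the full volume per query
voxel for a patch-level effect — a deliberate, documented narrowing.

## Losses

Multi-class soft Dice: `DSC_loss = Σ_{m=1..M} W_m · DL_m` over foreground
classes, `DL_m = 1 − 2|A_m∩B_m|/(|A_m|+|B_m|)` on softmax probabilities
(not argmax).  For binary segmentation this reduces exactly to the
single-class Dice loss.  The denominator is unconstrained for empty
patches; we stabilize with ε = 1e-5 added to the denominator only, which
preserves DL = 1 for disjoint non-empty masks (configurable).  Class
weights use inverse-frequency "balanced" weighting over foreground voxels,
`W_m = N_fg / (M_fg · N_m)` — the published text defers to a library
default; background is excluded from the totals, matching the foreground
indexing of the loss.  Voxel classification uses categorical cross-entropy
summed over observations, with probabilities clipped to
[1e-7, 1 − 1e-7] before the log.

## Training orchestration

Adam with lr₀ = 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e-7; learning rate
decays 5 % per epoch to a floor of 1e-4.  A UNet "epoch" is a fixed budget
of sampled pairs (4096 at study scale — roughly 34 per side per patient
over 60 bilateral cases; the notion of an epoch is a convention in
patch-based training and the budget is configurable).  The multi-view
network trains per epoch on a fresh random subset of at most 20 % of the
voxel pool, split equally (±1) across classes with minority oversampling
by replacement.  5-fold cross-validation partitions cases 48/12 at study
scale.  Only the checkpoint with the best validation DSC is kept;
validation DSC is computed on sampled patches/voxels rather than full
volumes for tractability (unspecified in the source), and the validation
cases are carved from the training pool, never from the held-out fold, to
avoid checkpoint-selection leakage.  Ensembles train n members
sequentially with seeds `base_seed + index` and fuse predictions by the
highest summed in-class probability; argmax ties break toward the lower
class index (background wins), deterministically.  Batch size for the UNet
defaults to 2 patches (the original was GPU-memory-bound; not printed).

## Inference and post-processing

Full-volume UNet prediction slides the window (64³ default) with stride
window/2 and scores only the central (window/2)³ voxels, so each voxel is
classified exactly once with context on all sides.  The volume is
edge-replication padded by window/4 plus whatever rounds each axis up to a
stride multiple, making the central tiles exactly cover the original grid.
Masked multi-view classification touches only voxels inside the evaluation
mask (reference ⊕ 15 mm for C2 — replicating the reference-derived mask of
the original evaluation, which leaks reference information into C2 and is
flagged as such; UNet foreground for C3), with runtime proportional to the
mask size.

Post-processing of the combined I–V structure: volumetric (3D) hole
filling — the source does not state 2D vs 3D; we choose 3D — then removal
of all but the largest 26-connected component(s).  The operation keeps one
component by default; the whole-volume pipeline keeps two, because the
combined structure occurs once per side of the neck and the original
processing was per unilateral ROI (its description uses the plural
"components").  Voxels added by hole filling take the majority label of
their 26-neighbourhood, propagated iteratively for deep holes.  PTVs are
Euclidean 4 mm expansions of the level unions I–V and II–IV.  All
expansions use the exact Euclidean distance transform in mm, not
voxel-count dilation, for anisotropic robustness.

## Evaluation metrics

DSC with the conventions: both masks empty → 1, exactly one empty → 0
(phantoms can lack a level).  Hausdorff distance is the exact
100th-percentile symmetric surface distance (HD95 is an option, not the
default); mean surface distance symmetrizes as the mean of the two
directed means.  Surfaces are 6-connectivity-exposed border voxels;
connected components use 26-connectivity.  Volume outside the reference is
|pred \ ref| × voxel volume in mL.  Volumetric agreement uses ICC(3,1) —
two-way mixed effects, single measurement, consistency — computed from the
two-way ANOVA sums of squares (cross-checked against pingouin in the
tests); it is undefined for constant inputs and fewer than 3 cases.
Paired significance testing (Wilcoxon signed-rank with Bonferroni
correction) is deliberately left to standard statistics libraries and is
not part of the evaluation surface.

## The synthetic phantom

The phantom emulates the features of the clinical data that drive the
method: bilateral level I–V structures inside a soft-tissue neck cylinder
(≈40 HU plus Gaussian noise, default SD 15 HU) with a bone-like spine
landmark (≈700 HU) on an air background (−1000 HU).  Levels II/III/IV are
stacked slabs sharing a lateral band — axially exclusive by construction
when the phantom is not angulated — with level I attached
anterior-cranially and level V posteriorly, so the combined structure is
one 26-connected component per side.  Level tissue is rendered at ≈70 HU:
a +30 HU contrast chosen as a plausible nodal-tissue excess over
background so that the default 0/700 window yields a learnable but noisy
signal (per-voxel SNR ≈ 2).  Each phantom draws a small random anatomical
variation from its seed — a rigid in-plane shift, a cranio-caudal placement
shift and a common scaling of the level extents, each within ±3 %
(`anatomy_jitter`) — emulating the inter-patient variation that gives the
truncated-Gaussian patch sampler a meaningful across-case standard
deviation; without it every case would have an identical centre of mass and
the sampler would degenerate to a single fixed patch position.  Optional
pitch/tilt angulation (≤20°) reproduces the slice-rule-breaking confounder
of angulated patients.  The default grid is 128×128×160 at 1.25 mm;
`PhantomSpec.tiny()` is the half-scale variant (64×64×80) used for
desk-scale training.

What the phantom does **not** emulate: anatomical boundary definitions
(the real task's labels derive from guideline landmarks, not intensity),
pathological nodes, contrast agents, CT artifacts, or inter-observer
variability.  Passing phantom tests therefore demonstrates that the
pipeline machinery — sampling, optimization, inference, fusion,
post-processing, metrics — is correct and learns intensity-plus-context
structure; it does not certify clinical segmentation accuracy.

## Scaled-down study conditions

The clinical results of the original setting require a 70-patient cohort
and GPU-scale budgets.  The package's end-to-end study
(`lnlevelseg.experiments.run_phantom_experiment`) runs the sequential
configuration at phantom scale: 16 half-scale phantoms (10 train /
2 validation / 4 held-out), a 3-member 2-class UNet ensemble with depth 2,
base 8 filters, 32³ patches, 256 pairs per epoch, 10 epochs, batch 4, and
a single small multi-view classifier (16 in-plane samples, 4/8/16 filters)
for relabelling.  These sizes are the package's chosen desk-scale
conditions: large enough that the combined-structure DSC on held-out
phantoms comfortably exceeds the 0.80 sanity bound and that ensemble
fusion's consistency benefit is visible, small enough to run in minutes on
one CPU.  `scripts/acceptance.py` runs the same study with 2 members.

## Numerical choices and known limitations

* float32 throughout the networks; losses accumulate reductions in
  float64.  Batch-norm statistics use one-pass einsum sums in float64.
* Compiled-kernel and numpy conv paths agree to float32 round-off but not
  bitwise; determinism holds within a path (the compiled path is used
  whenever a C compiler exists).
* Patch centers are rounded to the voxel grid after truncated-normal
  sampling, so the effective center law is the truncated normal quantized
  to the grid.
* The multi-view classifier re-extracts views per query voxel; neighbouring
  voxels share most of their views and a shared-extraction scheme would be
  faster (also noted as a limitation of the original implementation).
* `classify_masked_voxels` with an empty mask warns and returns an
  all-background map rather than raising, since an empty UNet foreground is
  a legitimate (if degenerate) pipeline state.
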