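# Methods

## Problem and model

`vesselseg` segments small blood vessels (apparent diameter of one to two
voxels) in 3D time-of-flight MR angiography volumes. Vessels are bright
tubular structures on a dark background; labels for such data are typically
produced semi-automatically and are noisy — they contain gaps and miss small
branches — so the training procedure is built to tolerate imperfect
supervision and to generalise from a handful of volumes.

The backbone is a modified 3D U-Net with multi-scale supervision (U-Net
MSS): four encoder levels of two (conv 3×3×3 → batch-norm → ReLU) blocks
followed by 2× max-pooling, channels doubling per level from
`base_channels`; a mirrored decoder with trilinear 2× upsampling and skip
concatenation; and 1×1×1 sigmoid heads on the last three decoder levels.
The two deeper heads are resampled to label resolution with
nearest-neighbour interpolation, so the loss sees three probability maps
ŷ₁..ŷ₃. With `supervision_taps=1` the model reduces to a plain U-Net,
which serves as the baseline comparator.

The per-map loss is the focal Tversky loss

    TI = (Σ p·g + ε) / (Σ p·g + α Σ (1−p)·g + β Σ p·(1−g) + ε)
    FTL = (1 − TI)^(1/γ)

with α = 0.7 (false-negative weight), β = 0.75 (false-positive weight),
γ = 4/3, ε = 1. The multi-scale loss is the α_i-weighted mean of the
per-tap FTLs with weights (1, 0.5, 0.25) from the full-resolution head
downward; it is invariant to rescaling the weights.

Training runs in two phases. Phase 1 minimises the multi-scale loss on
(patch, label) pairs. Phase 2 is a Siamese pass: each patch x and an
elastically deformed copy t(x) go through the same weights; the objective is

    L = L_MSS(f(x), y) + L_MSS(f(t(x)), t(y)) + FTL(f(t(x)), t(f(x)))

i.e. supervision on both branches plus a consistency term comparing the
deformed prediction of the clean branch (kept soft, no re-binarisation, no
stop-gradient — gradients flow through both branches and through the warp)
with the prediction of the deformed branch. This makes the network
approximately equivariant to elastic deformations rather than merely
augmenting the data with them.

## Elastic deformations

A deformation is a lattice of n³ random control-point displacements,
n drawn uniformly from {5, 6, 7}, each component uniform in
[−0.02, 0.02] in normalised coordinates (each axis spans [−1, 1], so 0.02
is 1% of the axis extent — about 0.6 voxels on a 64-voxel axis). The two
outermost control rings are locked to zero, so the deformation vanishes at
patch borders. The dense per-voxel field is the separable cubic-B-spline
interpolation of the lattice; warping is a backward map with trilinear (or
nearest) sampling and zero out-of-bounds reads (air background). Supervised
targets t(y) are warped trilinearly and re-binarised at 0.5; consistency
targets stay soft. One fresh transform is sampled per patch per iteration.

The interpretation of the 0.02 maximum displacement as a fraction of the
normalised axis extent (rather than voxels) is a design choice: the
magnitude is far too small to be meaningful in voxel units of the control
grid and matches the convention of kernel-transform implementations.

## Numerical backbone

The network, losses and warp run on a small reverse-mode automatic
differentiation module written on numpy (`vesselseg.autodiff`): elementwise
ops, reductions, sigmoid/ReLU, 3D convolution (computed as one matmul per
kernel offset over the contiguous padded volume), 2× max-pooling, separable
linear/nearest resampling, channel concatenation, batch normalisation, and
a trilinear backward warp differentiable with respect to the sampled image.
Every operator's analytic gradient is checked against central differences
in the test suite. Optimisation uses Adam (β₁ = 0.9, β₂ = 0.999) at the
reference learning rate 0.01. Training is deterministic given the seed on
a single-threaded CPU.

## Patching and inference

Patch grids enumerate origins on a per-axis stride lattice. Training and
validation grids use the bare lattice (for the reference geometry of
720×630×195 voxels, patch 64³ and strides 32/32/16 this yields 3402
patches per volume, hence 20 412 for six training volumes and 6804 for two
validation volumes). Inference grids append end-aligned origins so every
voxel is covered, and overlapping probabilities are averaged before
thresholding at 0.5 (the probability cutoff is configurable; averaging is
the variance-reducing convention). Volumes smaller than one patch are
zero-padded and cropped back. Each epoch samples training patches uniformly
without replacement, redrawn every epoch; the validation subset is a fixed
seeded uniform draw over the validation grid, frozen across epochs so the
curves are comparable. The checkpoint with the lowest validation loss is
kept (ties break to the earlier epoch); validation loss is supervised-only
in both phases so phase curves are mutually comparable.

## Evaluation

Dice and IoU on binary masks, with the convention that two empty masks
score 1 (a correct prediction of absence; this matters for vessel-free
slabs). IoU = Dice/(2 − Dice) holds exactly and is asserted. Slab-wise
Dice divides the sagittal axis into nine equal slabs for hypothesis
testing with a pooled-variance two-sample t-test (Welch variant available
via flag; degenerate zero-variance ties return p = 1 by convention).
Percent improvement between reported scores is 100·(new − old)/old to two
decimals. Qualitative views are maximum intensity projections and
MIP-space error overlays (red = false negative, blue = false positive,
white = true positive).

## Synthetic phantoms

The generator emulates the qualitative appearance of the target data, not
MR physics: seeded random-walk branching trees (bounded curvature, branch
probability 0.02 per 0.5-voxel step, radius tapering linearly from 2.5 to
1 voxel toward the leaves) rasterised as unions of balls, giving 2–7%
foreground — the sparsity regime of real angiography masks; intensity
background 0.1, vessels 0.8, boundary-smoothed. Corruptions: additive
Gaussian noise (σ = 0.05), a smooth multiplicative second-order polynomial
bias field (±20%), and optional global sinusoidal k-space-spike
interference. Label noise is emulated by deleting thin-branch chunks
totalling a requested fraction of the foreground and carving gaps along
remaining structures; the corrupted label is always a subset of the
original. What passing tests on phantoms do *not* show: performance on
real vessel geometry (tortuosity, kissing vessels, flow-related intensity
variation), real noise statistics, or real label-noise structure.

## Desk-scale study conditions

The reference end-to-end study (also what `scripts/acceptance.py` runs) is
sized for minutes on one CPU core: eight 96³ phantoms split 6 train /
1 validation / 1 test; training patches 16³ with stride 8; batch size 4;
240 training patches per epoch and a fixed 128-patch validation draw; ten
supervised epochs followed by five deformation-aware epochs at learning
rate 0.01; `base_channels = 8`; inference at the training patch size.

The per-epoch budget is deliberately large enough that the supervised
phase converges (monotonically decreasing validation loss) before the
Siamese phase starts. This matters because the consistency objective
compares *soft* probability maps: for two identical but diffuse maps the
Tversky index is far from 1 (the cross terms Σp(1−p) do not vanish), so
on an under-converged model the consistency gradient drags both branches
toward saturated agreement — gross over-segmentation — instead of
enforcing equivariance. Run phase 1 to convergence and the term behaves
as intended. Under the reference conditions the final model segments the
held-out phantom at Dice ≈ 0.95–0.98 across seeds, and the
deformation-aware phase improves the median test Dice rather than
degrading it.

Inference patch size matters: a network trained on 16³ patches degrades
when applied with much larger patches (the padded-convolution border
statistics it learned no longer hold), so the desk-scale study infers at
the training patch size. This mirrors the published observation that
inference patch size should track the training patch size and resolution.

## Numerical choices and degenerate inputs

- ε = 1 in the Tversky denominator (the smooth-Dice constant of the focal
  Tversky literature). A vanishing ε makes every vessel-free patch score
  FTL ≈ 1 regardless of the prediction, which swamps patch-averaged
  training and validation losses in sparse volumes and breaks checkpoint
  selection; ε = 1 gives empty-vs-empty patches a loss of 0.
- γ = 4/3, inside the admissible range [1, 3], the value the focal
  Tversky literature recommends; configurable.
- Min-max normalisation maps constant volumes to all zeros (background-only
  patches occur; avoids divide-by-zero).
- Best-checkpoint ties break to the earlier epoch.
- Batch reduction of all losses is the mean over samples; the Tversky sums
  pool voxels within one sample only.
- Weight init is Kaiming-normal from the run's seeded generator, so
  parameter counts depend only on the architecture and values only on the
  seed.

## Known limitations

- The phantom generator targets qualitative realism only; no inflow
  modelling, no vessel diameter distribution matched to anatomy.
- The numpy backbone is single-CPU and makes paper-scale training (64³
  patches, thousands of patches per epoch, 100 epochs) impractical; the
  architecture and objectives are the same at every scale, but reported
  desk-scale Dice values are for phantoms, not 7T MRA.
- Whether the consistency term should also be applied to the deeper
  supervision taps is undocumented in the source literature;
  full-resolution-only is implemented.
- The per-tap loss weights are not published; (1, 0.5, 0.25) emphasises
  the output head and is configurable.
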