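# Methods

## Problem setting

`cardioseg` trains multi-compartment segmentation networks for cardiac MR
images from a small labeled set Xl together with a larger unlabeled pool
Xu (with Xl ⊆ Xu). Four single-stage training strategies are implemented,
plus two-stage pseudo-label pipelines built from them:

* **SV** — supervised baseline. Per iteration, one labeled sample is
  drawn, augmented, and scored with a generalized Dice loss (GDL),
  `L = LSV`.
* **TC** — transformation consistency. One unlabeled sample `xu` is
  additionally drawn and a random transform TF sampled. The same network
  predicts on `xu` and on `TF(xu)`; the first prediction is warped by TF
  and, treated as a constant, serves as an MSE target for the second:
  `L = LSV + λ·LTC`.
* **STnoTC** — mean teacher without transforms. A teacher network, whose
  weights are an exponential moving average (EMA) of the student
  (`θT ← α·θT + (1−α)·θS` after every student update), predicts on the
  same input as the student; both run with dropout, which is the sole
  source of disagreement: `L = LSV + λ·LST`.
* **STTC** — mean teacher with transformation consistency. The student
  sees `TF(xu)`, the teacher sees `xu`; the teacher's prediction is
  warped by TF and used as the MSE target. Here the perturbation is the
  transform itself, so the teacher runs without dropout and its target is
  deterministic given its weights.

Pseudo-label (PL) pipelines train a stage-1 model, infer one hard
(arg-max) pseudo-label for **every** member of Xu — no filtering or
confidence selection — and train a freshly initialized stage-2 model on
the union of ground-truth and pseudo-labels. Per stage-2 iteration one
ground-truth-labeled and one pseudo-labeled sample are drawn (balanced
1:1), with GDL terms `LSV + λ1·LPL`; the cascaded variants (e.g.
STTC-PL-STTC) additionally keep a student-teacher consistency term on an
unlabeled draw, `LSV + λ1·LPL + λ2·LST`. Ground truth shadows the
pseudo-label wherever both exist.

All consistency/pseudo-label targets are gradient-detached: the autodiff
tape never propagates through a target branch, and teacher weights are
never touched by the optimizer.

## Backbone

A 4-level U-Net, identical in 2D and 3D: four contracting blocks (two
same-padded convolutions with kernel 3 per axis, an intermediate
element-wise dropout of rate 0.1, leaky ReLU slope 0.1 after each
convolution), factor-2 average pooling after each block, one
lowest-resolution block of the same form, and four expanding blocks each
preceded by factor-2 linear upsampling and concatenation of the matching
contracting features. A 1×1 convolution maps to the class channels,
followed by a voxel-wise softmax. There are no normalization layers.
With four pooling steps, input extents must be divisible by 16.

The paper-faithful width is 64 channels throughout; the desk profile uses
16. Weights are He-initialized; the classification head is initialized at
a tenth of the He scale so training starts from a near-uniform softmax
(see *Small-structure stability* below). The block count between the
paths is ambiguous in prose descriptions of this architecture family
("four blocks each" with pooling after every contracting block); the
lowest-resolution bridge block adopted here is the only arrangement in
which every skip connection finds a partner at its own resolution.

Because no deep-learning framework ships with the environment this
package targets, the backbone runs on a small reverse-mode autodiff
engine written on numpy (`cardioseg.autodiff`): convolutions are im2col +
BLAS matmuls, the input gradient of a same-padded stride-1 convolution is
the convolution with the channel-swapped spatially-flipped kernel, and
linear ×2 upsampling and its transpose are explicit gather/scatter
stencils (output sample 2i mixes inputs i−1, i with weights 0.25/0.75;
2i+1 mixes i, i+1). Gradient correctness is verified against central
finite differences in the test suite.

## Losses

**Generalized Dice loss.** `1 − 2·Σc wc Σv pcv·tcv / Σc wc Σv (pcv+tcv)`
with squared-reciprocal-volume class weights `wc = 1/(Σv tcv)²`, the
background class included. A class absent from the target would receive
infinite weight; it instead receives the largest finite class weight, so
it stays in the sums at the scale of the smallest present structure.
(An additive ε in the weight denominator was evaluated and rejected: it
makes an absent class's weight ~10⁸ times larger than the others' and
destabilizes training whenever augmentation warps a small structure off
the grid.) The loss is computed per sample; one labeled sample is drawn
per iteration.

**Consistency MSE.** Mean over all voxels and channels of squared
differences; the mean (rather than sum) normalization keeps the meaning
of λ independent of grid resolution. The target is detached inside the
loss, so stop-gradient semantics cannot be forgotten at a call site.

**Weights.** λ = 10 for TC/ST, λ1 = 1 and λ2 = 10 for the cascade, per
the full-scale configuration; all overridable.

## Schedules

Adam (β1 = 0.9, β2 = 0.999, ε = 1e−8) with exponential learning-rate
decay `lr(i) = lr0 · 0.1^(i/total)`. The unsupervised paths activate as a
hard switch at `switch_fraction` of the budget; the first phase is purely
supervised (the pseudo-label GDL term is a supervised component with
fixed targets and is active from iteration 0). For the student-teacher
strategies the teacher is created at the switch as a copy of the student
— an EMA from random weights would poison early targets — and follows
the EMA with α afterwards. The student is the model evaluated and
returned.

Full-scale profiles (`acdc2d`: 160², 180k iterations, lr0 1e−4/5e−5 for
SV-TC/ST-PL; `mmwhs3d`: 96³, 40k iterations) keep the published
constants with `switch_fraction = 0.5` and α = 0.999.

The desk profile (`desk2d`: 48², 16 channels, 1200 iterations) rescales
the schedule constants that are tied to the iteration budget:

* lr0 = 1e−3 for every strategy. The 2:1 SV:ST rate ratio of the
  full-scale setup was an empirical tuning in a saturated regime; at 1200
  iterations it would leave the ST variants' supervised warm-up
  undertrained relative to the SV baseline and confound the comparison.
* α = 0.99. The full-scale α = 0.999 has an EMA time constant of 1000
  iterations — appropriate for a 90k-iteration semi-supervised phase but
  effectively freezing the teacher at its initialization in a desk-scale
  run.
* `switch_fraction = 1/3`. The supervised phase converges within a few
  hundred iterations at this scale; the longer second phase gives the
  consistency and pseudo-label mechanisms room to act.
* `warmup_fraction = 0.1`: a linear learning-rate ramp over the first 10%
  of iterations (see below). Full-scale profiles use no warm-up.

## Small-structure stability

The combination GDL + softmax + Adam is bistable for small structures at
short budgets. Early in training the loss denominator's volume weighting
produces a large, sign-consistent gradient that pushes *every* foreground
class's probability down wherever other classes are already fitting; a
class only recovers once discriminative features for it have formed. If
suppression wins the race, the class's softmax mass underflows to exactly
zero in float32 and the gradient through the softmax vanishes — the
collapse is then permanent, while the total loss continues to decrease on
the remaining classes. Full-scale setups avoid this regime through wide
networks, long schedules, and the slice-exclusion rule that guarantees
minimum structure sizes.

Mitigations adopted (each reduces but does not eliminate the risk at desk
scale): the 0.1× head initialization (a strongly asymmetric initial
softmax accelerates the runaway; a fully zero head is worse — it creates
a symmetric trap — and was rejected after measurement), the
learning-rate warm-up ramp, and phantom geometry whose structures are
several pixels thick at the desk grid. A residual fraction of
(data, initialization) pairs still collapses one structure; because all
single-stage strategies share the identical supervised warm-up trajectory
under one seed, such collapses are common-mode for the strategy
comparison, but a cascade's stage-2 model rolls an independent
initialization. This is the dominant source of run-to-run variance in
the desk-scale experiments and is a property of the loss/optimizer
combination at this scale, not of the semi-supervision mechanisms.

## Augmentation

One `TransformSpec` freezes every random parameter of a draw so the same
warp can be re-applied to images, label maps (spatial part only, nearest
neighbor) and probability maps (spatial part only, linear, renormalized).
Spatial part: scaling, rotation and translation about the grid center
composed with an elastic deformation interpolated from a coarse node grid
(8 nodes per axis, cubic B-spline interpolation). Ranges at the 160-pixel
reference extent: translation ±20 px, rotation ±0.35 rad, per-axis size
change ±20 px (i.e. multiplicative factor 1 ± 20/extent — the natural
reading of a scaling range quoted in pixels), elastic maximum 15 px;
intensity shift ±0.2 and scale s in ±0.4 acting as the multiplier 1+s.
Pixel-valued ranges scale proportionally to smaller grids. Labeled
samples are augmented without elastic deformation; the unlabeled
consistency transform includes it. Warped images fill with the MR
intensity floor (−1, also the post-augmentation clamp), label maps with
background, probability maps with background probability 1; consistency
losses are computed over the full warped grid including fill.

## Preprocessing

Robust intensity normalization maps the 5th/95th intensity percentiles
per image to −1/+1 (affine in between, clamped below at −1 — the
percentile pair is the natural reading of a "map the 95th percentile to
−1 and 1 respectively" rule); Gaussian smoothing with σ = 1 grid unit;
center-aligned resampling (linear for images, nearest neighbor for
labels) to the profile grid. Integer class maps cannot be smoothed
directly; label smoothing smooths one-hot channels and re-argmaxes.
The cine slice materialization emits one 2D slice per (time, z), excludes
a slice position when any foreground class covers strictly less than
0.07% of the slice area in either annotated time step (equality retains),
takes labeled slices only from the two annotated time steps, and skips
patients whose out-of-plane orientation disagrees with the majority.

## Evaluation

DSC per class `2|y∩ŷ|/(|y|+|ŷ|)` in percent; ASSD as the symmetric mean
of nearest-boundary Euclidean distances in mm, with boundary voxels
defined by face adjacency (image border counts as outside) and distances
measured between boundary-voxel centers in physical coordinates via
exact Euclidean distance transforms. Foreground classes only. A class
empty in both masks scores DSC 100% / ASSD 0 (perfect agreement on
absence); empty in exactly one mask, its ASSD is undefined and reported
as NaN with a warning. Predictions are evaluated after linearly
resampling the probability channels to the original grid and spacing;
the ground truth is never resampled. Cross-validation aggregation:
per-(fold, sample) values are first averaged over repetitions; μ is the
grand mean of these, σ their sample standard deviation pooled across
folds, and the mean per-sample repetition spread is reported separately.

## The phantom generator

Analytic phantoms stand in for real cardiac MR: in cine mode, an
elliptical left-ventricle blood pool (class 3) enclosed by a myocardium
annulus (class 2) with an adjacent right-ventricle crescent (class 1) on
a consistent anatomical side (base direction −π/2, ±0.3 rad jitter);
in whole-heart mode, seven adjacent elliptical blobs. Each *patient*
draws one set of anatomy/contrast latents — radii, ellipse aspect
(0.80–0.95, area-preserving) and orientation (±0.6 rad), per-class
intensity means jittered ±0.10 around (0.15, 0.45, 0.30, 0.60) — and
contributes several samples that wander around those latents by 25% of
the population ranges, like time points of a cine acquisition. Images
are mean intensity per class plus Gaussian noise (σ 0.10), smoothed
(σ = 1) and robust-normalized. Labeling is granted per patient, so a low
labeled fraction means few labeled anatomies: the supervised baseline
undersamples the population while the unlabeled pool spans it — the
regime in which semi-supervision has something to contribute. Per-class
contrast variation was chosen as the main population axis deliberately:
it is the one realistic variation that the global intensity augmentation
cannot imitate.

What the phantom does **not** emulate: anisotropic voxels, slice
misalignment, bias fields, k-space artifacts, papillary muscles, through-
plane anatomy changes, inter-observer label noise. Passing desk-scale
tests therefore demonstrates the correctness and the qualitative behavior
of the training machinery, not clinical performance; the full-scale
profiles exist for real-data runs.

## Desk-scale experiment

The reference experiment (`cardioseg.experiments.ssl_comparison`, also
run by `scripts/acceptance.py`) uses 200 phantoms (50 patients × 4
samples) at 48², 5% of patients labeled, a held-out 20-phantom test set,
the desk schedule above, and 3 training seeds per variant; it reports
seed-averaged mean test DSC/ASSD for SV, STTC and STTC-PL-STTC. The
sizes were chosen to keep a full comparison within tens of minutes on a
single CPU with the numpy backbone. At this scale the pseudo-label
cascade shows the clearest gains over the supervised baseline; the pure
consistency margin is small and can be within seed noise of the baseline
— the mean-teacher mechanism is known to need long schedules, and the
desk budget is two orders of magnitude below the full-scale one.

## Known limitations

* The numpy backbone is single-image (no batching) and CPU-bound; the
  full-scale profiles are configuration presets, not a demonstrated
  capability of this implementation at that scale.
* Class collapse (above) makes individual desk-scale runs bimodal;
  conclusions should be drawn from multiple seeds.
* Checkpoints store raw parameter arrays with a JSON manifest; no
  optimizer state is persisted, so training cannot resume mid-stage.
* The elastic-deformation field is interpolated with cubic B-splines from
  the node grid; other interpolants would give slightly different warps
  for identical node draws.
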