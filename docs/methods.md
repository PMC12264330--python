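# Methods

## Problem setting

A SNAP acquisition yields seven intrinsically co-registered contrast channels
per voxel. Training labels (lumen / vessel wall / background) are contours
drawn on conventional multi-contrast MRI and registered onto the SNAP frame;
when registration fails, part of a contour misses the vessel. Each training
volume therefore carries a binary quality flag, and the learning problem is:
exploit the misaligned volumes instead of discarding them, without letting
their label errors corrupt the model.

## Training procedure

**Warm-up.** The student trains on well-registered volumes only, with the
multi-class Dice loss (mean of the binary Dice losses of the lumen and
vessel-wall channels; background is excluded because its Dice is dominated by
trivially correct voxels). The teacher is initialized as an exact copy of the
student and after *every* optimizer step — in both stages — is updated as
`θ_t ← α θ_t + (1−α) θ_s`. All teacher forward passes run without gradient
bookkeeping.

**Fine-tuning.** Per 8-slice training window:

1. student forward on the augmented image → `p_stu`;
2. teacher forward on the same image → `p_tea` (detached);
3. fitting target `ỹ`: the manual label for well-registered windows;
   for misaligned windows `ỹ = β y + (1−β) p_sel`, where `p_sel` hardens a
   voxel to one-hot iff the student and teacher argmax classes coincide and
   both maxima *strictly* exceed τ, else averages the two predictions.
   `ỹ` is built from detached arrays: no gradient flows through the teacher
   or the surrogate, which would otherwise make the target self-referential;
4. FGSM: `r_adv = ε · sign(∇_i CE(p(i, θ_s), ỹ))`, where CE is the
   *unweighted* voxel-mean cross-entropy. The gradient is taken on the
   augmented, unperturbed image — the same input the surrogate was computed
   on — and any parameter gradients accumulated by this extra backward pass
   are cleared before the training step;
5. student forward on `i + r_adv` → `p_adv`, scored by the class-weighted
   cross-entropy against `ỹ`;
6. one Adam step on (Dice + weighted CE), then one EMA update.

The perturbed image is not clipped or re-normalized: intensities are in
per-channel standardized units, so ε is measured in standard deviations.
`sign(0) = 0`, so flat input directions receive no perturbation.

The two cross-entropies are deliberately different functions: the attack uses
the plain CE, the Path-2 training loss uses class weights (2, 2, 1) to
counter the foreground/background imbalance. The weighted CE averages over
voxels (not over the weight mass). Soft targets are supported throughout; a
one-hot target is the special case.

## Hyperparameters

| name | default | meaning |
|---|---|---|
| α | 0.99 | EMA smoothing of the teacher |
| β | 0.5 | weight of the manual label in the surrogate |
| τ | 0.99 | confidence threshold for selective hardening (τ=1 disables hardening; strict `>` means ties at τ fall to the averaging branch) |
| ε | 4.0 | FGSM strength, in units of normalized intensity |
| w | (2, 2, 1) | CE class weights (lumen, wall, background) |
| lr | 2e-4 | Adam, weight decay 5e-4 (coupled L2 form) |
| schedule | ×0.9 / 500 iters | flat for the first 4000 iterations, decay counted from there (first reduction at 4500) |
| batch | 4 | windows per iteration (8 × 224 × 224 at clinical scale) |

Checkpoint selection maximizes validation `DSCavg` (mean of lumen and
outer-wall DSC), computed with the same fused student+teacher inference used
at test time — consistency between selection and deployment was preferred
over selecting on the student alone. Validation runs every `val_interval`
fine-tuning iterations (default 100).

## Backbone

A configurable 3D U-Net: two conv(3³)–GroupNorm–ReLU units per resolution
level, 2×2×2 average-pool downsampling, nearest-neighbour upsampling with
skip concatenation, and a 1×1×1 convolution into a 3-way softmax.
Pooling/nearest resampling was chosen over strided and transposed
convolutions because their gradients are exact, cheap and simple in the
package's hand-written NumPy engine (`snapseg.nn`), and the framework — not
the backbone — is the subject here; every comparison in the package runs on
this same backbone. GroupNorm uses the largest group count ≤ 8 dividing the
channel width; all parameters, including the affine normalization parameters,
participate in the EMA. Initialization is He-scaled Gaussian from a seeded
generator, so two builds with one seed are bit-identical. Defaults: depth 4 /
16 base channels at clinical scale, depth 2 / 8 channels for desk-scale
experiments.

The engine computes convolutions by explicit patch-matrix multiplication and
hand-derived backward passes; backprop to the *input* is what supplies the
FGSM gradient. Activations are float32; losses and their gradients are
evaluated in float64. All gradients are verified against central differences
in the test suite.

## Windows and inference

Training samples a uniformly random run of 8 consecutive slices per volume.
At inference a volume of N ∈ [8, 16] slices is covered by the windows at
starts 0 and N−8 (one window when N = 8); student and teacher probability
maps are averaged per window, slices covered twice get the mean of their two
fused maps, and voxels take the argmax class, ties resolved toward the lower
channel index. Volumes with N > 16 are rejected by default; a permissive mode
tiles them at stride 8 plus a final flush window, since the two-window rule
cannot cover them.

## Augmentation

One draw per window, applied identically to every slice (and to the label for
the geometric part): rotation from {0°, 90°, 180°, 270°}, horizontal flip
with probability 0.5, multiplicative contrast in [0.8, 1.2], gamma in
[0.8, 1.2] applied per channel on min-max-rescaled intensities. Order:
rotation → flip → contrast → gamma; the FGSM perturbation is computed after
augmentation.

## Losses: numerical choices

* Dice smoothing `s = 1e-5` in numerator and denominator defines the
  empty–empty case as loss 0.
* Probabilities are clamped to `[1e-7, 1]` inside logarithms; the clamp's
  gradient is zero below the floor.
* Dice is computed jointly over all voxels of a window (3D), not averaged
  per slice.

## Evaluation

DSC is reported in percent; both-empty masks score 100 (perfect agreement on
absence), one-empty pairs 0. Boundary voxels are foreground voxels with at
least one face-adjacent non-foreground neighbour *within their slice*
(in-plane 4-connectivity); distances between boundaries are Euclidean in 3D
with physical voxel spacing. HD95 and ASD are the 95th percentile and mean of
the pooled symmetric nearest-distance set (both directions pooled before
reduction — conventions differ across the literature; the pooled form is
oracle-tested against exhaustive all-pairs distances). The outer-wall mask is
lumen ∪ wall, the region enclosed by the outer boundary. Distances involving
an empty mask are reported as missing and excluded from aggregation, which is
per volume. Multi-method comparison uses Tukey's HSD (family-wise error 5%)
via statsmodels.

## Synthetic phantoms

Each phantom is a tube: per slice, voxels within `lumen_radius` of a
sinusoidally drifting centerline are lumen, the annulus up to `wall_radius`
is wall. Channel intensities are Gaussian around per-class, per-channel means
(noise SD 0.5 against class separations of order 1); the default 3×7 mean
matrix makes some channels discriminative, one ambiguous between lumen and
wall, and two nearly uninformative, mimicking how real contrast channels vary
in usefulness. Cohorts vary radii (±20%), wall thickness, centerline
amplitude and phase per volume.

Label corruption emulates misregistration in two modes: `slice_shift`
translates whole label slices rigidly; `sector_displace` (default) moves only
the contour points whose polar angle about the slice centroid falls in a
given sector, then re-rasterizes both region polygons (outer region painted
as wall first, lumen on top, guaranteeing a valid one-hot topology). By
default roughly half the slices of a misaligned volume are affected. Typical
misregistration magnitude in voxels is not well characterized; the default —
3 voxels over a 120° sector — is a stand-in chosen to clearly displace part
of the boundary while leaving most of it correct.

What the phantoms do *not* model: bifurcations, plaque components and their
intensity heterogeneity, MR physics (bias fields, flow artifacts), inter-
channel noise correlation, and anisotropic partial-volume effects. Passing
the end-to-end study therefore shows the training machinery behaves as
designed under controlled label noise — not that clinical-grade accuracy
would be reached on patient data.

## Desk-scale study sizes

The end-to-end robustness study in the test suite and in
`scripts/acceptance.py` runs at the package's desk scale, chosen so the whole
suite completes comfortably on one CPU core: 8×32×32 phantoms, 12 clean + 12
misaligned training volumes, 6 validation, 6 clean test; depth-2 / 8-channel
backbone; batch 2; 150 warm-up + 150 fine-tuning iterations (lr decay every
50 from iteration 150, validation every 50); three training seeds, medians
reported. The study arms are: full framework, baseline (adversarial branch
disabled), surrogate without hardening, and the full framework trained with
misaligned volumes excluded.

At this scale the full framework and the soft-surrogate ablation are
statistically tied: selective hardening requires both models to exceed
τ = 0.99 confidence, which a 300-iteration model reaches on few voxels. The
hardening step's specific contribution only becomes visible with longer
schedules; the desk-scale study demonstrates the ordering of the ladder's
ends (full vs. baseline) and the value of keeping misaligned data.

## Known limitations

* The NumPy engine holds per-layer patch matrices for backprop; memory grows
  with window area and channel width (fine at desk scale, a few hundred MB at
  clinical scale).
* Checkpoints store the full student+teacher state as `.npz`; optimizer and
  RNG state are not checkpointed, so training is restartable only from
  iteration 0.
* `compare_methods` assumes per-volume DSC values are exchangeable across
  methods; it does not model per-volume pairing.
* The corruption model displaces contours but never changes topology (no
  missing slices, no spurious components).
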