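# Methods

## Problem and scope

`ctvseg` implements a lightweight multi-phase segmentation method for
the postoperative pelvic clinical target volume (CTV) on paired CT:
a non-contrast phase (NECT, the planning image) and a contrast-enhanced
phase (CECT, which makes the iliac vessels that anchor the CTV boundary
visible).  The package covers the full method: the two-branch
bottleneck U-shape network, the boundary-aware multi-phase loss, the
evaluation suite (DSC, voxel-set ASSD, contour-band Dice), the
preprocessing/augmentation chain, a training loop, and a synthetic
two-phase phantom generator that supplies fully specified desk-scale
data in place of clinical images.

## Model

Each phase is processed by its own U-shape feature extractor
(Branch-N, Branch-C).  An extractor has a full-resolution stem
convolution unit followed by five downsampling stages with channel
widths 32, 64, 128, 256, 320; each stage holds two convolution units
(convolution + instance normalization + leaky rectifier, slope 0.01),
the first carrying the stage stride.  The decoder mirrors the encoder
with non-overlapping transposed convolutions (kernel = stride) and
concatenation skips, ending at 32 channels at input resolution.

Stage strides are pinned to (1,2,2), (1,2,2), (2,2,2), (2,2,2),
(2,2,2): the 5 mm slice axis is pooled less than the 1 mm in-plane
axes, so a (40, 224, 192) patch reaches a deepest feature grid of
(5, 7, 6).

**Bottleneck rule.**  Every convolution unit whose *input* channel
count exceeds 32 is replaced by a three-layer bottleneck: a 1×1×1
compression to `c/8` channels, a 3×3×3 convolution at the compressed
width (carrying any stride), and a 1×1×1 restoration to `c_out`, each
followed by instance norm + leaky rectifier.  Its weight count is

    c·(c/8) + (c/8)²·27 + (c/8)·c_out

versus `c·c_out·27` for the plain unit — a reduction of 1728/43 ≈ 40×
at `c_out = c`, independent of `c`.  First-stage units (32 input
channels) stay plain; decoder units obey the same rule after skip
concatenation.  Biases exist on all convolutions and are counted
separately from the closed-form weight formulas.

**Fusion.**  The two 32-channel feature maps are concatenated and
passed through a hidden convolution unit, then two single-channel
score maps; a two-way softmax across the phases yields spatial
attention weights, and the attention-weighted feature sum is refined
by one convolution unit before the fused head.  The hidden width is
the one width the architecture leaves open; it is pinned to 1344 so
that the standard two-branch 3-D model totals 5,694,917 trainable
parameters (5.7 M to one decimal).  This makes the fusion module
parameter-heavy — consistent with the mutual-learning fusion designs
this module descends from — and dominates the FLOP count, which is why
the analytic FLOP figure of the full model is well above that of the
extractors alone.  The counted FLOP convention is 2 FLOPs per
convolution multiply-accumulate; bias, normalization and activation
arithmetic are excluded.

Three 1×1×1 sigmoid heads produce probability maps from the N-branch
features, the C-branch features and the fused features.  In
single-extractor mode (single-phase training) only one head exists and
is carried in the fused slot; absent heads are `None`, never
zero-filled.  Weights use seeded Kaiming initialization (fan-in,
leaky-rectifier gain).

**Numerical backend.**  The network, its gradients and the optimizer
run on a compact reverse-mode automatic-differentiation engine over
NumPy arrays (`ctvseg.autodiff`).  Convolutions are evaluated by
kernel-offset loops with einsum reductions; gradients of every
operator are validated against central finite differences in the test
suite.

## Loss

Let `G` be the ground-truth mask, `F` its foreground and `B = G − F`.
Exact Euclidean distance transforms give `d_fg` (foreground voxels to
the nearest background voxel, zero on background) and `d_bg` (the
reverse).  Both fields are reversed (max − d) and normalized to [0, 1];
their sum is the distance-penalty weight

    w = 2 − d_fg / max(d_fg) − d_bg / max(d_bg),

which peaks at the foreground/background interface and decays into the
interior of both regions.  The per-head loss is

    (1 − 2·Σ w·p·q / (Σp + Σq + ε)) + BCE(p, q),

summed over the available heads with equal weight; the weights enter
the Dice numerator only.  The weighted Dice similarity can exceed 1
when boundary weights dominate, so the loss can be slightly negative;
it is bounded below by −2 per head.  The objective is sometimes
written additively as the Dice *similarity* plus cross-entropy;
minimizing that form verbatim would reward low overlap, so the package
implements the sign-corrected `1 − term` and keeps the uncorrected
form behind a documentation-only flag.

Numerical choices: Dice smoothing ε = 1e-5; BCE probability clamp
1e-7.  Distances are computed in physical millimetres using the voxel
spacing (voxel-unit mode is kept for tests).  Degenerate masks (empty
foreground or background after cropping) fall back to uniform w = 1
with a warning, recovering the unpenalized loss.  Weights are
recomputed from the mask of each augmented, cropped patch rather than
warped, because recomputation is exact.  The penalty is applied to all
three heads (toggleable).

## Preprocessing and augmentation

Intensities are truncated to the 0.5th/99.5th percentiles of the
pooled training-set distribution and z-scored with the mean/std of the
clipped training intensities (truncation alone would leave the scale
arbitrary).  The statistics are computed once, persisted as a
key-value text file next to checkpoints, and reused at inference.
Volumes are resampled to (5, 1, 1) mm (linear for images, nearest for
masks).  Training samples receive per-axis random flips (probability
0.5, the conventional choice), rotations drawn uniformly from ±15°
about the z, y, x axes in that order, and a random crop to the fixed
patch size; evaluation uses a centre crop.  One shared geometric
transform applies to both phases and the mask; the mask is re-binarized
after nearest-neighbour interpolation.

## Training

SGD with momentum 0.95; learning rate 0.01 decaying linearly to zero
(`lr0 · (1 − epoch/epochs)`); batch size 2; 200 epochs × 250
iterations at full scale.  Cases are sampled uniformly with
replacement.  The checkpoint with the best validation DSC of the fused
head (threshold 0.5) is kept; when no validation split exists the
final weights are returned.  All randomness derives from the single
config seed, so loss traces are bit-reproducible.

Desk-scale presets keep every structural rule at test-suite cost:
`NCLNetConfig.desk()` (widths 8–80, bottleneck threshold 8) and
`NCLNetConfig.tiny()` (three stages, widths 4/8/16, threshold 4,
compression 4) with matching `TrainConfig.desk()` (20 epochs × 20
iterations, 16×64×64 patches).  The optimization sanity check trains
the tiny model for 300 iterations on one 8×32×32 phantom with
augmentation disabled and reaches a fused-head training DSC above
0.95; the directional comparison of fusion and distance penalty runs
6 phantoms × 2 seeds × 3 epochs × 12 iterations in the suite (a
reduced edition of the study in `examples/ablation_echo.py`), and its
directions are reported rather than hard-asserted because at that
scale run-to-run noise can exceed the effect size.

## Evaluation metrics

* **DSC** — volumetric overlap `2|P∩G|/(|P|+|G|)`; both masks empty
  scores 1, exactly one empty scores 0 (pinned convention).
* **ASD/ASSD** — implemented literally in voxel-set form: the directed
  term averages, over *all* foreground voxels of one mask, the minimum
  physical distance to the other mask's foreground; ASSD is the mean
  of the two directed terms.  The conventional surface-restricted
  variant is available behind `surface=True`; the voxel-set form is
  the default, matching the definition above.
* **CDSC** — per axial slice, the inner contour band of each mask
  (mask pixels whose 2-D Euclidean distance to the background is at
  most the thickness, i.e. the mask minus its erosion at that radius;
  the slice border counts as background) is computed for prediction
  and ground truth; the 2-D Dice of the two bands is averaged over
  slices.  Slices empty in both bands are skipped; a one-sided-empty
  slice scores 0.  Thicknesses 2–9 mm are reported by default.  The
  band is pinned one-sided-inner since it is generated from each mask
  by its own distance field; a symmetric band would be a reasonable
  alternative and the laterality is the main open choice here.
* **Metric–time correlation** — the sample Pearson coefficient between
  per-case metric values and clinical modification times.

## Phantom generator

The phantom defines the desk-scale study conditions.  The target is a
tapered elliptical tube along the slice axis with a smooth centre
drift; at full scale its length is drawn from 160–200 mm and its
volume from 450–900 cm³ — within the ranges real postoperative pelvic
CTVs span — on a 40×224×192 grid at (5, 1, 1) mm.  The non-contrast
phase is background (30) plus a low offset (25) inside the
edge-blurred target, a smooth low-frequency field (amplitude 10,
correlation length 40 mm) and white noise (sd 15) — deliberately low
target contrast, in abstract units standing in for HU.  Vessels are
constant-radius (1.5 mm) tubes whose centrelines ride a shell 2–6 mm
inside the target surface; their intensity offset (200) is added in
the contrast phase only, so setting it to zero makes the phases
bit-identical — the control that ties any two-branch gain to the
contrast-only signal.

What the phantom does *not* emulate: anatomy (organs, bone, bladder or
rectal filling), CT physics (beam hardening, contrast kinetics),
inter-observer contour variability, and multi-structure context.
Passing tests therefore demonstrate that the implementation learns and
measures what it claims on data with the assumed structure — not
clinical-grade performance.

## Known limitations

* The fusion module's internals are the main source of architectural
  uncertainty; only its hidden width is calibrated (to the published
  total parameter count), and the counted FLOPs depend strongly on it.
* The NumPy backend is single-threaded-friendly and exact but slow;
  full-scale (40×224×192) training is not practical with it, which is
  why all empirical checks run at desk scale.
* The voxel-set ASSD differs from the surface ASSD on masks with
  interior volume; comparisons against surface-based implementations
  should use the `surface=True` variant.
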