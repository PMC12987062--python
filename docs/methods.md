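# Methods

This package reconstructs coherent, high-resolution 3D whole-heart label
volumes from the kind of segmentation stacks routine cardiac MR produces:
slices displaced against each other by respiratory motion, thick-slice
sampling along the scanner axis, and segmentation noise.  Everything
operates in the *label domain* — voxel grids of anatomical class IDs
(background, LV, RV, LA, RA, myocardium, aorta, pulmonary artery) — never on
image intensities.

## Degradation model

The simulator `cardiorecon.degrade` maps a clean volume to an
acquisition-like stack by composing, in acquisition order:

1. **Slice misalignment.** Each 2D slice is independently displaced with
   probability `misalign_prob` by an in-plane rigid transform with
   translation drawn uniformly from ±`translation_range` voxels per axis and
   rotation from ±`rotation_range` degrees about the slice center.
   Resampling is nearest-neighbour (labels stay categorical) and content
   shifted past the border becomes background.
2. **Label noise.** Per slice: with probability `boundary_perturb_prob` one
   present foreground class is dilated or eroded by a disk of
   `boundary_perturb_radius` voxels inside a random sub-window (morphology
   runs on a radius-expanded context window so window borders cannot act as
   fake boundaries); additionally a Poisson(`speckle_blob_rate`) number of
   small disks is flipped to random foreground classes.
3. **Through-plane decimation.** Slices with index ≡ `z_phase` (mod
   `z_factor`) are kept and the z spacing multiplied accordingly.  The
   default `z_factor=2, z_phase=0` corresponds to removing every second
   slice of a 1-based clinical numbering.

Every realized transform and noise event is logged in a
`DegradationRecord`; the record alone re-applies an identical misalignment
to any same-shape volume, and a neutral configuration is the bit-exact
identity at every stage.

Severity presets (unitless probabilities, voxels, degrees):

| level  | translation | rotation | p(misalign) | boundary p/r | speckle rate/r |
|--------|-------------|----------|-------------|--------------|----------------|
| easy   | 1           | 0        | 0.3         | 0 / 1        | 0 / 1          |
| medium | 3           | 2        | 0.6         | 0.2 / 1      | 0.2 / 1        |
| hard   | 6           | 5        | 0.9         | 0.4 / 2      | 0.5 / 2        |

No published quantification of clinical misalignment magnitudes is encoded
here; the presets are this package's own declaration, chosen to span
sub-voxel breathing drift up to gross slice displacement, and every value is
overridable.  They are componentwise monotone, so severity-ordered
properties (curvature inflation, correction benefit) are well-posed.

## Motion correction: shape-prior autoencoder

Correction is cast as projection onto a learned manifold of plausible
anatomy rather than slice registration.  A 3D convolutional autoencoder
consumes the one-hot label field (C+1 = 8 channels).  All pooling and
upsampling is **anisotropic**, kernel (1, 2, 2): two pooling stages compress
the in-plane axes by 4 while the slice axis is never pooled.  The code — the
*latent volume map* — has shape `(64, D, H/4, W/4)`: it keeps every slice
addressable (the slice-wise progression of anatomy is exactly what motion
corrupts) while in-plane compression forces the encoder to drop
high-frequency boundary jitter.

Default architecture (configurable via `DSLModelConfig`): encoder
conv(3³)+InstanceNorm+ReLU+pool at widths (8, 16), then a 64-channel latent
conv; decoder mirrors with nearest (1,2,2) upsampling, one full-resolution
refinement conv, and a zero-initialized logits conv.  Two choices matter on
CPU-scale problems and were made after observing training dynamics:

- **Instance normalization** after every hidden conv.  With ~80–95 %
  background voxels the combined loss initially rewards predicting
  background everywhere; an unnormalized network saturates its softmax in
  that state and gradients die.  Normalization bounds the logits and keeps
  the minority classes learnable.
- **Zero-initialized final logits**, so training starts from uniform class
  probabilities instead of a random, quickly-saturating state.
- **An input-residual path**: the full correction pass computes
  `softmax(decoder(encoder(x)) + β·x)` with a learnable scalar β (counted
  with the decoder parameters, so the finetune freeze covers it).  Without
  it the two smallest structures — the vessels, a few hundred voxels each —
  lose the softmax competition at the start of training and never recover,
  at any tested width or epoch budget at this problem size; with it,
  training starts from a scaled copy of the input (every structure present)
  and the autoencoder path learns the correction on top.  The pure
  encode/decode operations (latent volume map in, probabilities out) remain
  available without the skip and keep their shape contracts.

The loss is the weighted sum `λ1·L_L1 + λ2·L_Dice` with `λ1 = λ2 = 0.5`:
the L1 term is the mean over voxels of the channelwise absolute difference;
the Dice term pools intersections and squared norms over all classes and
voxels into a single fraction with a squared denominator and stability
constant ε = 1e-5.  Note the pooled form is background-dominated, which is
the root of the saturation behaviour above.

**Transfer protocol.** Pretraining pairs a clean cohort with freshly
degraded copies — a new degradation is drawn for every case every epoch, so
the corruption acts as augmentation and the manifold is learned from clean
geometry only.  Because the degraded stack has fewer slices than its target,
it is re-expanded to target depth by nearest z-repetition before entering
the network (the same expansion a viewer applies to a thick-slice stack);
input and reconstruction target then share one shape.  Finetuning on
target-domain (input, target) pairs updates **only the encoder** — the
decoder is frozen bit-exactly — so the output distribution stays on the
pretrained shape manifold while the encoder adapts to the new input
statistics.  Finetuning applies no synthetic degradation.

## Through-plane super-resolution: implicit label field

The SR stage (`cardiorecon.superres`) lifts an aligned LR stack by an
integer factor `s_z` along z.  Target voxels are indexed by normalized
coordinates in [−1, 1]³ with the voxel-center convention: index `i` on an
axis of length `n` maps to `−1 + 2i/(n−1)` (length-1 axes map to 0).  The
same convention drives all three ingredients, which makes "sample the LR
grid at its own centers" an exact identity:

1. trilinear **anchors**: the LR one-hot field sampled at each target
   coordinate (convex weights keep anchors on the probability simplex);
2. an **implicit feature field**: a pointwise MLP on `[z, y, x, anchors]`
   (input width C+3), hidden widths (32, 32), producing C′ = 8 features per
   voxel — evaluated in chunks whose size provably cannot affect results;
3. the **explicit branch**: the LR field linearly interpolated along z only,
   preserving input topology.

A shallow fusion convnet (3³ convs, widths (12, 12), instance-normalized,
zero-initialized logits) consumes `concat(explicit, features)` and emits
per-class logits, to which a residual `β · explicit` is added (learnable
scalar, initialized so training starts exactly at explicit-interpolation
quality with every structure present — the same small-structure rationale
as the corrector's input residual).  Argmax of the softmax gives the HR
labels with depth exactly `s_z · D_lr`.  Training follows degradation-reconstruction: each
step draws `s` from the training scale set {2, 3, 4}, decimates a clean HR
volume by `s`, and supervises against the original (predictions cropped to
the target depth when `s` does not divide it).  Finetuning uses
differential learning rates — the MLP at `lr × multiplier` (default 0.1),
the fusion net at full rate; multiplier 0 leaves the representation path
bit-identical and multiplier 1 is exactly uniform finetuning.  Non-integer
or untrained scales are rejected: the field is continuous but the training
scheme is not resolution-agnostic.

## Geometry metrics

`cardiorecon.metrics` pins the following conventions:

- **Surface area** sums the physical areas of voxel faces separating
  foreground from background; faces on the volume border count (the mask is
  conceptually padded with background).  The alternative silently shrinks
  areas at crop borders.
- **Mean curvature intensity** κ̄ = S/V (1/mm).  For a fixed physical shape
  κ̄ is stable under rediscretization, while stair-step artifacts inflate S
  at fixed V, so κ̄ tracks boundary jaggedness.  The **curvature variation
  rate** Rκ = |κ̄_post − κ̄_pre| / κ̄_pre quantifies how much a correction
  changed boundary complexity; it is reported per class and as a class mean.
- **HD95 / ASSD** operate on boundary-voxel center point sets (face
  connectivity against background, border exposed), pool directed
  nearest-neighbour distances over both directions, and take the 95th
  percentile (linear interpolation between order statistics) and the mean
  respectively.  Anisotropic spacing is respected by working in physical
  coordinates.
- **Dice** is per foreground class; classes absent from both volumes are
  excluded from the mean rather than scored 1, so phantoms missing a
  structure do not inflate averages.
- "Ventricular classes" in the recovery analyses means the ventricle
  chambers (LV, RV).  The myocardium is a thin-walled tissue whose κ̄
  behaves differently (a 2-voxel shell reconstructs rough at desk scale)
  and is reported per class rather than folded into the ventricular mean.

## Synthetic phantoms and what they do (not) show

`cardiorecon.phantom` builds 8-class whole-heart-like volumes from
analytically defined ellipsoids and tube polylines: LV enclosed by a
myocardial shell (grown by 6-connected dilation, so enclosure is exact by
construction) with a basal opening, RV/LA/RA carved against previously
placed structures, and curved AO/PA tubes.  Placement precedence LV/Myo →
RV → LA/RA → AO/PA means later structures can never break the enclosure
invariant; each draw is validated (presence, single 6-connected component
per class, enclosure) and resampled on failure.  Myocardial shells need
thickness ≥ 2 voxels to stay 6-connected on coarse grids.

The phantoms reproduce the *geometric regime* of the problem — nested
shells, adjacent chambers, thin vessels, anisotropic voxels — but none of
the morphological variability, trabeculation, or pathology of real anatomy,
and no intensity information.  Passing the recovery experiments therefore
demonstrates that the pipeline can learn and exploit a shape prior under
controlled corruption; it does not certify clinical performance.

## Problem sizes and training settings

The package's study configuration (the `PipelineConfig` defaults) is
deliberately desk-scale: phantoms on a 32×64×64 grid at (2, 1, 1) mm,
cropped to a 28×48×48 window centered on the cardiac region (the same
crop-to-heart preprocessing the clinical workflow uses; the window is tall
enough to keep the vessels intact), 30 pretraining / 5 finetuning / 10
held-out test cases, medium severity.  Optimization is Adam; `TrainConfig`
defaults to the reference setting lr = 1e-4 with λ1 = λ2 = 0.5, while the
desk-scale runs use lr = 3e-3 and a few tens of epochs (45 for the
corrector; 24 plus an 8-epoch settling phase at 1e-3 for the SR stage,
whose held-out score otherwise oscillates with the high rate) — at these
problem sizes the larger step size converges in minutes on one CPU, and
loss curves are recorded in every results object.  Label smoothing 0.05 is
on in the study configuration.  All randomness flows from a single master
seed through named child streams (phantom sampling, per-epoch degradations,
parameter initialization, scale sampling), so every experiment is
bit-reproducible.

## Known limitations

- The networks run on a NumPy layer substrate written for this package
  (float32, batch size one, explicit backprop, Adam); it is exact (gradient
  checked against finite differences) but not fast, which bounds feasible
  problem sizes.
- The pooled Dice term makes small structures (vessels) the last to be
  learned; under-trained models lose them entirely.  Training long enough
  for all seven structures is the main cost driver.
- The corrector assumes the input label topology is roughly right; missing
  structures are not hallucinated back (by design).
- Super-resolution is restricted to the trained integer scale set.
- Rigid per-slice motion only; no non-rigid deformation model.
- The encoder is deterministic.  A variational treatment (a distribution
  over latent volume maps) would enable sampling plausible corrections but
  adds nothing to the point estimates evaluated here.
- The myocardial shell's curvature intensity typically *rises* slightly
  after correction at this problem size even as its Dice improves — the
  corrected shell is accurate but voxel-rough.  The ventricle chambers and
  atria show the expected curvature reduction.
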