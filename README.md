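# cardiorecon

**Label-domain whole-heart reconstruction**: turn sparse, motion-corrupted
cardiac segmentation stacks into anatomically coherent, high-resolution 3D
label volumes.

Routine cardiac MR is acquired slice by slice over multiple breath-holds:
adjacent slices end up displaced against each other (stair-step artifacts),
the through-plane resolution is several times coarser than in-plane, and
automatic segmentations add their own boundary noise.  Meshes built from
such stacks are useless for downstream work (flow simulation,
electrophysiology, surgical planning).  `cardiorecon` repairs the *label
maps* directly, in two trainable stages:

1. **Motion correction** — a 3D convolutional autoencoder with anisotropic
   (1, 2, 2) pooling.  Its code, the *latent volume map*
   `Z ∈ R^{64 × D × H/4 × W/4}`, preserves every slice while compressing
   in-plane detail, so reconstruction through it projects a corrupted stack
   onto a learned manifold of plausible hearts: `X̂ = D_θ(E_φ(X̃))`.  The
   prior is learned from clean volumes paired with synthetically degraded
   copies; transfer to a target domain updates only the encoder while the
   decoder stays frozen.
2. **Through-plane super-resolution** — an implicit neural representation:
   for each target voxel at normalized coordinate `(z, y, x) ∈ [−1,1]³` a
   small MLP embeds `[z, y, x, trilinear anchors]` into a continuous feature
   field, which a shallow fusion network combines with an explicitly
   z-interpolated label tensor to produce class probabilities at any integer
   scale ×2/×3/×4.

Both stages minimize `λ1·L_L1 + λ2·L_Dice` (λ1 = λ2 = 0.5) on probability
fields.  Around them the package provides a **degradation simulator**
(slice-wise rigid misalignment, label noise, z-decimation — with a full
reproducibility record per realization), a **phantom generator** (8-class
whole-heart-like geometry: LV enclosed by myocardium, RV/LA/RA, aorta and
pulmonary artery), and **geometry metrics**: Dice, HD95, ASSD, and the mean
curvature intensity κ̄ = S(Ω)/V(Ω) (surface-to-volume ratio, 1/mm) whose
relative change Rκ = |κ̄_post − κ̄_pre| / κ̄_pre quantifies how much a
correction smoothed motion-inflated boundaries.

Everything runs on plain NumPy/SciPy — the neural layers are a small,
gradient-checked substrate inside the package — so the full study executes
on one CPU in minutes.

## Worked example

```python
import numpy as np
from cardiorecon.phantom import PhantomParams, generate_phantom
from cardiorecon.io import crop_or_pad, upsample_z_repeat, LabelVolume
from cardiorecon.degrade import severity_preset, degrade
from cardiorecon.motion import MotionCorrectionModel
from cardiorecon.train import TrainConfig
from cardiorecon.metrics import dice_coefficient, evaluate_case

rng = np.random.default_rng(0)
params = PhantomParams.desk_scale()
cohort = [crop_or_pad(generate_phantom(params, rng), (28, 48, 48))
          for _ in range(12)]
train, test = cohort[:10], cohort[10:]

model = MotionCorrectionModel(train, degradation="medium", seed=0)
results = model.fit(TrainConfig(epochs=30, lr=3e-3, label_smoothing=0.05))
print(results.summary())

clean = test[0]
lr, record = degrade(clean, severity_preset("medium"),
                     np.random.default_rng(1))
degraded = upsample_z_repeat(lr, 2)
degraded = LabelVolume(degraded.voxels[:clean.shape[0]],
                       spacing=degraded.spacing)
corrected = results.correct(degraded)
print("Dice degraded :", round(dice_coefficient(degraded, clean)[1], 3))
print("Dice corrected:", round(dice_coefficient(corrected, clean)[1], 3))
print("mean R_kappa  :",
      round(evaluate_case(corrected, clean, pre=degraded).r_kappa_mean, 3))
```

Output (one CPU, a few minutes):

```
motion-correction pretrain training results
========================================
cases:        10
epochs:       30
optimizer:    Adam (lr=0.003)
loss weights: l1=0.5, dice=0.5
initial loss: 0.13900 (l1=0.23496, dice=0.04304)
final loss:   0.05021 (l1=0.07698, dice=0.02345)

degradation severity: medium
Dice degraded : 0.805
Dice corrected: 0.829
mean R_kappa  : 0.048
```

The degraded stack (every second slice dropped, slices displaced by up to
3 voxels) overlaps the clean truth at mean Dice ≈ 0.80; projecting it
through the learned shape prior recovers ≈ 0.83, and the corrected surfaces
changed curvature intensity by ≈ 5 % relative to the corrupted input.

The command line mirrors the stages:

```bash
cardiorecon simulate --n 10 --out runs/sim --severity medium
cardiorecon demo                  # full pipeline on a synthetic cohort
cardiorecon ablate                # SR with vs without motion correction
cardiorecon severity              # curvature response across severities
cardiorecon evaluate --pred p.nii.gz --gt g.nii.gz --out report.csv
```

## Layout

| module                  | contents                                            |
|-------------------------|-----------------------------------------------------|
| `cardiorecon.io`        | `LabelVolume` / `ProbabilityVolume`, NIfTI I/O, one-hot, crop/pad, resampling |
| `cardiorecon.phantom`   | whole-heart label phantoms and dataset manifests    |
| `cardiorecon.degrade`   | the stochastic degradation operator and its records |
| `cardiorecon.motion`    | shape-prior autoencoder, pretrain/finetune/correct  |
| `cardiorecon.superres`  | implicit-field z-axis super-resolution              |
| `cardiorecon.metrics`   | Dice, HD95, ASSD, κ̄, Rκ, correlations              |
| `cardiorecon.pipeline`  | demo / ablation / severity studies, YAML config     |
| `cardiorecon.nn`        | NumPy layer substrate (conv3d, norm, MLP, Adam)     |

See `docs/methods.md` for the model descriptions, parameter defaults, and
the reasoning behind the numerical choices.
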