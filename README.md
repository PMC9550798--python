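# daunet — 3D DA-UNet liver segmentation from CT

`daunet` is a tested, desk-scale implementation of a volumetric deep
segmentation pipeline for liver CT: a 3D U-Net-style encoder–decoder
with a residual encoder, an atrous-inception (AI) bridge, deep
supervision (DS), Tversky-loss training, dense-CRF post-processing, and
the five standard volume/surface evaluation metrics.  It is aimed at
researchers who want to study or extend these components with exact,
reproducible tests: a seeded synthetic CT-phantom generator stands in
for patient data, so every stage — preprocessing, training, inference,
refinement, evaluation — runs end-to-end on a laptop CPU with no
downloads and no GPU.

The network and its training loop are implemented on a small,
self-contained numpy reverse-mode autodiff engine (`daunet.autodiff`),
so the whole stack is dependency-light and exactly reproducible.

## The model

**Architecture.**  Four encoder levels with two residual blocks each
(eight residual blocks), stride-2 2×2×2 convolutions instead of max
pooling (four down-sampling blocks), an AI module as the bridge, three
up-sampling blocks with skip concatenation, and four output modules
(sigmoid heads).  All trunk convolutions are 3×3×3 with PReLU
activations.  The AI bridge computes

    x1 = W11·x + b11                      (1×1×1 reduction)
    xk = W3k·x1 + b3k,  k = 2, 3, 4       (3×3×3, dilation 2, 4, 8)
    Y  = Wy·Concat[x1, x2, x3, x4] + bf   (1×1×1 fusion)

capturing context at receptive fields of 5, 9 and 17 voxels per branch.
Ablation flags reproduce the ladder **3D U-Net → +Res → +AI → +DS**.

**Loss.**  The Tversky loss
`T(α,β) = 1 − Σ pg / (Σ pg + α Σ (p ḡ)² + β Σ (p̄ g)²)` with defaults
α = 0.4, β = 0.6 weighs false negatives more than false positives;
at α = β = 0.5 (linear penalties) it reduces to the Dice loss.  With
deep supervision the total loss is `L = L_main + α_ds (L1 + L2 + L3)`,
where α_ds decays by 0.8 every 40 epochs.  Training uses Adam, batch
size 1, initial learning rate 1e-3 decayed ×0.1 at epochs 350 and 650.

**Refinement.**  A fully connected CRF over all voxel pairs with
Gaussian appearance (position + intensity) and smoothness (position)
kernels under a Potts model, solved by mean-field iteration.  An exact
O(N²) mode is the test oracle for small ROIs; a bilateral-grid
approximate mode scales to full volumes.

**Metrics.**  Dice, VOE (1 − Jaccard), signed RVD, and spacing-aware
ASD / RMSD computed from pooled directed nearest-surface distances
(6-connected surfaces, exact Euclidean distance transform).

## Worked example

Generate two seeded phantoms, train the reduced-width full model, and
evaluate a prediction with and without CRF refinement:

```bash
daunet generate-phantom --spec config.yaml --n 2 --out data
daunet train --manifest data/manifest.tsv --config config.yaml --out run
daunet predict --checkpoint run/checkpoint_final.npz \
    --in data/case_001_image.nii.gz --out pred.nii.gz --prob-out prob.nii.gz
daunet evaluate --pred pred.nii.gz --truth data/case_001_mask.nii.gz
```

with `config.yaml`:

```yaml
phantom:
  grid_shape: [16, 32, 32]
  organ_center: [7.5, 15.5, 15.5]
  organ_radii: [5.0, 10.0, 10.0]
  n_lobes: 2
  neighbor_offset: [0, 0, 20]
  neighbor_radii: [4.0, 7.0, 7.0]
  vessel_count: 1
  noise_sd: 10.0
  seed: 11
network:
  base_channels: 4
  patch_shape: [16, 32, 32]
preprocess:
  inplane_size: 32
train:
  epochs: 150
  seed: 0
crf:
  theta_pos_app: 3.0
  theta_pos_smooth: 1.5
  mode: approximate
```

This prints (about three minutes on one CPU core):

```
wrote 2 case(s); manifest: data/manifest.tsv
trained 150 epoch(s); final train dice 0.9806 -> run
prediction -> pred.nii.gz (2174 foreground voxels)
dice    0.9893
voe     0.0212
rvd     -0.0212
asd_mm  0.0900
rmsd_mm 0.3674
```

Dice is the overlap with the ground-truth organ (1.0 is perfect), VOE
the complementary volume-overlap error, RVD the signed relative volume
difference (negative = over-segmentation), and ASD/RMSD the mean and
root-mean-square distance in millimetres between the predicted and true
organ surfaces.  `daunet refine --prob prob.nii.gz --image
data/case_001_image.nii.gz --params config.yaml --out refined.nii.gz`
applies the dense CRF to the probability map; on an already
near-perfect prediction it mainly smooths the boundary (Dice 0.9823
here), while on corrupted predictions it repairs errors — the
flip-noise benchmark below quantifies that gain.

Further subcommands: `preprocess` (HU window → 1 mm z-resample → organ
span crop ± 20 slices → in-plane resize → [0,1] normalization),
`ablation` (trains the four-variant ladder, each evaluated raw and
+CRF), and `describe-model` (per-layer shapes and parameter totals).

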