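# segpipe

Modular pipelines for **semantic segmentation of medical images** — the
task of labeling every voxel of a CT or MRI volume with a class such as
background, organ, or tumor. Deep segmentation models themselves are well
understood; what usually costs the time is everything around them: reading
clinical image formats, intensity preprocessing, slicing volumes that do
not fit in memory into patches and stitching predictions back together,
augmentation, class-imbalance-aware losses, and unbiased cross-validation.
`segpipe` packages those steps as composable, individually tested blocks
for researchers who want to stand up a complete 2D/3D segmentation pipeline
in a few lines and swap any part of it.

What ships:

- **Data I/O** — NIfTI (`.nii`/`.nii.gz`) backend reading voxel spacing
  from the header, directory-per-sample datasets, and an open interface
  contract for registering custom formats.
- **Preprocessing** — intensity clipping (e.g. Hounsfield windows),
  z-score / min-max normalization, resampling to a target voxel spacing,
  one-hot encoding; predictions are restored to the original grid.
- **Patch-wise analysis** — deterministic covering grids of overlapping
  patches, blank-patch skipping, random-crop sampling, and mean-merging of
  overlapping probability maps (a voxel-exact round trip on ground truth).
- **Augmentation** — mirroring, rotation, scaling, elastic deformation,
  brightness, contrast, gamma, Gaussian noise; seeded and reproducible.
- **Metrics and losses** — soft and class-wise Dice, Jaccard, categorical
  cross-entropy, and the Tversky loss for unbalanced classes:

      TI_c = TP_c / (TP_c + α·FP_c + β·FN_c),   loss = 1 − mean_c TI_c

  over soft counts (ε-smoothed), with α = 0.3, β = 0.7 by default; custom
  metrics register by name.
- **Models** — a configurable 2D/3D U-Net (depth, base filters, batch
  norm, dropout) on the package's numpy backend with explicit
  backpropagation and Adam, behind an open architecture registry;
  save/load reproduces predictions exactly.
- **Pipeline & evaluation** — seeded training with epoch shuffling,
  optional rare-class-focused patch sampling and an
  optional disk cache, full-volume prediction, k-fold / leave-one-out /
  percentage / hold-out / detailed splits, cross-validation with
  tab-separated reports, dataset statistics, and slice overlay images.
- **Synthetic phantoms** — labeled 3D volumes (background + organ + lesion
  ellipsoids with class-dependent intensities and Gaussian noise), so every
  feature is exercisable end to end without downloading data.

See `docs/methods.md` for the design decisions and their rationale.

## Worked example

`examples/04_train_and_predict.py` trains a tiny 3D U-Net (8 base filters,
depth 2) on 8 synthetic phantoms with 16³ patches and the Tversky loss
(with rare-class-focused patch sampling), then predicts a held-out phantom
through the full pipeline:

```
 epoch split  metric    value
     0 train tversky 0.571765
     1 train tversky 0.474936
     2 train tversky 0.427278
     ...
    13 train tversky 0.180792
    14 train tversky 0.173966
held-out Dice per class: [0.999 0.983 0.947]  mean 0.976
```

The training Tversky loss (1 − mean class-wise Tversky index; 0 is perfect)
drops steeply because phantom classes are separable by intensity. The
held-out per-class Dice — overlap between predicted and true masks for
background, organ, and lesion — shows the pipeline recovers even the small
lesion class well. The other example scripts each demonstrate one
capability: dataset generation and statistics, the lossless patch-merge
round trip, metric closed forms, and threefold cross-validation.

A command-line interface wraps the same library calls:

```bash
segpipe phantom --out data/ --n 20 --seed 1
segpipe train   --config cfg.yaml --data data/ --out run/
segpipe predict --config cfg.yaml --model run/model.npz --data data/ --out preds/
segpipe evaluate --config cfg.yaml --data data/ --out report/
```

The shipped `src/segpipe/configs/kits19_reference.yaml` documents a
full-scale kidney/tumor CT study configuration (80×160×160 patches,
clipping to [−79, 304], 3.22×1.62×1.62 mm spacing, Tversky loss, 1000
epochs); it is reference documentation, not a desk-scale run.

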