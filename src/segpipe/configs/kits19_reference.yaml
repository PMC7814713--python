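# Reference configuration for kidney/tumor segmentation on KiTS19-style
# abdominal CT: multi-class 3D patch-wise analysis with 80x160x160 patches,
# batch size 2, z-score normalization, Hounsfield clipping to [-79, 304],
# resampling to 3.22 x 1.62 x 1.62 mm voxel spacing, random-crop patch
# sampling with full augmentation for training, 40x80x80 overlapping patches
# for prediction, a standard 3D U-Net with batch normalization, and Tversky
# loss for 1000 epochs at a starting learning rate of 1e-4.
#
# Shipped as documentation of a full-scale study setup; training it takes
# multi-GPU-days and is far beyond desk scale.

data:
  interface: nifti
  image_name: imaging.nii.gz
  seg_name: segmentation.nii.gz

preprocessing:
  clip_range: [-79, 304]
  normalization: zscore
  target_spacing: [3.22, 1.62, 1.62]
  n_classes: 3

patches:
  patch_shape: [80, 160, 160]
  overlap: [40, 80, 80]
  skip_blanks: true
  analysis: patchwise-crop

augmentation: {}   # all operators enabled at their default probabilities

model:
  architecture: unet
  n_dims: 3
  in_channels: 1
  n_classes: 3
  base_filters: 32
  depth: 4
  batch_norm: true
  dropout: 0.0

training:
  epochs: 1000
  learning_rate: 1.0e-4
  loss: tversky
  monitor_metrics: [dice_soft, dice_classwise, crossentropy_dice]

batch:
  batch_size: 2
  mode: on-the-fly

evaluation:
  mode: kfold
  k: 3
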