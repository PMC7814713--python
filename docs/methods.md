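# Methods

`segpipe` builds semantic-segmentation pipelines for volumetric (and planar)
medical images: per-voxel classification of 2D/3D scans into C classes
(e.g. background / organ / tumor), with the standard surrounding machinery —
data I/O, preprocessing, patch-wise analysis, augmentation, loss functions,
a configurable U-Net, and automatic evaluation. This note records the model
and the numerical and design choices, in the order data flows through the
pipeline.

## Data model and I/O

A `Sample` holds one subject: an image array with spatial axes plus an
explicit trailing channel axis (size 1 for scalar modalities such as CT),
an optional integer label mask over the same spatial grid, and per-axis
physical voxel sizes in millimetres. The original grid (shape and spacing
at load time) is recorded so predictions can be restored to it.

The bundled NIfTI backend reads `.nii`/`.nii.gz` through nibabel using a
directory-per-sample layout (`<root>/<id>/imaging.nii.gz` +
`segmentation.nii.gz`; names configurable). Only the header zooms (voxel
spacing / slice thickness) are consumed; the rotation component of the
affine is deliberately ignored and arrays are processed in stored voxel
order. Predicted masks are written with an integer dtype and a plain
scaling affine carrying the original spacing — no other source metadata is
copied. Spatially reorienting data into a canonical anatomical frame is out
of scope and must happen upstream. Any other storage scheme can be plugged
in by registering an object with `list_samples` / `load` /
`save_prediction` under a name.

## Preprocessing

Subfunctions run in a fixed order: **clip → resample → normalize**, then
one-hot encoding for labels. Clipping precedes resampling so interpolation
cannot re-create out-of-range intensities; normalization runs last so its
statistics describe the grid the network actually sees. Choices:

- Clipping to an intensity window `(lo, hi)` — for CT typically a
  Hounsfield window such as `[-79, 304]`.
- Resampling to a target spacing maps each axis to
  `round(shape * spacing / target)` voxels (minimum 1). Images use a
  third-order spline by default (configurable down to linear); label masks
  always use nearest-neighbour, the only label-preserving choice. The
  pre-resampling grid is kept in a `GridRecord`; predictions are restored
  to it by nearest-neighbour resampling.
- Normalization: z-score (per channel, population standard deviation;
  constant channels map to zeros to avoid division by zero), min-max to
  `[0, 1]` or `[-1, 1]`, or none.
- Labels are one-hot encoded for all C ≥ 2, binary problems included, so
  every loss sees a uniform class axis; decoding is the per-voxel argmax
  with ties broken toward the lower class index.

## Patch-wise analysis

Large volumes are processed as overlapping cuboid patches. Windows are
0-based and half-open; the grid strides by `patch − overlap` per axis and,
when the last regular window stops short of the boundary, a final window is
shifted back so it ends exactly at the boundary (**edge alignment**). This
guarantees full coverage without padding — padding would invent voxels and
contaminate normalization statistics — but it changes patch counts relative
to zero-padding implementations, so it is part of the documented contract.

Training can draw patches from the deterministic grid (with all-background
"blank" patches skipped) or as uniformly random crops, one or more per
sample per epoch; random cropping doubles as implicit translation
augmentation. Crops are rejection-sampled toward foreground-containing
windows with a capped number of retries, then accepted regardless — pure
rejection could loop forever on empty masks. Prediction always uses the
deterministic grid, with overlap recommended because accuracy decays at
patch edges; per-class probabilities of overlapping windows are merged by
the arithmetic mean, accumulated in double precision (sum and count
accumulators), so the merge is patch-order invariant to ~1e-12. Slicing
one-hot ground truth through any covering grid, merging, and decoding is
voxel-exact — the pipeline's flagship lossless-round-trip guarantee.

## Augmentation

Eight operators, each firing independently with its own probability:
mirroring, in-plane rotation, central scaling, elastic deformation
(white Gaussian noise fields smoothed with a Gaussian kernel and scaled to
a target amplitude), brightness offset, contrast scaling about the mean,
gamma remapping of the min-max-normalized range, and additive Gaussian
noise. Spatial operators transform image and mask through the same
geometric map — image linearly, mask nearest-neighbour, both with
edge-value fill — so the label set can never grow; intensity operators
touch the image only. Defaults (probability 0.15 per operator, rotation
±15°, scale 0.85–1.15, gamma 0.7–1.5, brightness ±0.1 image standard
deviations, contrast 0.75–1.25, elastic amplitude ≤ 2 voxels at smoothing
width 8, noise sd ≤ 0.1) are deliberately conservative and fully
overridable; augmentation applies in training only.

## Losses and metrics

All metrics take one-hot truth and per-class probabilities, class axis
last, smoothed with ε = 1e-5 so ratios stay defined on empty classes. A
class absent from both truth and prediction scores 1 (ε/ε), which inflates
class-wise means when classes are missing — worth remembering when reading
reports.

The training default is the **Tversky loss**: per class,

    TI_c = (TP_c + ε/2) / (TP_c + α·FP_c + β·FN_c + ε/2),   loss = 1 − mean_c TI_c

over soft counts, with α = 0.3, β = 0.7 by default (recall-weighted, for
unbalanced foregrounds). The smoothing enters halved so that two algebraic
identities hold exactly: α = β = 0.5 reduces the Tversky loss to the
class-wise soft-Dice loss, and Jaccard (also ε/2-smoothed) satisfies
J = D/(2−D). Also provided: global and class-wise soft Dice, Jaccard, and
the combined score CE − soft Dice (categorical cross-entropy minus global
soft Dice; negative when predictions are good). Custom metrics register
under a name; supplying an analytic gradient with respect to the predicted
probabilities additionally makes a metric usable as a training loss — a
requirement of the explicit-backpropagation backend below. Batch losses are
the mean over batch members.

**The training objective masks absent classes.** The registered `tversky`
training loss averages the Tversky index over the classes *present in the
batch ground truth* rather than over all C classes. The distinction
matters at small patch and batch sizes: a rare class is absent from most
batches, and in an absent-class batch the smoothed ratio scores ≈ 0 while
any residual probability mass exists but exactly ε/ε = 1 once the class's
softmax channel is completely silenced — so with the all-class mean,
killing the rare class's channel is a *stable optimum* of the training
objective, and a saturated softmax (gradients scale with the channel
probability) can never recover from it. We observed exactly this
degenerate convergence on phantom data for most initializations.
Restricting the class mean to present classes removes the incentive; the
evaluation metric keeps the plain all-class mean.

**Rare-class-focused patch sampling.** Masking alone does not prevent the
channel dying as a side effect of the other classes gaining confidence
(feature aliasing pushes the organ logit up at lesion voxels, and softmax
normalization drives the lesion probability toward zero everywhere).
`TrainSpec.rare_class_focus` (off by default) therefore optionally
restricts the grid-mode training inventory to patches containing the
rarest foreground class — the class-balanced-sampling remedy standard in
medical segmentation training. The rare class's voxels then contribute
gradient in every batch and its channel never saturates away. On phantom
data this turns rare-class learning from initialization luck into a
reliable outcome across seeds.

## Network backend and the U-Net

Models train and predict through a small numpy backend written for this
package: N-D "same" convolutions as im2col GEMM with hand-derived backward
passes, 2× max-pooling, kernel-2 stride-2 transposed convolutions
(non-overlapping output blocks, which keeps the backward pass exact and
cheap), batch normalization, inverted dropout, channel softmax, and Adam.
Gradients are verified against central finite differences in the test
suite. The backend is single-process and CPU-oriented; it is sized for
desk-scale experiments, not for multi-GPU studies.

The bundled architecture is the standard 2D/3D U-Net: `depth` encoder
levels of two 3^n convolutions (ReLU, optional batch norm/dropout) with
filter counts doubling from `base_filters`, 2× max-pooling between levels,
a two-convolution bottleneck, and a mirrored decoder with transposed-conv
upsampling and skip concatenation; a kernel-1 convolution maps to C
channels and a per-voxel softmax yields a class distribution summing to 1.
Every input spatial size must be divisible by 2^depth; violations raise a
configuration error naming the axis. He initialization is seeded from the
pipeline seed for reproducibility. The softmax is the multi-class
normalization of the per-class sigmoid view: each channel is still a
probability estimate per class, but the channels are coupled to sum to 1,
which is the natural choice given the uniform one-hot representation.
Alternative architectures register under a name and are validated against
the shape/probability contract on first build. Models serialize to a single
`.npz` of parameters plus a JSON header; loading reproduces predictions to
float32 precision.

## Training loop, batches, cache

An epoch fits the full training inventory once: grid mode uses the
deterministic non-blank patches; crop mode draws `crops_per_sample` fresh
crops per sample per epoch. Items are bundled into ⌈n/batch⌉ batches;
shuffling permutes only the processing order of batches (contents are
untouched) and is deterministic in (seed, epoch). The optional disk cache
writes each prepared batch to one `.npz` container with a tab-separated
manifest; cached and on-the-fly modes feed bit-identical voxels because
augmentation draws are seeded per (seed, epoch, batch index), independent
of mode and shuffle order. Augmentation is applied after cache load, so the
cache stores un-augmented patches and epochs still vary. Per-epoch training
loss and any monitored metrics are appended to a tab-separated history file
(columns epoch / split / metric / value).

## Evaluation

Split plans: k-fold (test sets partition the ids; the first `n mod k` folds
take the extra sample), leave-one-out, percentage/hold-out (one fold, the
same mechanism under both names), and detailed (explicit user lists,
copied verbatim). Random modes are seed-deterministic. Cross-validation
trains per fold on training ids only, predicts the held-out ids through the
full pipeline, scores them with the requested registered metrics, and
writes per-sample and aggregate (per-fold + overall mean) tab-separated
tables. Dataset statistics report per-sample intensity ranges and per-class
voxel counts/fractions. Overlay rendering blends a fixed class palette at
alpha 0.4 over the grayscale slice (side-by-side with truth when given) as
static per-slice PNGs with deterministic pixel output.

## Synthetic phantoms

The generator emulates the class structure of abdominal CT tumor datasets
at desk scale: a dominant background, an "organ" ellipsoid (class 1) at a
random interior position, and for three-class problems a smaller "lesion"
ellipsoid (class 2) placed strictly inside the organ (rejection-sampled
with a one-voxel interior margin, capped at 100 tries). Voxel intensities
are the class mean plus i.i.d. Gaussian noise. Defaults: 32³ voxels, class
means (0, 0.5, 1.0), noise sd 0.05, organ semi-axes 6–10, lesion 2–4, unit
spacing.

Noiseless phantoms are exactly threshold-separable (a midpoint-threshold
classifier reaches Dice 1.0 per class), and at noise sd ≤ 0.1× the class
gap still ≥ 0.95 — an analytic ceiling that anchors the end-to-end
expectation for a trained network. What phantoms do **not** emulate:
anatomical shape variability, textured organs, partial-volume effects, CT
physics (beam hardening, calibrated Hounsfield units), or inter-scanner
variation. Passing phantom tests therefore demonstrates that the pipeline's
plumbing and optimization are correct, not that a given configuration will
reach any particular accuracy on clinical data.

## Desk-scale study sizes

The end-to-end test and `scripts/acceptance.py` train a tiny 3D U-Net
(base filters 8, depth 2, batch norm) on 16 phantoms of 32³ voxels with
16³ patches at 8³ overlap, batch size 2, Tversky loss with rare-class
focus, Adam at learning rate 1e-3, for 10 epochs — enough for the loss to
converge because the phantom classes are separable by intensity — then
score 4 held-out phantoms (mean class-wise Dice ≥ 0.80 expected; ~0.97
typical across seeds). The threefold cross-validation check runs a reduced
depth-1/4-filter network for 2 epochs on 12 phantoms, since it verifies
report bookkeeping rather than accuracy. The shipped `kits19_reference`
configuration documents a full-scale study setup (80×160×160 patches,
1000 epochs, learning rate 1e-4) and is a documentation fixture, not
something to run on a workstation.

## Known limitations

- No DICOM or PNG/TIFF-stack backends ship (the interface contract supports
  adding them).
- The NIfTI affine's rotation/shear is ignored; oblique acquisitions must
  be resampled upstream.
- Single-process, CPU-bound training; no learning-rate schedules or early
  stopping (both are extension points), no Gaussian-weighted patch
  blending, no test-time augmentation, no surface-distance metrics.
- Prediction files carry spacing only, not the full source affine.
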