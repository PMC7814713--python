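"""Orchestration: batch assembly, epoch shuffling, disk cache, training loop,
and full-sample prediction.

The training inventory depends on the analysis mode:

``patchwise-grid``
    The deterministic covering grid per sample, with blank (all-background)
    patches skipped when configured.  This inventory is epoch-independent
    and is what the optional disk cache stores.  With ``rare_class_focus``
    the inventory is further restricted to windows containing the rarest
    foreground class (see :func:`focus_rarest_class`).
``patchwise-crop``
    ``crops_per_sample`` random crops per sample drawn fresh each epoch,
    rejection-sampled towards foreground-containing windows with a capped
    number of retries (then the last draw is accepted, so empty masks
    cannot loop).  Crops are always generated on the fly.
``fullimage``
    One item per sample.

Shuffling permutes only the processing order of batches, never their
contents, and is deterministic in ``(seed, epoch)``.  Augmentation draws are
seeded per ``(seed, epoch, batch index)``, so the voxels entering the model
in an epoch are identical between the disk-cache and on-the-fly modes and
under any shuffle order.

Prediction runs preprocess -> overlapping grid -> per-patch probabilities ->
mean merge -> argmax decode -> restore to the original grid -> save.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .augmentation import AugmentSpec, augment_pair
from .data_io import DataInterface, Sample
from .errors import CacheError, ConfigurationError, ValidationError
from .patching import (PatchConfig, PatchSet, compute_patch_grid,
                       extract_patches, filter_blank_patches,
                       merge_overlapping_predictions, random_crop)
from .preprocessing import (GridRecord, PreprocSpec, one_hot_decode,
                            one_hot_encode, preprocess_sample,
                            restore_to_original_grid)

BATCH_MODES = ("disk-cache", "on-the-fly")

Item = Tuple[np.ndarray, np.ndarray]  # (image patch, integer label patch)
Batch = List[Item]


@dataclasses.dataclass
class BatchPlan:
    """Batch size, generation mode and (for disk-cache) the cache directory."""

    batch_size: int = 2
    mode: str = "on-the-fly"
    cache_dir: Optional[str] = None
    epoch_seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.mode not in BATCH_MODES:
            raise ConfigurationError(
                f"unknown batch mode {self.mode!r}; choose from {BATCH_MODES}"
            )
        if self.mode == "disk-cache" and not self.cache_dir:
            raise ConfigurationError("disk-cache mode requires cache_dir")


@dataclasses.dataclass
class TrainSpec:
    """Training schedule: epochs, learning rate, loss and monitored metrics."""

    epochs: int = 1
    learning_rate: float = 1e-4
    loss: str = "tversky"
    monitor_metrics: Tuple[str, ...] = ("dice_soft", "dice_classwise")
    seed: int = 0
    crops_per_sample: int = 1
    crop_retry_cap: int = 10
    rare_class_focus: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.crops_per_sample < 1:
            raise ValidationError("crops_per_sample must be >= 1")


# ------------------------------------------------------------------ batching

def make_batches(items: Sequence, batch_size: int) -> List[List]:
    """Split items into ceil(n / batch_size) batches, order preserved."""
    if batch_size < 1:
        raise ValidationError(f"batch_size must be >= 1, got {batch_size}")
    if len(items) == 0:
        raise ValidationError("cannot batch an empty item list")
    return [list(items[i:i + batch_size]) for i in range(0, len(items), batch_size)]


def shuffle_epoch(batches: Sequence, epoch_index: int, seed: int) -> List:
    """Permute the batch processing order; contents are untouched."""
    if len(batches) == 0:
        raise ValidationError("no batches to shuffle")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, epoch_index])
    order = rng.permutation(len(batches))
    return [batches[i] for i in order]


def batch_cache(batches: Sequence[Batch], cache_dir: str) -> Dict:
    """Write each batch to one .npz container and return the manifest."""
    os.makedirs(cache_dir, exist_ok=True)
    entries = []
    for i, batch in enumerate(batches):
        fname = f"batch_{i:05d}.npz"
        path = os.path.join(cache_dir, fname)
        arrays = {}
        for j, (x, y) in enumerate(batch):
            arrays[f"x_{j}"] = x
            arrays[f"y_{j}"] = y
        np.savez(path, **arrays)
        entries.append({"index": i, "file": fname, "size": len(batch)})
    manifest = {"cache_dir": cache_dir, "entries": entries}
    with open(os.path.join(cache_dir, "manifest.tsv"), "w") as fh:
        fh.write("index\tfile\tsize\n")
        for e in entries:
            fh.write(f"{e['index']}\t{e['file']}\t{e['size']}\n")
    return manifest


def load_cached(manifest: Dict, index: int) -> Batch:
    """Load one cached batch; arrays are voxel-identical to the originals."""
    entries = manifest["entries"]
    if not 0 <= index < len(entries):
        raise CacheError(f"batch index {index} outside manifest (n={len(entries)})")
    entry = entries[index]
    path = os.path.join(manifest["cache_dir"], entry["file"])
    if not os.path.exists(path):
        raise CacheError(f"cached batch {index} missing: {path}")
    try:
        with np.load(path) as data:
            return [(data[f"x_{j}"], data[f"y_{j}"]) for j in range(entry["size"])]
    except CacheError:
        raise
    except Exception as exc:
        raise CacheError(f"cached batch {index} unreadable: {exc}") from exc


# ------------------------------------------------------------------ assembly

def _preprocess_all(samples: Sequence[Sample], preproc: PreprocSpec):
    prepped = []
    for s in samples:
        if s.segmentation is None:
            raise ValidationError(f"sample {s.id!r} has no segmentation")
        img, seg, record = preprocess_sample(s.image, s.segmentation,
                                             s.spacing, preproc)
        prepped.append((img, seg, record))
    return prepped


def grid_inventory(prepped, patchcfg: PatchConfig) -> List[Item]:
    """Epoch-independent training items for grid and fullimage analyses."""
    items: List[Item] = []
    for img, seg, _ in prepped:
        shape = img.shape[:-1]
        if patchcfg.analysis == "fullimage":
            items.append((img, seg))
            continue
        offsets = compute_patch_grid(shape, patchcfg.patch_shape, patchcfg.overlap)
        ps_img = extract_patches(img, offsets, patchcfg.patch_shape)
        ps_seg = extract_patches(seg[..., np.newaxis], offsets, patchcfg.patch_shape)
        if patchcfg.skip_blanks:
            ps_img, ps_seg = filter_blank_patches(ps_img, ps_seg)
        for x, y in zip(ps_img.patches, ps_seg.patches):
            items.append((x, y[..., 0]))
    return items


def focus_rarest_class(items: List[Item]) -> List[Item]:
    """Restrict training items to patches containing the rarest foreground class.

    With small patches and batches, ratio losses let the network silence a
    rare class entirely (its softmax channel saturates at zero and cannot
    recover); biasing the patch inventory toward windows that contain the
    rarest class keeps its gradient signal alive.  Falls back to the full
    inventory when no foreground class exists.
    """
    totals: Dict[int, int] = {}
    for _, y in items:
        for c, n in zip(*np.unique(np.asarray(y), return_counts=True)):
            if c != 0:
                totals[int(c)] = totals.get(int(c), 0) + int(n)
    if not totals:
        return items
    rarest = min(totals, key=totals.get)
    focused = [(x, y) for x, y in items if np.any(np.asarray(y) == rarest)]
    return focused or items


def crop_inventory(prepped, patchcfg: PatchConfig, spec: TrainSpec,
                   epoch: int) -> List[Item]:
    """Fresh random crops per epoch, biased towards foreground windows."""
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, epoch, 0xC401])
    items: List[Item] = []
    for img, seg, _ in prepped:
        for _ in range(spec.crops_per_sample):
            x = y = None
            for _attempt in range(spec.crop_retry_cap):
                x, y = random_crop(img, seg, patchcfg.patch_shape, rng)
                if not patchcfg.skip_blanks or np.any(y != 0):
                    break
            items.append((x, y))
    return items


# ------------------------------------------------------------------ training

def _augment_batch(batch: Batch, augspec: AugmentSpec, seed: int, epoch: int,
                   batch_index: int) -> Batch:
    rng = np.random.default_rng([seed & 0x7FFFFFFF, epoch, batch_index])
    return [augment_pair(x, y, augspec, rng) for x, y in batch]


def write_history(history: pd.DataFrame, path: str) -> str:
    """Fitting callback output: tab-separated epoch/split/metric/value rows."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    history.to_csv(path, sep="\t", index=False)
    return path


def train(model, samples: Sequence[Sample], preproc: PreprocSpec,
          patchcfg: PatchConfig, augspec: AugmentSpec, plan: BatchPlan,
          spec: TrainSpec, out_dir: Optional[str] = None):
    """Fit the model; returns (model, per-epoch metric history DataFrame)."""
    if len(samples) == 0:
        raise ValidationError("need at least one training sample")
    model.compile(spec.learning_rate, spec.loss)
    monitor = [m for m in spec.monitor_metrics if m != spec.loss]
    monitor_fns = {name: metrics_mod.get_metric(name).fn for name in monitor}

    prepped = _preprocess_all(samples, preproc)
    use_crops = patchcfg.analysis == "patchwise-crop"

    manifest = None
    static_batches: Optional[List[Batch]] = None
    if not use_crops:
        items = grid_inventory(prepped, patchcfg)
        if spec.rare_class_focus:
            items = focus_rarest_class(items)
        if len(items) == 0:
            raise ValidationError(
                "training inventory is empty (all patches blank?); disable "
                "skip_blanks or check the masks"
            )
        static_batches = make_batches(items, plan.batch_size)
        if plan.mode == "disk-cache":
            manifest = batch_cache(static_batches, plan.cache_dir)

    rows = []
    for epoch in range(spec.epochs):
        if use_crops:
            batches = make_batches(crop_inventory(prepped, patchcfg, spec, epoch),
                                   plan.batch_size)
        elif manifest is not None:
            batches = [load_cached(manifest, i)
                       for i in range(len(manifest["entries"]))]
        else:
            batches = static_batches
        indexed = list(enumerate(batches))
        order = shuffle_epoch(indexed, epoch, plan.epoch_seed ^ spec.seed)

        loss_sum = 0.0
        metric_sums = {name: 0.0 for name in monitor}
        n_items = 0
        for batch_index, batch in order:
            batch = _augment_batch(batch, augspec, spec.seed, epoch, batch_index)
            x = np.stack([b[0] for b in batch]).astype(np.float32)
            y = np.stack([
                one_hot_encode(np.asarray(b[1], dtype=np.int32), model.n_classes)
                for b in batch
            ])
            loss_val, probs = model.train_on_batch(x, y)
            loss_sum += loss_val * len(batch)
            n_items += len(batch)
            for name, fn in monitor_fns.items():
                metric_sums[name] += float(fn(y, probs)) * len(batch)

        rows.append({"epoch": epoch, "split": "train", "metric": spec.loss,
                     "value": loss_sum / n_items})
        for name in monitor:
            rows.append({"epoch": epoch, "split": "train", "metric": name,
                         "value": metric_sums[name] / n_items})

    history = pd.DataFrame(rows, columns=["epoch", "split", "metric", "value"])
    if out_dir is not None:
        write_history(history, os.path.join(out_dir, "history.tsv"))
    return model, history


# ---------------------------------------------------------------- prediction

def predict_sample(model, sample: Sample, preproc: PreprocSpec,
                   patchcfg: PatchConfig, out_path: Optional[str] = None,
                   interface: Optional[DataInterface] = None,
                   batch_size: int = 8) -> np.ndarray:
    """Predict one sample's mask on its original grid (and optionally save it)."""
    img, _, record = preprocess_sample(sample.image, None, sample.spacing, preproc)
    shape = img.shape[:-1]
    if patchcfg.analysis == "fullimage":
        offsets = [(0,) * len(shape)]
        patch_shape = shape
    else:
        patch_shape = patchcfg.patch_shape
        if any(p > s for p, s in zip(patch_shape, shape)):
            raise ValidationError(
                f"patch shape {patch_shape} exceeds preprocessed volume {shape}; "
                "use fullimage analysis or a smaller patch shape"
            )
        # prediction always uses the deterministic (overlapping) grid
        offsets = compute_patch_grid(shape, patch_shape, patchcfg.overlap)
    ps = extract_patches(img, offsets, patch_shape)
    try:
        probs = model.predict(ps.patches, offsets=offsets, batch_size=batch_size)
    except TypeError:
        probs = model.predict(ps.patches, batch_size=batch_size)
    merged = merge_overlapping_predictions(
        PatchSet(list(ps.offsets), probs, tuple(shape)), shape, model.n_classes)
    mask = one_hot_decode(merged)
    mask = restore_to_original_grid(mask, record)
    if out_path is not None:
        iface = interface
        if iface is None:
            from .data_io import save_nifti_segmentation
            save_nifti_segmentation(mask, sample, out_path)
        else:
            iface.save_prediction(sample.id, mask, sample, out_path)
    return mask
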