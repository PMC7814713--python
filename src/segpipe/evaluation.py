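"""Automatic evaluation: split plans, cross-validation, statistics, overlays.

Split modes: ``kfold`` (test sets partition the ids, sizes differing by at
most one, the first ``n mod k`` folds taking the extra sample), ``loo``
(one singleton test per id), ``percentage`` and ``holdout`` (one fold with
a given training fraction — the same mechanism under two names) and
``detailed`` (explicit user-provided train/test lists).  All random modes
sample deterministically from the seed.

Cross-validation trains per fold on the training ids only, predicts the
held-out ids, and scores each prediction with the requested registered
metrics; per-sample and aggregate tables are written tab-separated.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import matplotlib
import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .augmentation import AugmentSpec
from .data_io import Sample
from .errors import ValidationError
from .patching import PatchConfig
from .pipeline import BatchPlan, TrainSpec, predict_sample, train
from .preprocessing import PreprocSpec, one_hot_encode

matplotlib.use("Agg")  # non-interactive rendering only

SPLIT_MODES = ("kfold", "loo", "percentage", "holdout", "detailed")

# fixed class palette for overlays (RGB in [0, 1]); class 0 = background
OVERLAY_PALETTE = np.array([
    [0.00, 0.00, 0.00],  # background (never painted)
    [0.89, 0.10, 0.11],  # red
    [0.22, 0.49, 0.72],  # blue
    [0.30, 0.69, 0.29],  # green
    [1.00, 0.50, 0.00],  # orange
    [0.60, 0.31, 0.64],  # purple
])
OVERLAY_ALPHA = 0.4


@dataclasses.dataclass
class SplitPlan:
    """Evaluation mode plus per-fold (train ids, test ids)."""

    mode: str
    folds: List[Tuple[Tuple[str, ...], Tuple[str, ...]]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in SPLIT_MODES:
            raise ValidationError(f"unknown split mode {self.mode!r}")
        for i, (tr, te) in enumerate(self.folds):
            if set(tr) & set(te):
                raise ValidationError(f"fold {i}: train and test ids overlap")
            if len(te) == 0:
                raise ValidationError(f"fold {i}: empty test set")


def make_split(ids: Sequence[str], mode: str, k: Optional[int] = None,
               fraction: Optional[float] = None,
               folds: Optional[Sequence[Tuple[Sequence[str], Sequence[str]]]] = None,
               seed: int = 0) -> SplitPlan:
    """Build a deterministic :class:`SplitPlan` over the given identifiers."""
    ids = list(ids)
    if mode not in SPLIT_MODES:
        raise ValidationError(f"unknown split mode {mode!r}")
    if mode != "detailed" and len(ids) < 2:
        raise ValidationError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)

    if mode == "kfold":
        if k is None or not 2 <= k <= len(ids):
            raise ValidationError(f"kfold requires 2 <= k <= n, got k={k}, n={len(ids)}")
        perm = [ids[i] for i in rng.permutation(len(ids))]
        n, base, extra = len(ids), len(ids) // k, len(ids) % k
        plan_folds = []
        start = 0
        for f in range(k):
            size = base + (1 if f < extra else 0)
            test = tuple(perm[start:start + size])
            train = tuple(x for x in perm if x not in test)
            plan_folds.append((train, test))
            start += size
        return SplitPlan("kfold", plan_folds, seed)

    if mode == "loo":
        return SplitPlan(
            "loo",
            [(tuple(x for x in ids if x != t), (t,)) for t in ids],
            seed,
        )

    if mode in ("percentage", "holdout"):
        if fraction is None or not 0.0 < fraction < 1.0:
            raise ValidationError(f"{mode} requires a training fraction in (0, 1)")
        perm = [ids[i] for i in rng.permutation(len(ids))]
        n_test = max(1, min(len(ids) - 1, int(round(len(ids) * (1.0 - fraction)))))
        return SplitPlan(mode, [(tuple(perm[n_test:]), tuple(perm[:n_test]))], seed)

    # detailed: copy the explicit lists verbatim
    if not folds:
        raise ValidationError("detailed mode requires explicit folds")
    known = set(ids)
    for tr, te in folds:
        unknown = (set(tr) | set(te)) - known
        if unknown:
            raise ValidationError(f"unknown sample ids in detailed split: {sorted(unknown)}")
    return SplitPlan("detailed", [(tuple(tr), tuple(te)) for tr, te in folds], seed)


# --------------------------------------------------------- cross-validation

def run_cross_validation(
    samples: Dict[str, Sample],
    plan: SplitPlan,
    model_factory: Callable[[int], object],
    preproc: PreprocSpec,
    patchcfg: PatchConfig,
    augspec: AugmentSpec,
    batchplan: BatchPlan,
    trainspec: TrainSpec,
    eval_metrics: Sequence[str] = ("tversky", "dice_soft", "dice_classwise",
                                   "crossentropy_dice"),
    out_dir: Optional[str] = None,
    predictor: Optional[Callable[[object, Sample], np.ndarray]] = None,
    n_classes: Optional[int] = None,
) -> Dict[str, pd.DataFrame]:
    """Train/predict/score per fold; test ids never influence the fitting.

    ``model_factory(fold_index)`` returns a fresh model per fold (a stub
    without a ``train_on_batch`` method skips fitting).  ``predictor``
    overrides how a test sample's mask is produced; by default the full
    prediction pipeline runs.  Returns per-sample and aggregate tables.
    """
    for f, (train_ids, test_ids) in enumerate(plan.folds):
        for sid in list(train_ids) + list(test_ids):
            if sid not in samples:
                raise ValidationError(f"fold {f}: unknown sample id {sid!r}")
            if sid in test_ids and samples[sid].segmentation is None:
                raise ValidationError(f"fold {f}: test sample {sid!r} has no ground truth")

    metric_fns = {name: metrics_mod.get_metric(name).fn for name in eval_metrics}
    rows = []
    for fold_index, (train_ids, test_ids) in enumerate(plan.folds):
        model = model_factory(fold_index)
        if hasattr(model, "train_on_batch"):
            fold_dir = (os.path.join(out_dir, f"fold_{fold_index}")
                        if out_dir is not None else None)
            fold_spec = dataclasses.replace(
                trainspec, seed=(trainspec.seed + fold_index) & 0x7FFFFFFF)
            fold_plan = batchplan
            if batchplan.mode == "disk-cache":
                fold_plan = dataclasses.replace(
                    batchplan,
                    cache_dir=os.path.join(batchplan.cache_dir, f"fold_{fold_index}"))
            model, _ = train(model, [samples[sid] for sid in train_ids], preproc,
                             patchcfg, augspec, fold_plan, fold_spec,
                             out_dir=fold_dir)
        for sid in test_ids:
            sample = samples[sid]
            if predictor is not None:
                mask = predictor(model, sample)
            else:
                mask = predict_sample(model, sample, preproc, patchcfg)
            c = n_classes or getattr(model, "n_classes", None) or preproc.n_classes
            truth = one_hot_encode(np.asarray(sample.segmentation, np.int32), c)
            pred = one_hot_encode(np.asarray(mask, np.int32), c)
            for name, fn in metric_fns.items():
                rows.append({"fold": fold_index, "sample_id": sid,
                             "metric": name, "value": float(fn(truth, pred))})

    per_sample = pd.DataFrame(rows, columns=["fold", "sample_id", "metric", "value"])
    fold_means = (per_sample.groupby(["fold", "metric"], as_index=False)["value"]
                  .mean())
    fold_means["fold"] = fold_means["fold"].astype(str)
    overall = (per_sample.groupby("metric", as_index=False)["value"].mean())
    overall.insert(0, "fold", "mean")
    aggregate = pd.concat([fold_means, overall], ignore_index=True)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        per_sample.to_csv(os.path.join(out_dir, "report.tsv"), sep="\t", index=False)
        aggregate.to_csv(os.path.join(out_dir, "aggregate.tsv"), sep="\t", index=False)
    return {"per_sample": per_sample, "aggregate": aggregate}


# --------------------------------------------------------------- statistics

def dataset_statistics(samples: Sequence[Sample],
                       n_classes: Optional[int] = None) -> pd.DataFrame:
    """Per-sample intensity range and per-class voxel counts/fractions."""
    if len(samples) == 0:
        raise ValidationError("need at least one sample")
    if n_classes is None:
        n_classes = 1 + max(
            int(s.segmentation.max()) for s in samples if s.segmentation is not None
        )
    rows = []
    for s in samples:
        lo, hi = float(s.image.min()), float(s.image.max())
        if s.segmentation is None:
            rows.append({"sample_id": s.id, "image_min": lo, "image_max": hi,
                         "class": -1, "voxel_count": 0, "fraction": float("nan")})
            continue
        total = s.segmentation.size
        counts = np.bincount(s.segmentation.ravel(), minlength=n_classes)
        for c in range(n_classes):
            rows.append({"sample_id": s.id, "image_min": lo, "image_max": hi,
                         "class": c, "voxel_count": int(counts[c]),
                         "fraction": counts[c] / total})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ overlay

def _render_slice(gray: np.ndarray, mask_slice: np.ndarray) -> np.ndarray:
    lo, hi = gray.min(), gray.max()
    norm = (gray - lo) / (hi - lo) if hi > lo else np.zeros_like(gray)
    rgb = np.repeat(norm[..., np.newaxis], 3, axis=-1)
    fg = mask_slice > 0
    colors = OVERLAY_PALETTE[np.clip(mask_slice, 0, len(OVERLAY_PALETTE) - 1)]
    rgb[fg] = (1 - OVERLAY_ALPHA) * rgb[fg] + OVERLAY_ALPHA * colors[fg]
    return np.clip(rgb, 0.0, 1.0)


def render_overlay(sample: Sample, mask: np.ndarray,
                   truth: Optional[np.ndarray] = None,
                   slice_index="all", out_dir: str = ".",
                   axis: int = 0) -> List[str]:
    """Write static per-slice overlay images (prediction, and truth side by side).

    The grayscale slice is blended with a fixed per-class color palette at
    alpha 0.4; pixel output is deterministic given the inputs.
    """
    import matplotlib.image as mpimg

    if tuple(mask.shape) != tuple(sample.spatial_shape):
        raise ValidationError("mask is not aligned to the sample grid")
    if truth is not None and truth.shape != mask.shape:
        raise ValidationError("truth is not aligned to the mask")
    image = sample.image[..., 0]
    ndim = image.ndim
    if ndim == 2:
        indices = [None]
    else:
        depth = image.shape[axis]
        if slice_index == "all":
            indices = list(range(depth))
        else:
            if not 0 <= int(slice_index) < depth:
                raise ValidationError(
                    f"slice {slice_index} out of range [0, {depth})")
            indices = [int(slice_index)]

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for idx in indices:
        if idx is None:
            gray, mslice = image, mask
            tslice = truth
            name = "overlay.png"
        else:
            slicer = tuple(idx if a == axis else slice(None) for a in range(ndim))
            gray, mslice = image[slicer], mask[slicer]
            tslice = truth[slicer] if truth is not None else None
            name = f"overlay_{idx:03d}.png"
        panel = _render_slice(gray, mslice)
        if tslice is not None:
            panel = np.concatenate([_render_slice(gray, tslice), panel], axis=1)
        path = os.path.join(out_dir, name)
        mpimg.imsave(path, panel)
        paths.append(path)
    return paths
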