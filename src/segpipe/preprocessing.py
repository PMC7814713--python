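"""Per-sample preprocessing: clipping, resampling, normalization, one-hot.

Subfunctions run in a fixed order — clip, then resample to the target
spacing, then normalize — so that interpolation cannot re-create
out-of-range intensities and normalization statistics describe the grid the
model actually sees.  Label masks are always resampled nearest-neighbour.

Normalization statistics are computed per channel.  The z-score uses the
population (``n``) standard deviation; a constant channel maps to zeros.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ValidationError

NORMALIZATION_MODES = ("zscore", "minmax01", "minmax11", "none")


@dataclasses.dataclass
class PreprocSpec:
    """Preprocessing configuration for one pipeline.

    clip_range
        Optional ``(lo, hi)`` intensity window (e.g. a CT Hounsfield window);
        values outside are clipped to the bounds.
    normalization
        One of ``zscore``, ``minmax01``, ``minmax11``, ``none``.
    target_spacing
        Optional per-axis voxel size (mm) to resample every sample to.
    n_classes
        Number of segmentation classes C (>= 2).
    interpolation_order
        Spline order for image resampling (labels are always order 0).
    """

    clip_range: Optional[Tuple[float, float]] = None
    normalization: str = "zscore"
    target_spacing: Optional[Tuple[float, ...]] = None
    n_classes: int = 2
    interpolation_order: int = 3

    def __post_init__(self) -> None:
        if self.clip_range is not None:
            lo, hi = self.clip_range
            if not lo < hi:
                raise ValidationError(f"clip range requires lo < hi, got ({lo}, {hi})")
        if self.normalization not in NORMALIZATION_MODES:
            raise ConfigurationError(
                f"unknown normalization mode {self.normalization!r}; "
                f"choose from {NORMALIZATION_MODES}"
            )
        if self.target_spacing is not None and any(t <= 0 for t in self.target_spacing):
            raise ValidationError("target_spacing entries must be > 0")
        if self.n_classes < 2:
            raise ValidationError(f"n_classes must be >= 2, got {self.n_classes}")
        if not 0 <= self.interpolation_order <= 5:
            raise ConfigurationError("interpolation_order must be in [0, 5]")


@dataclasses.dataclass(frozen=True)
class GridRecord:
    """The pre-resampling grid, kept so predictions can be restored to it."""

    pre_resample_shape: Tuple[int, ...]
    pre_resample_spacing: Tuple[float, ...]

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.pre_resample_shape):
            raise ValidationError("pre_resample_shape entries must be >= 1")
        if any(s <= 0 for s in self.pre_resample_spacing):
            raise ValidationError("pre_resample_spacing entries must be > 0")


def clip_intensities(image: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Clip intensities into ``[lo, hi]``; values inside the window pass through."""
    if not lo < hi:
        raise ValidationError(f"clip range requires lo < hi, got ({lo}, {hi})")
    return np.clip(image, lo, hi)


def normalize(image: np.ndarray, mode: str) -> np.ndarray:
    """Normalize intensities per channel (channel axis last)."""
    if mode not in NORMALIZATION_MODES:
        raise ConfigurationError(
            f"unknown normalization mode {mode!r}; choose from {NORMALIZATION_MODES}"
        )
    if image.size == 0:
        raise ValidationError("cannot normalize an empty image")
    if mode == "none":
        return np.asarray(image, dtype=np.float32)

    x = np.asarray(image, dtype=np.float64)
    spatial_axes = tuple(range(x.ndim - 1))
    if mode == "zscore":
        mean = x.mean(axis=spatial_axes, keepdims=True)
        sd = x.std(axis=spatial_axes, keepdims=True)  # population sd
        out = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    else:
        lo = x.min(axis=spatial_axes, keepdims=True)
        hi = x.max(axis=spatial_axes, keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        out = np.where(hi > lo, (x - lo) / span, 0.0)
        if mode == "minmax11":
            out = out * 2.0 - 1.0
    return out.astype(np.float32)


def resampled_shape(shape: Sequence[int], spacing: Sequence[float],
                    target: Sequence[float]) -> Tuple[int, ...]:
    """Output shape of resampling: ``round(shape * spacing / target)``, min 1."""
    return tuple(
        max(1, int(round(s * sp / t))) for s, sp, t in zip(shape, spacing, target)
    )


def resample_to_spacing(
    image: np.ndarray,
    segmentation: Optional[np.ndarray],
    spacing: Sequence[float],
    target: Sequence[float],
    order: int = 3,
) -> Tuple[np.ndarray, Optional[np.ndarray], GridRecord]:
    """Resample image (spline) and mask (nearest-neighbour) to a target spacing.

    Returns the resampled arrays and a :class:`GridRecord` of the source grid.
    """
    spacing = tuple(float(s) for s in spacing)
    target = tuple(float(t) for t in target)
    if any(s <= 0 for s in spacing) or any(t <= 0 for t in target):
        raise ValidationError("spacing and target spacing must be > 0")
    spatial_shape = image.shape[:-1]
    if len(spacing) != len(spatial_shape) or len(target) != len(spatial_shape):
        raise ValidationError("spacing/target length must match the spatial rank")

    new_shape = resampled_shape(spatial_shape, spacing, target)
    record = GridRecord(tuple(spatial_shape), spacing)

    zoom = [n / o for n, o in zip(new_shape, spatial_shape)] + [1.0]
    out_image = ndimage.zoom(
        np.asarray(image, dtype=np.float32), zoom, order=order, mode="nearest"
    )
    assert out_image.shape[:-1] == new_shape

    out_seg = None
    if segmentation is not None:
        out_seg = ndimage.zoom(segmentation, zoom[:-1], order=0, mode="nearest")
        assert out_seg.shape == new_shape
    return out_image, out_seg, record


def restore_to_original_grid(mask: np.ndarray, record: GridRecord) -> np.ndarray:
    """Resample an integer mask back onto the pre-resampling grid (nearest)."""
    if tuple(mask.shape) == tuple(record.pre_resample_shape):
        return mask.copy()
    zoom = [n / o for n, o in zip(record.pre_resample_shape, mask.shape)]
    out = ndimage.zoom(mask, zoom, order=0, mode="nearest")
    assert out.shape == tuple(record.pre_resample_shape)
    return out


def one_hot_encode(segmentation: np.ndarray, n_classes: int) -> np.ndarray:
    """Encode integer labels as a binary array with a trailing class axis."""
    seg = np.asarray(segmentation)
    if not np.issubdtype(seg.dtype, np.integer):
        raise ValidationError("segmentation must be an integer array")
    if seg.size:
        lo, hi = int(seg.min()), int(seg.max())
        if lo < 0 or hi >= n_classes:
            raise ValidationError(
                f"labels must lie in [0, {n_classes}), found range [{lo}, {hi}]"
            )
    return np.eye(n_classes, dtype=np.float32)[seg]


def one_hot_decode(probabilities: np.ndarray) -> np.ndarray:
    """Per-voxel argmax over the trailing class axis; ties go to the lower class."""
    probs = np.asarray(probabilities)
    if probs.ndim < 1 or probs.shape[-1] < 2:
        raise ValidationError("need a trailing class axis of size >= 2")
    return np.argmax(probs, axis=-1).astype(np.int32)


def preprocess_sample(image: np.ndarray, segmentation: Optional[np.ndarray],
                      spacing: Sequence[float], spec: PreprocSpec
                      ) -> Tuple[np.ndarray, Optional[np.ndarray], GridRecord]:
    """Apply the full chain clip -> resample -> normalize to one sample."""
    if spec.clip_range is not None:
        image = clip_intensities(image, *spec.clip_range)
    if spec.target_spacing is not None:
        image, segmentation, record = resample_to_spacing(
            image, segmentation, spacing, spec.target_spacing,
            order=spec.interpolation_order,
        )
    else:
        record = GridRecord(tuple(image.shape[:-1]), tuple(float(s) for s in spacing))
    image = normalize(image, spec.normalization)
    return image, segmentation, record
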