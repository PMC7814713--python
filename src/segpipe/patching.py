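"""Patch-wise analysis: grids, extraction, blank filtering, crops, merging.

Windows are 0-based and half-open: offset ``o`` covers ``[o, o + P)``.  The
grid strides by ``S = P - O`` per axis and, when the last regular window
stops short of the boundary, appends a final edge-aligned offset at
``shape - P`` so every voxel is covered without padding the volume.  This
last-window policy changes patch counts relative to padding schemes and is
therefore part of the documented contract.

Overlapping patch predictions are merged by the arithmetic mean of all
windows covering a voxel, accumulated in double precision.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import List, Sequence, Tuple

import numpy as np

from .errors import CoverageError, ValidationError

ANALYSIS_MODES = ("fullimage", "patchwise-grid", "patchwise-crop")


@dataclasses.dataclass
class PatchConfig:
    """Patch shape P, per-axis overlap O (0 <= O < P), and the analysis mode."""

    patch_shape: Tuple[int, ...] = (128, 128, 128)
    overlap: Tuple[int, ...] = (0, 0, 0)
    skip_blanks: bool = True
    analysis: str = "patchwise-grid"

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSIS_MODES:
            raise ValidationError(
                f"unknown analysis mode {self.analysis!r}; choose from {ANALYSIS_MODES}"
            )
        if len(self.patch_shape) != len(self.overlap):
            raise ValidationError("patch_shape and overlap must have equal rank")
        for axis, (p, o) in enumerate(zip(self.patch_shape, self.overlap)):
            if p < 1:
                raise ValidationError(f"patch_shape[{axis}] must be >= 1")
            if not 0 <= o < p:
                raise ValidationError(
                    f"overlap[{axis}]={o} must satisfy 0 <= overlap < patch_shape={p}"
                )

    @property
    def stride(self) -> Tuple[int, ...]:
        return tuple(p - o for p, o in zip(self.patch_shape, self.overlap))


@dataclasses.dataclass
class PatchSet:
    """Patches cut from one volume together with their source offsets."""

    offsets: List[Tuple[int, ...]]
    patches: np.ndarray  # (n_patches, *patch_shape, channels)
    source_shape: Tuple[int, ...]

    def __len__(self) -> int:
        return len(self.offsets)


def compute_patch_grid(shape: Sequence[int], patch_shape: Sequence[int],
                       overlap: Sequence[int]) -> List[Tuple[int, ...]]:
    """Deterministic covering grid of window offsets, lexicographically ordered."""
    shape = tuple(int(s) for s in shape)
    cfg = PatchConfig(tuple(int(p) for p in patch_shape), tuple(int(o) for o in overlap))
    for axis, (s, p) in enumerate(zip(shape, cfg.patch_shape)):
        if p > s:
            raise ValidationError(
                f"patch larger than volume on axis {axis} ({p} > {s}); "
                "pad the input or use fullimage analysis"
            )
    per_axis: List[List[int]] = []
    for s, p, stride in zip(shape, cfg.patch_shape, cfg.stride):
        offs = list(range(0, s - p + 1, stride))
        if offs[-1] != s - p:  # edge-aligned final window
            offs.append(s - p)
        per_axis.append(offs)
    return [tuple(o) for o in itertools.product(*per_axis)]


def extract_patches(image: np.ndarray, offsets: Sequence[Tuple[int, ...]],
                    patch_shape: Sequence[int]) -> PatchSet:
    """Cut the windows at ``offsets``; the channel axis is carried through."""
    spatial_shape = image.shape[:-1]
    p = tuple(patch_shape)
    patches = np.empty((len(offsets),) + p + (image.shape[-1],), dtype=image.dtype)
    for i, off in enumerate(offsets):
        slicer = tuple(slice(o, o + pp) for o, pp in zip(off, p))
        if any(o < 0 or o + pp > s for o, pp, s in zip(off, p, spatial_shape)):
            raise ValidationError(f"window at offset {off} exceeds volume {spatial_shape}")
        patches[i] = image[slicer]
    return PatchSet(list(map(tuple, offsets)), patches, tuple(spatial_shape))


def filter_blank_patches(patchset_image: PatchSet, patchset_seg: PatchSet,
                         background_class: int = 0) -> Tuple[PatchSet, PatchSet]:
    """Drop aligned patch pairs whose label window is entirely background."""
    if patchset_image.offsets != patchset_seg.offsets:
        raise ValidationError("image and segmentation patch sets are not aligned")
    keep = [
        i for i in range(len(patchset_seg))
        if np.any(patchset_seg.patches[i] != background_class)
    ]
    return (
        PatchSet([patchset_image.offsets[i] for i in keep],
                 patchset_image.patches[keep], patchset_image.source_shape),
        PatchSet([patchset_seg.offsets[i] for i in keep],
                 patchset_seg.patches[keep], patchset_seg.source_shape),
    )


def random_crop(image: np.ndarray, segmentation: np.ndarray,
                patch_shape: Sequence[int],
                rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Crop image and mask at one uniformly drawn valid offset."""
    spatial_shape = image.shape[:-1]
    p = tuple(patch_shape)
    if any(pp > s for pp, s in zip(p, spatial_shape)):
        raise ValidationError(
            f"patch {p} larger than volume {tuple(spatial_shape)}"
        )
    offset = tuple(int(rng.integers(0, s - pp + 1)) for s, pp in zip(spatial_shape, p))
    slicer = tuple(slice(o, o + pp) for o, pp in zip(offset, p))
    return image[slicer], segmentation[slicer]


def merge_overlapping_predictions(prob_patches: PatchSet, source_shape: Sequence[int],
                                  n_classes: int) -> np.ndarray:
    """Mean-merge per-class probability patches back into one volume.

    Each voxel's class-c value is the arithmetic mean over all windows that
    contain the voxel (sum accumulator divided by count accumulator), which
    makes the result invariant to patch order up to double rounding.
    """
    source_shape = tuple(source_shape)
    acc = np.zeros(source_shape + (n_classes,), dtype=np.float64)
    count = np.zeros(source_shape, dtype=np.int64)
    if not np.all(np.isfinite(prob_patches.patches)):
        raise ValidationError("probabilities must be finite")
    patch_shape = prob_patches.patches.shape[1:-1]
    for off, patch in zip(prob_patches.offsets, prob_patches.patches):
        slicer = tuple(slice(o, o + pp) for o, pp in zip(off, patch_shape))
        acc[slicer] += patch
        count[slicer] += 1
    if np.any(count == 0):
        uncovered = int((count == 0).sum())
        raise CoverageError(f"{uncovered} voxels not covered by any patch window")
    return acc / count[..., np.newaxis]
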