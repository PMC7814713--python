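"""Synthetic labeled phantoms for exercising the pipeline end to end.

Each phantom is a dominant background with an "organ" ellipsoid (class 1)
at a random interior position and, for three-class problems, a smaller
"lesion" ellipsoid (class 2) fully contained in the organ — the same
background/organ/lesion class structure as abdominal CT tumor-segmentation
datasets, at desk scale.  Voxel intensities are the class mean plus
independent Gaussian noise, so with zero noise the classes are exactly
threshold-separable and with small noise nearly so; this bounds what a
trained segmentation model can reach on phantom data.

Defaults (32^3 volume, class means 0 / 0.5 / 1.0, noise sd 0.05, organ
semi-axes 6-10 voxels, lesion semi-axes 2-4 voxels, unit spacing) are
chosen so that a tiny U-Net separates the classes in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Dict, List, Optional, Tuple

import numpy as np

from .data_io import (DEFAULT_IMAGE_NAME, DEFAULT_SEG_NAME, NiftiInterface,
                      Sample, save_nifti_segmentation)
from .errors import ValidationError

import nibabel as nib


@dataclasses.dataclass
class PhantomConfig:
    shape: Tuple[int, ...] = (32, 32, 32)
    n_classes: int = 3
    class_means: Tuple[float, ...] = (0.0, 0.5, 1.0)
    noise_sd: float = 0.05
    organ_semiaxes: Tuple[int, int] = (6, 10)
    lesion_semiaxes: Tuple[int, int] = (2, 4)
    spacing: Tuple[float, ...] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValidationError("n_classes must be 2 or 3")
        means = self.class_means[: self.n_classes]
        if any(a >= b for a, b in zip(means, means[1:])):
            raise ValidationError("class means must be strictly increasing")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if 2 * self.organ_semiaxes[1] >= min(self.shape):
            raise ValidationError("organ semi-axes too large for the volume")
        if self.lesion_semiaxes[1] > self.organ_semiaxes[0]:
            raise ValidationError("lesion semi-axes must fit inside the organ")
        if len(self.spacing) != len(self.shape):
            raise ValidationError("spacing rank must match shape rank")


def _ellipsoid_mask(shape: Tuple[int, ...], center: np.ndarray,
                    semiaxes: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    dist = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return dist <= 1.0


def generate_phantom(config: PhantomConfig,
                     rng: Optional[np.random.Generator] = None,
                     sample_id: str = "phantom") -> Sample:
    """Generate one labeled phantom; exact class counts land in ``meta``."""
    rng = rng or np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    ndim = len(shape)

    organ_ax = rng.uniform(config.organ_semiaxes[0], config.organ_semiaxes[1],
                           size=ndim)
    lo = np.ceil(organ_ax)
    hi = np.array(shape) - 1 - np.ceil(organ_ax)
    organ_center = rng.uniform(lo, hi)
    mask = np.zeros(shape, dtype=np.int32)
    organ = _ellipsoid_mask(shape, organ_center, organ_ax)
    mask[organ] = 1

    if config.n_classes == 3:
        lesion_ax = rng.uniform(config.lesion_semiaxes[0],
                                config.lesion_semiaxes[1], size=ndim)
        placed = False
        for _ in range(100):
            # rejection-sample a lesion center until it fits inside the organ
            frac = rng.uniform(-0.5, 0.5, size=ndim)
            lesion_center = organ_center + frac * organ_ax
            lesion = _ellipsoid_mask(shape, lesion_center, lesion_ax)
            # require a strictly interior lesion: a one-voxel margin of organ
            halo = _ellipsoid_mask(shape, lesion_center, lesion_ax + 1.0)
            if lesion.any() and not np.any(halo & ~organ):
                placed = True
                break
        if not placed:
            raise ValidationError("could not place the lesion inside the organ")
        mask[lesion] = 2

    means = np.asarray(config.class_means[: config.n_classes], dtype=np.float64)
    image = means[mask]
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=shape)
    image = image.astype(np.float32)[..., np.newaxis]

    counts = np.bincount(mask.ravel(), minlength=config.n_classes)
    return Sample(
        id=sample_id, image=image, segmentation=mask,
        spacing=tuple(config.spacing),
        meta={"class_counts": {int(c): int(n) for c, n in enumerate(counts)}},
    )


def generate_phantom_dataset(root: str, n: int, config: PhantomConfig,
                             seed: int = 0) -> NiftiInterface:
    """Write ``n`` phantoms in the standard NIfTI dataset layout.

    A ``manifest.tsv`` of ground-truth class counts is written alongside.
    """
    rng = np.random.default_rng(seed)
    os.makedirs(root, exist_ok=True)
    lines = ["sample_id\t" + "\t".join(f"class_{c}" for c in range(config.n_classes))]
    for i in range(n):
        sid = f"phantom_{i:03d}"
        sample = generate_phantom(config, rng, sample_id=sid)
        sample_dir = os.path.join(root, sid)
        os.makedirs(sample_dir, exist_ok=True)

        affine = np.eye(4)
        for axis, zoom in enumerate(sample.spacing[:3]):
            affine[axis, axis] = zoom
        img = nib.Nifti1Image(sample.image[..., 0], affine)
        img.header.set_zooms(sample.spacing)
        nib.save(img, os.path.join(sample_dir, DEFAULT_IMAGE_NAME))
        save_nifti_segmentation(sample.segmentation, sample,
                                os.path.join(sample_dir, DEFAULT_SEG_NAME))
        counts = sample.meta["class_counts"]
        lines.append(sid + "\t" + "\t".join(
            str(counts[c]) for c in range(config.n_classes)))
    with open(os.path.join(root, "manifest.tsv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return NiftiInterface(root)


def generate_phantom_samples(n: int, config: PhantomConfig,
                             seed: int = 0) -> List[Sample]:
    """In-memory convenience variant of :func:`generate_phantom_dataset`."""
    rng = np.random.default_rng(seed)
    return [generate_phantom(config, rng, sample_id=f"phantom_{i:03d}")
            for i in range(n)]
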