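"""Training-time stochastic augmentation of image/label pairs.

Spatial operators (mirror, rotation, scaling, elastic deformation) apply the
same geometric map to image and mask — the image interpolated linearly, the
mask nearest-neighbour, both with edge-value boundary fill — so the label
set can never grow.  Intensity operators (brightness, contrast, gamma,
Gaussian noise) touch the image only.  Translations are realized implicitly
by random cropping in the patching module rather than as a resampling
operator.

Each enabled operator fires independently with its configured probability.
All randomness flows through one :class:`numpy.random.Generator`, so a fixed
seed reproduces outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ValidationError


@dataclasses.dataclass
class AugmentSpec:
    """Per-operator firing probabilities and parameter ranges.

    Defaults are conservative: probability 0.15 per operator, rotations
    within +-15 degrees, scaling 0.85-1.15, gamma 0.7-1.5, brightness offsets
    within +-0.1 image standard deviations, contrast 0.75-1.25, elastic
    displacement up to 2 voxels after Gaussian smoothing with width 8, and
    additive noise with sd up to 0.1.  All overridable from the config file.
    """

    mirror_p: float = 0.15
    rotate_p: float = 0.15
    scale_p: float = 0.15
    elastic_p: float = 0.15
    brightness_p: float = 0.15
    contrast_p: float = 0.15
    gamma_p: float = 0.15
    noise_p: float = 0.15
    rotation_range: Tuple[float, float] = (-15.0, 15.0)
    scale_range: Tuple[float, float] = (0.85, 1.15)
    elastic_amplitude: float = 2.0
    elastic_sigma: float = 8.0
    brightness_range: Tuple[float, float] = (-0.1, 0.1)  # fraction of image sd
    contrast_range: Tuple[float, float] = (0.75, 1.25)
    gamma_range: Tuple[float, float] = (0.7, 1.5)
    noise_sd_range: Tuple[float, float] = (0.0, 0.1)

    def __post_init__(self) -> None:
        for name in ("mirror_p", "rotate_p", "scale_p", "elastic_p",
                     "brightness_p", "contrast_p", "gamma_p", "noise_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} must lie in [0, 1]")
        for name in ("rotation_range", "scale_range", "brightness_range",
                     "contrast_range", "gamma_range", "noise_sd_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must be ordered (lo <= hi)")
        if self.scale_range[0] <= 0 or self.gamma_range[0] <= 0 or self.contrast_range[0] <= 0:
            raise ConfigurationError("scale, gamma and contrast ranges must be > 0")
        if self.elastic_amplitude < 0 or self.elastic_sigma <= 0:
            raise ConfigurationError("elastic amplitude must be >= 0 and sigma > 0")

    @classmethod
    def disabled(cls) -> "AugmentSpec":
        return cls(mirror_p=0, rotate_p=0, scale_p=0, elastic_p=0,
                   brightness_p=0, contrast_p=0, gamma_p=0, noise_p=0)


def _check_pair(image: np.ndarray, segmentation: Optional[np.ndarray]) -> None:
    if segmentation is not None and tuple(segmentation.shape) != tuple(image.shape[:-1]):
        raise ValidationError(
            f"segmentation shape {segmentation.shape} does not match image "
            f"spatial shape {image.shape[:-1]}"
        )


# ---------------------------------------------------------------- spatial ops

def op_mirror(image: np.ndarray, segmentation: Optional[np.ndarray],
              axes: Sequence[int]) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Reverse the chosen spatial axes of image and mask."""
    _check_pair(image, segmentation)
    out_img = np.flip(image, axis=tuple(axes)).copy() if axes else image.copy()
    out_seg = None
    if segmentation is not None:
        out_seg = (np.flip(segmentation, axis=tuple(axes)).copy()
                   if axes else segmentation.copy())
    return out_img, out_seg


def _per_channel(image: np.ndarray, fn) -> np.ndarray:
    out = np.empty_like(image, dtype=np.float32)
    for c in range(image.shape[-1]):
        out[..., c] = fn(np.asarray(image[..., c], dtype=np.float32))
    return out


def op_rotate(image: np.ndarray, segmentation: Optional[np.ndarray],
              angle: float, plane: Tuple[int, int] = (0, 1)
              ) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Rotate by ``angle`` degrees in one spatial plane, shape preserved."""
    _check_pair(image, segmentation)
    out_img = _per_channel(
        image, lambda ch: ndimage.rotate(ch, angle, axes=plane, reshape=False,
                                         order=1, mode="nearest"))
    out_seg = None
    if segmentation is not None:
        out_seg = ndimage.rotate(segmentation, angle, axes=plane, reshape=False,
                                 order=0, mode="nearest")
    return out_img, out_seg


def op_scale(image: np.ndarray, segmentation: Optional[np.ndarray],
             factor: float) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Zoom about the volume centre by ``factor``; output shape unchanged."""
    if factor <= 0:
        raise ValidationError(f"scale factor must be > 0, got {factor}")
    _check_pair(image, segmentation)
    ndim = image.ndim - 1
    center = (np.asarray(image.shape[:-1], dtype=np.float64) - 1) / 2.0
    matrix = np.eye(ndim) / factor
    offset = center - matrix @ center

    def warp(arr, order):
        return ndimage.affine_transform(arr, matrix, offset=offset, order=order,
                                        mode="nearest")

    out_img = _per_channel(image, lambda ch: warp(ch, 1))
    out_seg = warp(segmentation, 0) if segmentation is not None else None
    return out_img, out_seg


def op_elastic(image: np.ndarray, segmentation: Optional[np.ndarray],
               displacement_field: np.ndarray
               ) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Warp through a smooth per-axis displacement field (voxels)."""
    _check_pair(image, segmentation)
    ndim = image.ndim - 1
    if displacement_field.shape != (ndim,) + tuple(image.shape[:-1]):
        raise ValidationError(
            "displacement field must have shape (ndim, *spatial_shape)"
        )
    grid = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in image.shape[:-1]],
                       indexing="ij")
    coords = [g + d for g, d in zip(grid, displacement_field)]

    out_img = _per_channel(
        image, lambda ch: ndimage.map_coordinates(ch, coords, order=1, mode="nearest"))
    out_seg = None
    if segmentation is not None:
        out_seg = ndimage.map_coordinates(segmentation, coords, order=0, mode="nearest")
    return out_img, out_seg


def make_displacement_field(spatial_shape: Sequence[int], amplitude: float,
                            sigma: float, rng: np.random.Generator) -> np.ndarray:
    """White Gaussian noise per axis, Gaussian-smoothed, scaled to ``amplitude``."""
    fields = []
    for _ in spatial_shape:
        noise = rng.standard_normal(tuple(spatial_shape))
        smooth = ndimage.gaussian_filter(noise, sigma)
        peak = np.abs(smooth).max()
        fields.append(smooth * (amplitude / peak) if peak > 0 else smooth)
    return np.stack(fields)


# -------------------------------------------------------------- intensity ops

def op_brightness(image: np.ndarray, offset: float) -> np.ndarray:
    """Add a constant intensity offset."""
    return np.asarray(image, dtype=np.float32) + np.float32(offset)


def op_contrast(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale intensities about the image mean; the mean is preserved."""
    if factor <= 0:
        raise ValidationError(f"contrast factor must be > 0, got {factor}")
    x = np.asarray(image, dtype=np.float64)
    mean = x.mean()
    return (mean + factor * (x - mean)).astype(np.float32)


def op_gamma(image: np.ndarray, exponent: float) -> np.ndarray:
    """Gamma-map min-max-normalized intensities, then restore the range."""
    if exponent <= 0:
        raise ValidationError(f"gamma exponent must be > 0, got {exponent}")
    x = np.asarray(image, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return x.astype(np.float32)
    return (((x - lo) / (hi - lo)) ** exponent * (hi - lo) + lo).astype(np.float32)


def op_noise(image: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Add independent zero-mean Gaussian noise with standard deviation ``sd``."""
    if sd < 0:
        raise ValidationError(f"noise sd must be >= 0, got {sd}")
    x = np.asarray(image, dtype=np.float32)
    if sd == 0:
        return x.copy()
    return x + rng.normal(0.0, sd, size=x.shape).astype(np.float32)


# ------------------------------------------------------------------- pipeline

def augment_pair(image: np.ndarray, segmentation: np.ndarray, spec: AugmentSpec,
                 rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Apply the enabled operators, each firing with its own probability.

    The operator order is fixed (mirror, rotate, scale, elastic, brightness,
    contrast, gamma, noise) and all draws come from ``rng``, so a fixed seed
    reproduces the output bit-exactly.
    """
    _check_pair(image, segmentation)
    img = np.asarray(image, dtype=np.float32).copy()
    seg = segmentation.copy()
    ndim = img.ndim - 1

    if spec.mirror_p > 0 and rng.random() < spec.mirror_p:
        axes = [a for a in range(ndim) if rng.random() < 0.5]
        img, seg = op_mirror(img, seg, axes)
    if spec.rotate_p > 0 and rng.random() < spec.rotate_p:
        planes = [(a, b) for a in range(ndim) for b in range(a + 1, ndim)]
        plane = planes[int(rng.integers(len(planes)))]
        angle = float(rng.uniform(*spec.rotation_range))
        img, seg = op_rotate(img, seg, angle, plane)
    if spec.scale_p > 0 and rng.random() < spec.scale_p:
        img, seg = op_scale(img, seg, float(rng.uniform(*spec.scale_range)))
    if spec.elastic_p > 0 and rng.random() < spec.elastic_p:
        amplitude = float(rng.uniform(0.0, spec.elastic_amplitude))
        field = make_displacement_field(img.shape[:-1], amplitude,
                                        spec.elastic_sigma, rng)
        img, seg = op_elastic(img, seg, field)
    if spec.brightness_p > 0 and rng.random() < spec.brightness_p:
        offset = float(rng.uniform(*spec.brightness_range)) * float(img.std())
        img = op_brightness(img, offset)
    if spec.contrast_p > 0 and rng.random() < spec.contrast_p:
        img = op_contrast(img, float(rng.uniform(*spec.contrast_range)))
    if spec.gamma_p > 0 and rng.random() < spec.gamma_p:
        img = op_gamma(img, float(rng.uniform(*spec.gamma_range)))
    if spec.noise_p > 0 and rng.random() < spec.noise_p:
        img = op_noise(img, float(rng.uniform(*spec.noise_sd_range)), rng)
    return img, seg
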