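"""Data I/O: the abstract data-interface contract and a NIfTI backend.

A dataset is a directory with one sub-directory per sample, each holding an
image file and (optionally) an integer segmentation mask::

    <root>/<sample_id>/imaging.nii.gz
    <root>/<sample_id>/segmentation.nii.gz

File names are configurable.  Any other storage scheme can be supported by
registering a custom :class:`DataInterface` implementation under a name and
selecting it from the pipeline configuration.

Only the per-axis voxel sizes (the header "zooms", e.g. slice thickness) are
consumed from the NIfTI header; the rotation part of the affine is ignored
and arrays are processed in stored voxel order.
"""

from __future__ import annotations

import abc
import dataclasses
import os
from typing import Any, Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, FormatError, ValidationError

DEFAULT_IMAGE_NAME = "imaging.nii.gz"
DEFAULT_SEG_NAME = "segmentation.nii.gz"


@dataclasses.dataclass
class Sample:
    """One subject: image array, optional label mask, and grid metadata.

    The image always carries an explicit trailing channel axis (size 1 for
    scalar modalities) so downstream shapes are uniform.  ``original_shape``
    and ``original_spacing`` record the grid at load time so that a predicted
    mask can be restored to it after resampling.
    """

    id: str
    image: np.ndarray
    segmentation: Optional[np.ndarray] = None
    spacing: Tuple[float, ...] = (1.0,)
    original_shape: Tuple[int, ...] = ()
    original_spacing: Tuple[float, ...] = ()
    meta: Dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.ndim < 3:
            raise ValidationError(
                f"sample {self.id!r}: image must have >= 2 spatial axes plus a "
                f"channel axis, got ndim={self.image.ndim}"
            )
        spatial = self.spatial_shape
        if not self.original_shape:
            self.original_shape = spatial
        if len(self.spacing) != len(spatial):
            raise ValidationError(
                f"sample {self.id!r}: spacing has {len(self.spacing)} entries "
                f"for {len(spatial)} spatial axes"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"sample {self.id!r}: spacing must be positive")
        if not self.original_spacing:
            self.original_spacing = tuple(self.spacing)
        if self.segmentation is not None:
            if tuple(self.segmentation.shape) != spatial:
                raise ValidationError(
                    f"sample {self.id!r}: segmentation shape "
                    f"{self.segmentation.shape} != image spatial shape {spatial}"
                )
            if not np.issubdtype(self.segmentation.dtype, np.integer):
                raise ValidationError(
                    f"sample {self.id!r}: segmentation dtype must be integer"
                )
            if self.segmentation.size and self.segmentation.min() < 0:
                raise ValidationError(
                    f"sample {self.id!r}: segmentation labels must be >= 0"
                )

    @property
    def spatial_shape(self) -> Tuple[int, ...]:
        return tuple(self.image.shape[:-1])

    @property
    def n_channels(self) -> int:
        return int(self.image.shape[-1])


class DataInterface(abc.ABC):
    """Contract every storage backend must honour.

    ``load`` must be pure (repeated calls yield identical arrays) and
    ``save_prediction`` followed by a load of the written file must
    round-trip the mask voxel-exactly.
    """

    @abc.abstractmethod
    def list_samples(self) -> List[str]:
        """Return the ordered sample identifiers of the dataset."""

    @abc.abstractmethod
    def load(self, sample_id: str) -> Sample:
        """Load one sample (image plus segmentation when present)."""

    @abc.abstractmethod
    def save_prediction(self, sample_id: str, mask: np.ndarray,
                        sample: Sample, path: str) -> str:
        """Write a predicted integer mask on the sample's original grid."""


def _ensure_channel_axis(data: np.ndarray) -> np.ndarray:
    if data.ndim in (2, 3):
        return data[..., np.newaxis]
    if data.ndim == 4:
        return data
    raise FormatError(f"expected a 2D/3D (optionally multi-channel) image, got ndim={data.ndim}")


def _load_nifti_array(path: str) -> Tuple[np.ndarray, Tuple[float, ...]]:
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[: min(3, data.ndim)])
    return data, zooms


def load_nifti_sample(path: str, with_segmentation: bool = False,
                      image_name: str = DEFAULT_IMAGE_NAME,
                      seg_name: str = DEFAULT_SEG_NAME,
                      sample_id: Optional[str] = None) -> Sample:
    """Load a NIfTI sample from a sample directory or a single image file.

    ``path`` may be a per-sample directory (KiTS19-style layout, file names
    configurable) or a direct ``.nii``/``.nii.gz`` image path, in which case
    a segmentation is looked up as a sibling file named ``seg_name``.
    """
    if os.path.isdir(path):
        image_path = os.path.join(path, image_name)
        seg_path = os.path.join(path, seg_name)
        sid = sample_id or os.path.basename(os.path.normpath(path))
    else:
        image_path = path
        seg_path = os.path.join(os.path.dirname(path), seg_name)
        sid = sample_id or os.path.basename(path).split(".")[0]

    data, zooms = _load_nifti_array(image_path)
    image = _ensure_channel_axis(np.asarray(data, dtype=np.float32))
    spacing = zooms[: image.ndim - 1]

    segmentation = None
    if with_segmentation:
        if not os.path.exists(seg_path):
            raise IOError(f"segmentation requested but {seg_path} does not exist")
        seg_data, _ = _load_nifti_array(seg_path)
        segmentation = np.asarray(np.rint(seg_data), dtype=np.int32)
        if segmentation.shape != image.shape[:-1]:
            raise ValidationError(
                f"segmentation shape {segmentation.shape} does not match image "
                f"spatial shape {image.shape[:-1]}"
            )

    return Sample(
        id=sid,
        image=image,
        segmentation=segmentation,
        spacing=spacing,
        original_shape=tuple(image.shape[:-1]),
        original_spacing=spacing,
    )


def save_nifti_segmentation(mask: np.ndarray, sample: Sample, path: str) -> str:
    """Write an integer label mask as NIfTI on the sample's original grid.

    The affine is a plain scaling matrix carrying the original voxel
    spacing; no further source metadata is copied.
    """
    mask = np.asarray(mask)
    if tuple(mask.shape) != tuple(sample.original_shape):
        raise ValidationError(
            f"mask shape {mask.shape} != sample original shape {sample.original_shape}"
        )
    if not np.issubdtype(mask.dtype, np.integer):
        rounded = np.rint(mask)
        if not np.allclose(mask, rounded):
            raise ValidationError("mask must contain integer labels")
        mask = rounded
    mask = mask.astype(np.int16 if mask.size == 0 or mask.max() < 2 ** 15 else np.int32)

    affine = np.eye(4)
    for axis, zoom in enumerate(sample.original_spacing[:3]):
        affine[axis, axis] = zoom
    img = nib.Nifti1Image(mask, affine)
    img.header.set_zooms(sample.original_spacing[: mask.ndim])
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    nib.save(img, path)
    return path


class NiftiInterface(DataInterface):
    """Directory-per-sample NIfTI backend (the bundled default)."""

    def __init__(self, root: str, image_name: str = DEFAULT_IMAGE_NAME,
                 seg_name: str = DEFAULT_SEG_NAME, with_segmentation: bool = True):
        self.root = root
        self.image_name = image_name
        self.seg_name = seg_name
        self.with_segmentation = with_segmentation

    def list_samples(self) -> List[str]:
        if not os.path.isdir(self.root):
            raise IOError(f"dataset root {self.root} does not exist")
        return sorted(
            d for d in os.listdir(self.root)
            if os.path.isdir(os.path.join(self.root, d))
            and os.path.exists(os.path.join(self.root, d, self.image_name))
        )

    def load(self, sample_id: str) -> Sample:
        sample_dir = os.path.join(self.root, sample_id)
        has_seg = self.with_segmentation and os.path.exists(
            os.path.join(sample_dir, self.seg_name)
        )
        return load_nifti_sample(
            sample_dir, with_segmentation=has_seg,
            image_name=self.image_name, seg_name=self.seg_name,
            sample_id=sample_id,
        )

    def save_prediction(self, sample_id: str, mask: np.ndarray,
                        sample: Sample, path: str) -> str:
        return save_nifti_segmentation(mask, sample, path)


class InMemoryInterface(DataInterface):
    """Backend serving samples held in memory; useful for phantoms and tests."""

    def __init__(self, samples: Sequence[Sample]):
        self._samples = {s.id: s for s in samples}

    def list_samples(self) -> List[str]:
        return sorted(self._samples)

    def load(self, sample_id: str) -> Sample:
        if sample_id not in self._samples:
            raise IOError(f"unknown sample id {sample_id!r}")
        s = self._samples[sample_id]
        return Sample(
            id=s.id, image=s.image.copy(),
            segmentation=None if s.segmentation is None else s.segmentation.copy(),
            spacing=tuple(s.spacing), original_shape=tuple(s.original_shape),
            original_spacing=tuple(s.original_spacing), meta=dict(s.meta),
        )

    def save_prediction(self, sample_id: str, mask: np.ndarray,
                        sample: Sample, path: str) -> str:
        return save_nifti_segmentation(mask, sample, path)


_INTERFACE_REGISTRY: Dict[str, DataInterface] = {}
_CONTRACT_METHODS = ("list_samples", "load", "save_prediction")


def register_data_interface(name: str, interface: DataInterface) -> None:
    """Register a backend under a name resolvable from the pipeline config."""
    if name in _INTERFACE_REGISTRY:
        raise ConfigurationError(f"data interface {name!r} is already registered")
    for method in _CONTRACT_METHODS:
        if not callable(getattr(interface, method, None)):
            raise ValidationError(
                f"data interface {name!r} is missing contract method {method!r}"
            )
    _INTERFACE_REGISTRY[name] = interface


def get_data_interface(name: str) -> DataInterface:
    if name not in _INTERFACE_REGISTRY:
        raise ConfigurationError(
            f"unknown data interface {name!r}; registered: {sorted(_INTERFACE_REGISTRY)}"
        )
    return _INTERFACE_REGISTRY[name]


def clear_data_interfaces() -> None:
    """Drop all registered interfaces (test isolation helper)."""
    _INTERFACE_REGISTRY.clear()
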