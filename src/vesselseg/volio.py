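"""NIfTI volume I/O and intensity normalisation.

Axis convention used throughout the package: array axis 0 = sagittal (width),
axis 1 = coronal (height), axis 2 = axial (depth).  Coordinates are 0-based
and voxel-centred with half-open extents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class VolumeFormatError(ValueError):
    """Raised for files that are not readable 3D NIfTI images."""


@dataclass
class Volume:
    """A 3D intensity volume with voxel spacing (mm) and world affine."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"volume data must be 3D, got {self.data.ndim}D shape {self.data.shape}"
            )
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise VolumeFormatError(f"spacing must be positive, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelVolume(Volume):
    """A binary vessel mask sharing its Volume's shape and affine."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise VolumeFormatError(
                f"label values must be binary, found {vals[:5]}"
            )
        self.data = self.data.astype(np.uint8)


def load_volume(path, as_label: bool = False) -> Volume:
    """Load a NIfTI-1 volume; labels are binarised at > 0.5.

    4D images with a trailing singleton axis are squeezed to 3D with a
    warning; any other dimensionality is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        if all(s == 1 for s in data.shape[3:]):
            warnings.warn(
                f"{path.name}: squeezing {data.ndim}D image with singleton "
                "trailing axes to 3D",
                stacklevel=2,
            )
            data = data.reshape(data.shape[:3])
        else:
            raise VolumeFormatError(
                f"{path.name} is {data.ndim}D with shape {data.shape}; expected 3D"
            )
    elif data.ndim < 3:
        raise VolumeFormatError(
            f"{path.name} is {data.ndim}D with shape {data.shape}; expected 3D"
        )
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if as_label:
        return LabelVolume((data > 0.5).astype(np.uint8), spacing, img.affine)
    return Volume(data, spacing, img.affine)


def save_volume(v: Volume, path) -> None:
    """Write a Volume (or LabelVolume) as NIfTI-1, preserving the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = v.data
    if isinstance(v, LabelVolume):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, v.affine)
    img.header.set_zooms(tuple(v.spacing))
    nib.save(img, str(path))


def normalize_minmax(v: Volume) -> Volume:
    """Rescale intensities to [0, 1]; constant volumes map to all zeros."""
    data = v.data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return Volume(out, v.spacing, v.affine)
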