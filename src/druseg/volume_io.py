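"""NIfTI volume and mask containers with metadata-preserving I/O.

HU grids are stored as 32-bit floats after load regardless of on-disk dtype;
masks as 8-bit integers.  Voxel indexing is 0-based with half-open extents,
axis order (x, y, z) as stored in the file.  Orientation is taken from the
NIfTI affine; no resampling or reorientation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple, Union

import nibabel as nib
import numpy as np

__all__ = ["CTVolume", "BinaryMask", "read_nifti", "write_nifti",
           "ValidationError"]


class ValidationError(ValueError):
    """Raised when a grid violates its container's invariants."""


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _check_grid(data: np.ndarray, spacing) -> None:
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D grid, got {data.ndim} axes")
    if min(data.shape) < 1:
        raise ValidationError(f"every axis must have length >= 1: {data.shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be 3 positive reals, got {spacing}")


@dataclass
class CTVolume:
    """A 3D CT grid in Hounsfield units with physical voxel spacing (mm)."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = None
    id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        _check_grid(self.data, self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A {0,1} grid aligned voxel-for-voxel with a :class:`CTVolume`."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = None
    id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.data)
        bad = np.setdiff1d(np.unique(arr), [0, 1])
        if bad.size:
            raise ValidationError(
                f"mask values must be exactly 0 or 1; found {bad[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        _check_grid(self.data, self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


Volume = Union[CTVolume, BinaryMask]


def read_nifti(path, kind: str = "auto") -> Volume:
    """Load a NIfTI-1/2 file as a :class:`CTVolume` or :class:`BinaryMask`.

    Parameters
    ----------
    path : path-like
        File ending in ``.nii`` or ``.nii.gz``.
    kind : {"auto", "image", "mask"}
        ``"mask"`` validates the values against {0, 1}; ``"auto"`` returns a
        mask when the data are integral and {0,1}-valued, else an image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(
            f"{path.name}: expected a 3D image, got {data.ndim} dimensions")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    vol_id = path.name.removesuffix(".gz").removesuffix(".nii")
    if kind == "auto":
        vals = np.unique(data)
        kind = "mask" if np.isin(vals, [0, 1]).all() else "image"
    if kind == "mask":
        return BinaryMask(data, spacing, img.affine, vol_id)
    if kind == "image":
        return CTVolume(data, spacing, img.affine, vol_id)
    raise ValueError(f"unknown kind {kind!r}")


def write_nifti(volume: Volume, path) -> Path:
    """Write a volume or mask to NIfTI, preserving spacing and affine.

    Masks are written as uint8 (bit-exact round-trip); HU grids as float32.
    """
    path = Path(path)
    data = volume.data
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path
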