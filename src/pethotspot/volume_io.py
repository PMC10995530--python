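"""NIfTI input/output and the voxel/world geometry conventions.

Every other module relies on the conventions fixed here:

* voxel indices are 0-based ``(i, j, k)`` triples with ``i`` the
  fastest-varying (x) axis;
* world coordinates are millimetres and refer to voxel *centers*;
* ``world = origin + index * spacing`` component-wise, so anisotropic
  voxels are handled correctly and all distances downstream are
  Euclidean distances in physical space.

Only axis-aligned geometry is modelled: the distance-based biomarkers
computed downstream are rotation-covariant, so any consistent
orientation convention yields the same feature values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ScalarVolume3D",
    "LesionMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "voxel_to_world",
    "world_to_voxel",
    "require_same_geometry",
]


def _as_triple(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float)).ravel()
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError(f"{name} must be a scalar or length-3 sequence, got {x!r}")
    return arr


@dataclass
class ScalarVolume3D:
    """A 3D grid of SUV intensities with physical spacing and origin.

    Parameters
    ----------
    values
        3D array of standardized uptake values (dimensionless, finite).
    spacing
        Per-axis voxel size in mm (strictly positive). A scalar is
        broadcast to all three axes.
    origin
        World position (mm) of the *center* of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.values.ndim}D data")
        if self.values.size == 0:
            raise ValueError("volume grid is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing = _as_triple(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LesionMask:
    """A binary 3D segmentation sharing the geometry of a paired volume."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.values.ndim}D data")
        if self.values.size == 0:
            raise ValueError("mask grid is empty")
        self.spacing = _as_triple(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def require_same_geometry(a, b, atol: float = 1e-6) -> None:
    """Raise if two volume-like objects do not share grid and geometry."""
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=atol):
        raise ValueError(f"spacings differ: {a.spacing} vs {b.spacing}")
    if not np.allclose(a.origin, b.origin, atol=atol):
        raise ValueError(f"origins differ: {a.origin} vs {b.origin}")


def voxel_to_world(index, vol) -> np.ndarray:
    """World coordinates (mm) of the center of the voxel at ``index``.

    ``index`` must lie within the grid bounds of ``vol``.
    """
    idx = np.asarray(index, dtype=float).ravel()
    if idx.size != 3:
        raise ValueError("voxel index must have three components")
    shape = np.asarray(vol.shape)
    if np.any(idx < 0) or np.any(idx > shape - 1):
        raise IndexError(f"voxel index {index} outside grid of shape {vol.shape}")
    return vol.origin + idx * vol.spacing


def world_to_voxel(point, vol) -> tuple[int, int, int]:
    """Nearest voxel index for a world point; inverse of :func:`voxel_to_world`."""
    pt = np.asarray(point, dtype=float).ravel()
    if pt.size != 3:
        raise ValueError("world point must have three components")
    idx = np.rint((pt - vol.origin) / vol.spacing).astype(int)
    shape = np.asarray(vol.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise IndexError(f"world point {point} maps outside grid of shape {vol.shape}")
    return tuple(int(i) for i in idx)


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> ScalarVolume3D:
    """Read a 3D SUV volume from a NIfTI-1 file.

    Spacing is taken from the header ``pixdim``; the origin is the
    translation part of the affine. Non-3D data or non-positive
    spacing is rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D data in {path}, got {data.ndim}D")
    spacing = np.asarray(img.header["pixdim"][1:4], dtype=float)
    if np.any(spacing <= 0):
        raise ValueError(f"non-positive voxel spacing in {path}: {spacing}")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return ScalarVolume3D(data.astype(np.float64), spacing, origin)


def write_volume(vol: ScalarVolume3D, path) -> None:
    """Write a volume as NIfTI-1; round-trips values bit-exactly."""
    img = nib.Nifti1Image(vol.values.astype(np.float64), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def read_mask(path) -> LesionMask:
    """Read a binary mask (any nonzero voxel is foreground) from NIfTI-1."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask in {path}, got {data.ndim}D")
    spacing = np.asarray(img.header["pixdim"][1:4], dtype=float)
    if np.any(spacing <= 0):
        raise ValueError(f"non-positive voxel spacing in {path}: {spacing}")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return LesionMask(data != 0, spacing, origin)


def write_mask(mask: LesionMask, path) -> None:
    """Write a mask as a 0/1 uint8 NIfTI-1 file."""
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.header.set_zooms(tuple(mask.spacing))
    nib.save(img, str(path))
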