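"""Image transformations of the robustness study.

Gaussian postfiltering (isotropic SD expressed in mm), resampling to a
fixed voxel grid, and fixed-bin-width gray-level discretization of the
VOI intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume_io import LesionMask, ScalarVolume3D, _as_triple, require_same_geometry

__all__ = [
    "DiscretizationParams",
    "DiscretizedVolume",
    "gaussian_filter",
    "resample",
    "discretize",
]


@dataclass(frozen=True)
class DiscretizationParams:
    """Fixed-bin-width gray-level discretization over a fixed SUV range.

    The defaults (0 to 60 SUV in 192 levels) give a bin width of
    exactly 60/192 = 0.3125 SUV.
    """

    lower: float = 0.0
    upper: float = 60.0
    n_levels: int = 192

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")
        if self.n_levels < 1:
            raise ValueError("n_levels must be a positive integer")

    @property
    def bin_width(self) -> float:
        return (self.upper - self.lower) / self.n_levels


@dataclass
class DiscretizedVolume:
    """Integer gray levels in 1..G on mask voxels (0 elsewhere)."""

    levels: np.ndarray
    mask: LesionMask
    params: DiscretizationParams


def gaussian_filter(vol: ScalarVolume3D, sigma_mm: float) -> ScalarVolume3D:
    """Convolve with an isotropic gaussian of SD ``sigma_mm`` in physical units.

    The per-axis SD in voxels is ``sigma_mm / spacing``, so anisotropic
    grids still receive an isotropic physical blur. Borders use reflect
    padding to avoid edge darkening of lesions near the field of view.
    """
    if sigma_mm <= 0:
        raise ValueError(f"sigma_mm must be positive, got {sigma_mm}")
    sigma_vox = sigma_mm / vol.spacing
    filtered = ndi.gaussian_filter(vol.values, sigma=sigma_vox, mode="reflect")
    return ScalarVolume3D(filtered, vol.spacing.copy(), vol.origin.copy())


def _output_grid(shape, spacing, target):
    out_shape = np.maximum(1, np.ceil(np.asarray(shape) * spacing / target)).astype(int)
    return tuple(int(s) for s in out_shape)


def _coords(out_shape, spacing_in, spacing_out):
    # voxel-center alignment: output voxel 0 center coincides with input origin
    axes = [
        np.arange(n) * spacing_out[a] / spacing_in[a] for a, n in enumerate(out_shape)
    ]
    return np.meshgrid(*axes, indexing="ij")


def resample(obj, target_spacing_mm, mode: str | None = None):
    """Resample a volume or mask to a new voxel grid.

    Intensities use trilinear interpolation, masks nearest-neighbor
    (the defaults; ``mode`` forces ``"linear"`` or ``"nearest"``). The
    output grid is aligned to the input origin and covers the input
    physical extent; values beyond the last voxel center are taken
    from the nearest edge voxel.
    """
    target = _as_triple(target_spacing_mm, "target_spacing_mm")
    if np.any(target <= 0):
        raise ValueError(f"target spacing must be positive, got {target}")
    is_mask = isinstance(obj, LesionMask)
    if mode is None:
        mode = "nearest" if is_mask else "linear"
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    order = 0 if mode == "nearest" else 1

    out_shape = _output_grid(obj.shape, obj.spacing, target)
    coords = _coords(out_shape, obj.spacing, target)
    src = obj.values.astype(np.float64)
    out = ndi.map_coordinates(src, coords, order=order, mode="nearest")
    if is_mask:
        return LesionMask(out > 0.5, target, obj.origin.copy())
    return ScalarVolume3D(out, target, obj.origin.copy())


def discretize(
    vol: ScalarVolume3D,
    mask: LesionMask,
    params: DiscretizationParams = DiscretizationParams(),
) -> DiscretizedVolume:
    """Discretize in-mask SUVs into gray levels 1..G with a fixed bin width.

    ``level = min(G, floor((v - lower) / width) + 1)``; values below the
    lower bound clamp to level 1 and values at or above the upper bound
    clamp to level G, so the level count is fixed regardless of the
    observed SUV range.
    """
    require_same_geometry(vol, mask)
    if mask.n_voxels == 0:
        raise ValueError("cannot discretize an empty mask")
    g = params.n_levels
    raw = np.floor((vol.values - params.lower) / params.bin_width).astype(np.int64) + 1
    levels = np.clip(raw, 1, g)
    levels = np.where(mask.values, levels, 0).astype(np.int64)
    return DiscretizedVolume(levels, mask, params)
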