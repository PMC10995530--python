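"""Lesion delineation: isocontour thresholding and morphological closing.

The metabolically active volume is segmented as the voxels at or above
a fixed fraction (default 40%) of the maximum SUV inside a seed VOI,
optionally restricted to the connected component carrying that maximum.
A morphological closing with a physical ball radius can then swallow
cold internal (necrotic) regions into the VOI. Geometric summaries
(centroid, equivalent-sphere radius, boundary voxels) feed the
hot-spot displacement features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .volume_io import LesionMask, ScalarVolume3D, require_same_geometry

__all__ = [
    "SegmentationParams",
    "LesionGeometry",
    "threshold_segment",
    "close_mask",
    "segment_lesion",
    "geometry",
    "ball_footprint",
]

# 26-connectivity for component labelling, 6 (face) adjacency for boundaries
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndi.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the isocontour segmentation.

    ``closing_radius_mm=None`` means "2x the largest voxel spacing";
    0 disables closing entirely.
    """

    threshold_fraction: float = 0.40
    closing_radius_mm: Optional[float] = None
    keep_largest_component: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold fraction must lie in (0, 1)")
        if self.closing_radius_mm is not None and self.closing_radius_mm < 0:
            raise ValueError("closing radius must be >= 0")

    def resolved_closing_radius(self, spacing) -> float:
        if self.closing_radius_mm is None:
            return 2.0 * float(np.max(spacing))
        return float(self.closing_radius_mm)


@dataclass
class LesionGeometry:
    """Geometric summary of a segmented lesion."""

    voxel_count: int
    mtv_cm3: float
    centroid_mm: np.ndarray  # unweighted mean of in-mask voxel centers
    r_eq_mm: float  # radius of the equal-volume sphere
    boundary: np.ndarray  # boolean grid of in-mask face-boundary voxels


def threshold_segment(
    vol: ScalarVolume3D,
    seed_voi: LesionMask,
    params: SegmentationParams = SegmentationParams(),
) -> LesionMask:
    """Isocontour the lesion at a fraction of the in-seed maximum SUV.

    The threshold is lesion-relative: the reference maximum is taken
    inside the seed VOI, not over the whole image. With
    ``keep_largest_component`` the result is restricted to the
    26-connected component containing the maximum-SUV voxel.
    """
    require_same_geometry(vol, seed_voi)
    seed = seed_voi.values
    if not seed.any():
        raise ValueError("seed VOI is empty")
    suv_max = float(vol.values[seed].max())
    if suv_max <= 0:
        raise ValueError("maximum SUV within the seed VOI must be positive")
    mask = seed & (vol.values >= params.threshold_fraction * suv_max)
    if not mask.any():
        raise ValueError("thresholding produced an empty mask")
    if params.keep_largest_component:
        labels, _ = ndi.label(mask, structure=_STRUCT26)
        # component of the first (smallest linear index) maximum voxel
        masked = np.where(seed, vol.values, -np.inf)
        hot = np.unravel_index(int(np.argmax(masked)), vol.shape)
        mask = labels == labels[hot]
    return LesionMask(mask, vol.spacing.copy(), vol.origin.copy())


def ball_footprint(radius_mm: float, spacing) -> np.ndarray:
    """Boolean structuring element: a ball of physical radius in voxels."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.maximum(0, np.floor(radius_mm / spacing)).astype(int)
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij")
    return dx**2 + dy**2 + dz**2 <= radius_mm**2 + 1e-9


def close_mask(mask: LesionMask, radius_mm: float) -> LesionMask:
    """Morphological closing with a ball of the given physical radius.

    Dilation followed by erosion; the output always contains the input
    and a radius of 0 is the identity. The grid is padded by the
    footprint half-width so lesions touching the grid edge behave as if
    surrounded by background.
    """
    if radius_mm < 0:
        raise ValueError("closing radius must be >= 0")
    if radius_mm == 0:
        return LesionMask(mask.values.copy(), mask.spacing.copy(), mask.origin.copy())
    fp = ball_footprint(radius_mm, mask.spacing)
    pad = [(s // 2,) * 2 for s in fp.shape]
    padded = np.pad(mask.values, pad, mode="constant", constant_values=False)
    closed = ndi.binary_closing(padded, structure=fp)
    sl = tuple(slice(p[0], p[0] + n) for p, n in zip(pad, mask.shape))
    out = closed[sl] | mask.values
    return LesionMask(out, mask.spacing.copy(), mask.origin.copy())


def segment_lesion(
    vol: ScalarVolume3D,
    seed_voi: LesionMask,
    params: SegmentationParams = SegmentationParams(),
    apply_closing: bool = True,
) -> LesionMask:
    """Threshold segmentation followed (optionally) by closing."""
    mask = threshold_segment(vol, seed_voi, params)
    if apply_closing:
        radius = params.resolved_closing_radius(vol.spacing)
        if radius > 0:
            mask = close_mask(mask, radius)
    return mask


def geometry(mask: LesionMask) -> LesionGeometry:
    """Voxel count, MTV, centroid, equivalent-sphere radius and boundary.

    The centroid is the unweighted mean of in-mask voxel-center world
    coordinates. Boundary voxels are in-mask voxels with at least one
    of their 6 face neighbors outside the mask or beyond the grid edge.
    ``r_eq_mm`` is the radius of the hypothetical sphere with the same
    volume as the lesion.
    """
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    count = mask.n_voxels
    volume_mm3 = count * mask.voxel_volume_mm3
    mtv_cm3 = volume_mm3 / 1000.0
    idx = np.argwhere(mask.values)
    centroid = mask.origin + idx.mean(axis=0) * mask.spacing
    r_eq = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    eroded = ndi.binary_erosion(mask.values, structure=_STRUCT6, border_value=0)
    boundary = mask.values & ~eroded
    return LesionGeometry(count, mtv_cm3, centroid, r_eq, boundary)
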