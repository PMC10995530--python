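"""Textural features over the discretized VOI.

Six features from three matrix families:

* GLCM (gray-level co-occurrence): joint entropy (log10) and inverse
  difference moment;
* GLRLM (gray-level run length): short and long run emphasis;
* GLSZM (gray-level size zone): low and high gray-level zone emphasis.

GLCM and GLRLM pool the 13 unique 3D directions at distance 1 into a
single merged matrix before normalization; GLSZM zones are
26-connected components of equal gray level. Gray levels ``i`` in the
formulas are the 1-based levels produced by the discretization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .preprocess import DiscretizedVolume

__all__ = [
    "DIRECTIONS_13",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "SizeZoneMatrix",
    "glcm",
    "glcm_features",
    "glrlm",
    "glrlm_features",
    "glszm",
    "glszm_features",
    "texture_features",
]

# the 13 unique (up to sign) offsets of the 26-neighborhood
DIRECTIONS_13 = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CooccurrenceMatrix:
    """Normalized symmetric pair-probability table p(i, j), 1-based levels."""

    p: np.ndarray  # G x G
    n_pairs: int
    distance: int = 1
    directions: tuple = DIRECTIONS_13


@dataclass
class RunLengthMatrix:
    """Run counts r(level, length) pooled over 13 directions."""

    counts: Counter  # (level, length) -> count
    n_runs: int


@dataclass
class SizeZoneMatrix:
    """Zone counts s(level, size) over 26-connected equal-level zones."""

    counts: Counter  # (level, size) -> count
    n_zones: int


def _offset_slices(shape, off):
    a = tuple(
        slice(max(0, -o), min(n, n - o)) for n, o in zip(shape, off)
    )
    b = tuple(
        slice(max(0, o), min(n, n + o)) for n, o in zip(shape, off)
    )
    return a, b


def glcm(dvol: DiscretizedVolume, directions=DIRECTIONS_13) -> CooccurrenceMatrix:
    """Distance-1 co-occurrences, both orderings counted, restricted to
    in-mask voxel pairs, merged over ``directions`` and normalized."""
    mask = dvol.mask.values
    if not mask.any():
        raise ValueError("empty discretized VOI")
    lev = dvol.levels
    g = dvol.params.n_levels
    counts = np.zeros((g, g), dtype=np.int64)
    for off in directions:
        sa, sb = _offset_slices(mask.shape, off)
        both = mask[sa] & mask[sb]
        a = lev[sa][both] - 1
        b = lev[sb][both] - 1
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
    total = int(counts.sum())
    if total == 0:  # single isolated voxel: no pairs
        raise ValueError("VOI has no neighboring voxel pairs")
    return CooccurrenceMatrix(counts / total, total, 1, tuple(directions))


def glcm_features(m: CooccurrenceMatrix) -> tuple[float, float]:
    """(joint entropy in log10, inverse difference moment)."""
    p = m.p
    nz = p > 0
    entropy = float(-(p[nz] * np.log10(p[nz])).sum())
    i, j = np.nonzero(nz)
    idm = float((p[nz] / (1.0 + (i - j) ** 2)).sum())
    return entropy, idm


def _shift_lookup(arr, off, fill):
    """out[x] = arr[x + off], with ``fill`` beyond the grid."""
    out = np.full(arr.shape, fill, dtype=arr.dtype)
    sa, sb = _offset_slices(arr.shape, off)
    out[sa] = arr[sb]
    return out


def glrlm(dvol: DiscretizedVolume, directions=DIRECTIONS_13) -> RunLengthMatrix:
    """Maximal runs of equal gray level along each direction, merged."""
    mask = dvol.mask.values
    if not mask.any():
        raise ValueError("empty discretized VOI")
    lev = dvol.levels
    counts: Counter = Counter()
    n_runs = 0
    for off in directions:
        fwd = _shift_lookup(lev, off, 0)
        same_fwd = mask & _shift_lookup(mask, off, False) & (lev == fwd)
        back = tuple(-o for o in off)
        same_back = _shift_lookup(same_fwd, back, False)
        starts = np.argwhere(mask & ~same_back)
        n_runs += len(starts)
        if len(starts) == 0:
            continue
        levels = lev[tuple(starts.T)]
        pos = starts.copy()
        length = np.ones(len(starts), dtype=np.int64)
        alive = same_fwd[tuple(pos.T)]
        step = np.asarray(off)
        while alive.any():
            pos[alive] += step
            length[alive] += 1
            alive_idx = np.where(alive)[0]
            alive[alive_idx] = same_fwd[tuple(pos[alive_idx].T)]
        for g, ln in zip(levels, length):
            counts[(int(g), int(ln))] += 1
    return RunLengthMatrix(counts, n_runs)


def glrlm_features(dvol: DiscretizedVolume, directions=DIRECTIONS_13) -> tuple[float, float]:
    """(short run emphasis, long run emphasis)."""
    m = glrlm(dvol, directions)
    sre = sum(c / (ln * ln) for (_, ln), c in m.counts.items()) / m.n_runs
    lre = sum(c * ln * ln for (_, ln), c in m.counts.items()) / m.n_runs
    return float(sre), float(lre)


def glszm(dvol: DiscretizedVolume) -> SizeZoneMatrix:
    """26-connected zones of equal gray level with their sizes."""
    mask = dvol.mask.values
    if not mask.any():
        raise ValueError("empty discretized VOI")
    lev = dvol.levels
    counts: Counter = Counter()
    n_zones = 0
    for g in np.unique(lev[mask]):
        labels, n = ndi.label((lev == g) & mask, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        n_zones += n
        for s in sizes:
            counts[(int(g), int(s))] += 1
    return SizeZoneMatrix(counts, n_zones)


def glszm_features(dvol: DiscretizedVolume) -> tuple[float, float]:
    """(low gray-level zone emphasis, high gray-level zone emphasis)."""
    m = glszm(dvol)
    lgze = sum(c / (g * g) for (g, _), c in m.counts.items()) / m.n_zones
    hgze = sum(c * g * g for (g, _), c in m.counts.items()) / m.n_zones
    return float(lgze), float(hgze)


def texture_features(dvol: DiscretizedVolume) -> dict:
    """All six texture features as a flat dictionary."""
    entropy, idm = glcm_features(glcm(dvol))
    sre, lre = glrlm_features(dvol)
    lgze, hgze = glszm_features(dvol)
    return {
        "joint_entropy_log10": entropy,
        "inverse_difference_moment": idm,
        "short_run_emphasis": sre,
        "long_run_emphasis": lre,
        "low_gray_zone_emphasis": lgze,
        "high_gray_zone_emphasis": hgze,
    }
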