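"""Digital phantoms and survival cohorts with known ground truth.

The phantom is an ellipsoidal lesion of uniform plateau uptake on a
low-uptake background, with a gaussian hot-spot bump displaced a known
radial fraction ``f`` of the way from the lesion center to its edge,
an optional cold (necrotic) core, and additive gaussian noise. The
displacement fraction is the analytic ground truth the NHOC/NHOP
estimators are checked against: on a spherical lesion the expected
values are ``NHOC = f`` and ``NHOP = 1 - f``.

In necrotic phantoms the bump is suppressed inside the cold core, so
the hottest uptake sits on the core rim: lesions with necrosis
therefore show higher NHOC and lower NHOP than matched controls, the
mechanism by which central necrosis displaces the hot spot in real
tumors.

Survival cohorts draw exponential event times whose subject hazard is
``baseline * exp(sum(beta * feature))``, with exponential and/or
administrative censoring, so the direction and strength of every
feature–hazard link is known by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .volume_io import LesionMask, ScalarVolume3D

__all__ = ["PhantomSpec", "CohortSpec", "make_phantom", "make_seed_box", "simulate_cohort"]

# feature distributions (mean, SD) typical of advanced-NSCLC primary
# lesions; used as the default cohort feature generator
DEFAULT_FEATURES = {
    "nhoc_max": (0.62, 0.29),
    "nhop_max": (0.26, 0.16),
    "suv_max": (13.3, 7.2),
    "mtv_cm3": (57.1, 112.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one phantom.

    All lengths in mm, all intensities in SUV. ``hotspot_fraction``
    is the radial position of the bump center: 0 at the lesion
    centroid, 1 on the lesion surface along ``hotspot_direction``.
    """

    shape: tuple = (57, 57, 57)  # odd: the grid center is a voxel center
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    semi_axes_mm: tuple = (20.0, 20.0, 20.0)
    center_mm: Optional[tuple] = None  # default: grid center
    background_suv: float = 0.5
    plateau_suv: float = 5.0
    hotspot_amplitude: float = 5.0
    hotspot_sigma_mm: float = 3.5
    hotspot_fraction: float = 0.0
    hotspot_direction: tuple = (1.0, 0.0, 0.0)
    core_radius_mm: float = 0.0
    core_suv: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        if not 0.0 <= self.hotspot_fraction <= 1.0:
            raise ValueError("hotspot fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.core_radius_mm < 0:
            raise ValueError("core radius must be >= 0")
        if self.core_radius_mm >= min(self.semi_axes_mm):
            if self.core_radius_mm > 0:
                raise ValueError("necrotic core must fit inside the lesion")
        extent = np.asarray(self.shape) * np.asarray(self.spacing_mm)
        if np.any(2 * np.asarray(self.semi_axes_mm) >= extent):
            raise ValueError("lesion does not fit inside the grid")


def _grid_world(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def make_phantom(spec: PhantomSpec) -> tuple[ScalarVolume3D, dict]:
    """Render a phantom volume and its ground-truth record.

    Deterministic given ``spec.seed``. The ground truth holds the true
    hot-spot world position (the bump center), the displacement
    fraction, the analytic lesion volume and equal-volume-sphere
    radius, and the necrosis flag.
    """
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    axes_mm = np.asarray(spec.semi_axes_mm, dtype=float)
    if spec.center_mm is None:
        center = (np.asarray(shape) - 1) / 2.0 * spacing
    else:
        center = np.asarray(spec.center_mm, dtype=float)

    xx, yy, zz = _grid_world(shape, spacing)
    dx, dy, dz = xx - center[0], yy - center[1], zz - center[2]
    inside = (dx / axes_mm[0]) ** 2 + (dy / axes_mm[1]) ** 2 + (dz / axes_mm[2]) ** 2 <= 1.0

    values = np.full(shape, spec.background_suv, dtype=np.float64)
    values[inside] = spec.plateau_suv

    r2 = dx**2 + dy**2 + dz**2
    core = np.zeros(shape, dtype=bool)
    if spec.core_radius_mm > 0:
        core = r2 <= spec.core_radius_mm**2
        values[core & inside] = spec.core_suv

    u = np.asarray(spec.hotspot_direction, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("hotspot direction must be non-zero")
    u = u / norm
    # distance from center to the ellipsoid surface along u
    t_edge = 1.0 / np.sqrt(np.sum((u / axes_mm) ** 2))
    hs_center = center + spec.hotspot_fraction * t_edge * u
    if spec.core_radius_mm > 0 and spec.hotspot_fraction * t_edge <= spec.core_radius_mm:
        warnings.warn(
            "hotspot center lies inside the necrotic core; the rendered "
            "maximum will sit on the core rim",
            stacklevel=2,
        )

    d2 = (xx - hs_center[0]) ** 2 + (yy - hs_center[1]) ** 2 + (zz - hs_center[2]) ** 2
    bump = spec.hotspot_amplitude * np.exp(-d2 / (2.0 * spec.hotspot_sigma_mm**2))
    values[inside & ~core] += bump[inside & ~core]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, shape)
    values = np.clip(values, 0.0, None)

    vol = ScalarVolume3D(values, spacing, np.zeros(3))
    volume_mm3 = 4.0 / 3.0 * np.pi * float(np.prod(axes_mm))
    truth = {
        "hotspot_world_mm": hs_center.tolist(),
        "hotspot_fraction": float(spec.hotspot_fraction),
        "center_mm": center.tolist(),
        "lesion_volume_mm3": volume_mm3,
        "r_eq_mm": float((3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)),
        "necrotic": bool(spec.core_radius_mm > 0),
        "core_radius_mm": float(spec.core_radius_mm),
        "seed": int(spec.seed),
    }
    return vol, truth


def make_seed_box(spec: PhantomSpec, margin_mm: float = 6.0) -> LesionMask:
    """Axis-aligned box seed VOI around the phantom lesion."""
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    axes_mm = np.asarray(spec.semi_axes_mm, dtype=float)
    if spec.center_mm is None:
        center = (np.asarray(shape) - 1) / 2.0 * spacing
    else:
        center = np.asarray(spec.center_mm, dtype=float)
    lo = np.maximum(0, np.floor((center - axes_mm - margin_mm) / spacing)).astype(int)
    hi = np.minimum(
        np.asarray(shape) - 1, np.ceil((center + axes_mm + margin_mm) / spacing)
    ).astype(int)
    m = np.zeros(shape, dtype=bool)
    m[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
    return LesionMask(m, spacing, np.zeros(3))


@dataclass(frozen=True)
class CohortSpec:
    """Parametric description of a simulated survival cohort.

    ``log_hazard`` maps feature names to coefficients applied to the
    raw feature values; a hazard ratio of ``h`` per SD of a feature
    corresponds to ``beta = ln(h) / sd``. ``baseline_hazard`` is the
    event rate per month for a subject with all features at zero, so
    features are usually supplied centered. Censoring combines an
    optional exponential rate with an optional administrative horizon.
    """

    n: int = 244
    features: dict = field(default_factory=lambda: dict(DEFAULT_FEATURES))
    log_hazard: dict = field(default_factory=dict)
    baseline_hazard: float = 1.0 / 18.0  # per month; median ~ 12.5 months
    censor_rate: float = 0.0
    censor_horizon_months: Optional[float] = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censoring rate must be >= 0")
        unknown = set(self.log_hazard) - set(self.features)
        if unknown:
            raise ValueError(f"log-hazard coefficients for unknown features: {unknown}")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a survival cohort as a tidy per-subject table.

    Columns: ``id``, ``time_months``, ``event`` plus one column per
    feature. Event times are exponential with subject hazard
    ``baseline * exp(sum(beta_f * x_f))``; the recorded time is the
    minimum of the event time, an exponential censoring time and the
    administrative horizon. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cols = {}
    linpred = np.zeros(spec.n)
    for name, (mean, sd) in spec.features.items():
        x = rng.normal(mean, sd, spec.n)
        cols[name] = x
        beta = spec.log_hazard.get(name, 0.0)
        if beta:
            linpred = linpred + beta * x
    hazard = spec.baseline_hazard * np.exp(linpred)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = (
        rng.exponential(1.0 / spec.censor_rate, spec.n)
        if spec.censor_rate > 0
        else np.full(spec.n, np.inf)
    )
    horizon = (
        spec.censor_horizon_months if spec.censor_horizon_months is not None else np.inf
    )
    t_cens = np.minimum(t_cens, horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if horizon == 0:
        warnings.warn("censoring horizon is 0: every record is censored at 0",
                      stacklevel=2)
        event[:] = 0
    df = pd.DataFrame({"id": np.arange(spec.n), "time_months": time, "event": event})
    for name, x in cols.items():
        df[name] = x
    return df
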