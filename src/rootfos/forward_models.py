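"""Physical forward models linking root growth to fiber strain.

Two mechanisms, one per growth habit:

* **Primary growth (rice crown roots).**  A gravitropic root tip presses
  downward on the soil.  The tip is idealised as a vertical point load ``P``
  in an infinite homogeneous elastic medium with shear modulus ``G`` and
  Poisson ratio ``nu`` (Kelvin problem).  The gauge observable is the hoop
  (tangential) strain about the vertical axis through the tip,

      eps_theta_theta = P * dz / (16 * pi * G * (1 - nu) * r**3),

  with ``dz`` the sensor depth minus the tip depth (positive below the tip)
  and ``r`` the 3-D tip-sensor distance.  The kernel is linear in ``P``,
  axially symmetric, scales as 1/G, and decays as 1/r^2 along any ray --
  everything the inverse localization relies on.  ``nu = 0.5``
  (incompressible, the soil-like default) is regular.

* **Secondary growth (radish tuber).**  A tuber of radius ``a`` thickening at
  the pot axis displaces incompressible soil outward; a fiber loop at an
  effective radial stand-off ``d`` must lengthen to enclose the added root
  cross-section, giving the hoop strain

      eps(a) = sqrt(1 + (a/d)**2) - 1,

  diluted by gauge length relative to the 30 mm design spacing.  ``d`` is
  calibrated once so that a 0.3 mm *diameter* root produces 15 microstrain at
  the 30 mm design spacing -- the device's stated sensitivity target -- which
  puts ``d`` at 27.386 mm, comparable to the spiral radius.  The map is
  strictly increasing and analytically invertible.

Units: mm, microstrain, G in GPa.  ``P`` is kept in the model units used for
the per-pot fits (magnitudes 1e5-2.5e6); linearity makes every downstream
estimate insensitive to the unit convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .geometry import SensorLayout

__all__ = [
    "ElasticParams",
    "RootTip",
    "RadiusModelParams",
    "hoop_strain",
    "kelvin_displacement",
    "strains_for_tips",
    "strain_from_radius",
    "radius_from_strain",
]

_DESIGN_SPACING_MM = 30.0
_FOURPI = 4.0 * np.pi


@dataclass(frozen=True)
class ElasticParams:
    """Point-load kernel parameters (per-pot fits used G=0.1 GPa, nu=0.5)."""

    P: float = 2.0e5
    G: float = 0.1
    nu: float = 0.5
    regularization_mm: float = 1.0

    def __post_init__(self):
        if self.G <= 0:
            raise ParameterError(f"shear modulus must be positive, got {self.G}")
        if not (0.0 <= self.nu <= 0.5):
            raise ParameterError(f"Poisson ratio outside [0, 0.5]: {self.nu}")
        if self.P <= 0:
            raise ParameterError(f"load amplitude must be positive, got {self.P}")
        if self.regularization_mm <= 0:
            raise ParameterError("regularization radius must be positive")


@dataclass(frozen=True)
class RootTip:
    """A point load at a root tip; ``load=None`` means use ElasticParams.P."""

    position: np.ndarray
    load: float | None = None
    active: bool = True

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if pos[2] < 0:
            raise ParameterError(f"tip depth must be >= 0, got {pos[2]}")
        object.__setattr__(self, "position", pos)

    @property
    def horizontal_radius(self) -> float:
        return float(np.hypot(self.position[0], self.position[1]))


@dataclass(frozen=True)
class RadiusModelParams:
    """Calibration of the tuber strain<->radius map.

    ``anchor_radius_mm``/``anchor_strain_ue`` pin the design sensitivity point
    (0.15 mm radius -> 15 microstrain at the 30 mm design spacing).
    ``detection_threshold_ue`` zeroes strains below instrument resolution when
    inverting; 0 disables it.
    """

    gauge_spacing: float = 30.0
    anchor_radius_mm: float = 0.15
    anchor_strain_ue: float = 15.0
    detection_threshold_ue: float = 0.0

    def __post_init__(self):
        if self.gauge_spacing <= 0:
            raise ParameterError("gauge spacing must be positive")
        if self.anchor_radius_mm <= 0 or self.anchor_strain_ue <= 0:
            raise ParameterError("calibration anchor must be positive")

    @property
    def standoff_mm(self) -> float:
        """Effective loop radius implied by the calibration anchor."""
        eps = self.anchor_strain_ue * 1e-6
        return self.anchor_radius_mm / np.sqrt((1.0 + eps) ** 2 - 1.0)


def _relative(tip: RootTip, sensor_xyz: np.ndarray, reg: float):
    """Tip->sensor offsets with the near-field clamp applied.

    Sensors closer than the regularization radius are evaluated at the
    direction-preserving point on the regularization sphere (the point-load
    singularity is unphysical below root-tip scale).
    """
    pts = np.atleast_2d(np.asarray(sensor_xyz, dtype=float))
    rel = pts - tip.position
    r = np.linalg.norm(rel, axis=1)
    close = r < reg
    if np.any(close):
        rc = r[close]
        # coincident sensor/tip has no direction: evaluate at the lower pole
        dirs = np.where(
            rc[:, None] == 0.0,
            np.array([0.0, 0.0, 1.0]),
            rel[close] / np.where(rc == 0.0, 1.0, rc)[:, None],
        )
        rel[close] = dirs * reg
        r[close] = reg
    return rel, r


def hoop_strain(
    tip: RootTip, sensor_xyz, params: ElasticParams = ElasticParams()
) -> np.ndarray | float:
    """Tangential strain (microstrain) at sensor(s) for a downward tip load.

    Axially symmetric about the vertical through the tip, linear in the load,
    positive below the tip depth and negative above it.
    """
    load = params.P if tip.load is None else tip.load
    rel, r = _relative(tip, sensor_xyz, params.regularization_mm)
    dz = rel[:, 2]
    coef = load / (_FOURPI * 4.0 * params.G * (1.0 - params.nu))
    eps = coef * dz / r**3
    if np.ndim(sensor_xyz) == 1:
        return float(eps[0])
    return eps


def kelvin_displacement(
    tip: RootTip, sensor_xyz, params: ElasticParams = ElasticParams()
) -> np.ndarray:
    """Displacement field of the vertical point load (micro-units of mm).

    Components (force along +z, i.e. downward/depth-positive):

        u_x = C * x * dz / r^3
        u_y = C * y * dz / r^3
        u_z = C * ((3 - 4 nu)/r + dz^2 / r^3),   C = P / (16 pi G (1 - nu)).

    Scaled so that spatial derivatives of ``u`` (per mm) are microstrain;
    differentiating this field is the independent cross-check for
    :func:`hoop_strain`.
    """
    load = params.P if tip.load is None else tip.load
    rel, r = _relative(tip, sensor_xyz, params.regularization_mm)
    C = load / (_FOURPI * 4.0 * params.G * (1.0 - params.nu))
    inv3 = 1.0 / r**3
    dz = rel[:, 2]
    u = np.empty_like(rel)
    u[:, 0] = C * rel[:, 0] * dz * inv3
    u[:, 1] = C * rel[:, 1] * dz * inv3
    u[:, 2] = C * ((3.0 - 4.0 * params.nu) / r + dz * dz * inv3)
    if np.ndim(sensor_xyz) == 1:
        return u[0]
    return u


def strains_for_tips(
    tips: Sequence[RootTip], layout: SensorLayout, params: ElasticParams = ElasticParams()
) -> np.ndarray:
    """Superposed hoop strain of all active tips at every gauge (microstrain)."""
    out = np.zeros(len(layout))
    for tip in tips:
        if tip.active:
            out += hoop_strain(tip, layout.xyz, params)
    return out


def strain_from_radius(
    radius, params: RadiusModelParams = RadiusModelParams()
) -> np.ndarray | float:
    """Gauge strain (microstrain) produced by a tuber of ``radius`` mm.

    Incompressible displaced-area loop stretch, diluted by gauge length
    relative to the 30 mm design spacing.  Strictly increasing in radius.
    """
    a = np.asarray(radius, dtype=float)
    if np.any(a < 0):
        raise ParameterError("radius must be non-negative")
    d = params.standoff_mm
    eps = np.sqrt(1.0 + (a / d) ** 2) - 1.0
    ue = eps * 1e6 * (_DESIGN_SPACING_MM / params.gauge_spacing)
    return float(ue) if np.ndim(radius) == 0 else ue


def radius_from_strain(
    strain_ue, params: RadiusModelParams = RadiusModelParams()
) -> np.ndarray | float:
    """Invert :func:`strain_from_radius`; sub-threshold or negative -> 0 mm."""
    ue = np.asarray(strain_ue, dtype=float)
    ue = np.where(ue < params.detection_threshold_ue, 0.0, ue)
    ue = np.maximum(ue, 0.0)
    eps = ue * 1e-6 * (params.gauge_spacing / _DESIGN_SPACING_MM)
    a = params.standoff_mm * np.sqrt((1.0 + eps) ** 2 - 1.0)
    return float(a) if np.ndim(strain_ue) == 0 else a


def with_load(params: ElasticParams, P: float) -> ElasticParams:
    """Copy of ``params`` with a different load amplitude."""
    return replace(params, P=P)
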