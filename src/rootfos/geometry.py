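"""Spiral sensing backbone and the arc-length -> 3-D spatial encoding.

A single-mode fiber is fixed in horizontal passes on a polymer film that is
wound as an Archimedean spiral inside a cultivation pot.  Because optical
frequency-domain reflectometry resolves strain *along the fiber*, knowing the
3-D position of every arc-length coordinate turns the 1-D sensor into a
volumetric one.  This module owns that map.

Conventions
-----------
Cylindrical frame centred on the pot axis at the soil surface, millimetres
throughout, and ``z`` increasing **downward** (depth-positive).  Angles are in
radians internally.  The fiber runs in horizontal spiral passes stacked at a
constant vertical pitch; consecutive passes are joined by short vertical
connector segments (serpentine routing: odd passes traverse the spiral in the
reverse angular direction so the fiber is continuous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import GeometryError, ParameterError

__all__ = [
    "DeviceGeometry",
    "SensorLayout",
    "build_spiral_geometry",
    "spiral_pass_length",
    "arc_to_xyz",
    "make_sensor_layout",
]


def _spiral_cumlen(r0: float, b: float, theta: np.ndarray | float):
    """Arc length of r(t) = r0 + b*t from t=0 to t=theta (closed form).

    For an Archimedean spiral the integrand sqrt(r^2 + (dr/dt)^2) has the
    antiderivative (b/2)*(u*sqrt(1+u^2) + asinh(u)) with u = r/b.
    """
    theta = np.asarray(theta, dtype=float)
    if b == 0.0:  # degenerate spiral: a circle
        return r0 * theta

    def antider(u):
        return 0.5 * b * (u * np.sqrt(1.0 + u * u) + np.arcsinh(u))

    u0 = r0 / b
    u1 = (r0 + b * theta) / b
    return antider(u1) - antider(u0)


@dataclass(frozen=True)
class DeviceGeometry:
    """Spiral backbone description plus derived arc-length bookkeeping.

    ``n_loops`` horizontal passes lie at depths ``z_top + k*pitch``; each pass
    follows the full Archimedean footprint
    ``r(theta) = r_inner + (r_outer - r_inner) * theta / (2*pi*turns)``.
    """

    turns: float
    r_inner: float
    r_outer: float
    film_height: float
    pitch: float
    pot_radius: float = 35.0
    pot_depth: float = 150.0
    routing: str = "serpentine"
    orientation: int = 1  # +1 counter-clockwise seen from above
    z_top: float = 0.0

    @property
    def theta_span(self) -> float:
        return 2.0 * np.pi * self.turns

    @property
    def slope(self) -> float:
        """Radial growth per radian of the footprint."""
        return (self.r_outer - self.r_inner) / self.theta_span

    @property
    def n_loops(self) -> int:
        return int(np.floor(self.film_height / self.pitch + 1e-9)) + 1

    @property
    def pass_length(self) -> float:
        return float(_spiral_cumlen(self.r_inner, self.slope, self.theta_span))

    @property
    def total_arc_length(self) -> float:
        return self.n_loops * self.pass_length + (self.n_loops - 1) * self.pitch

    @property
    def arc_origin(self) -> np.ndarray:
        """Start point of the sensed fiber section: footprint start, top pass."""
        return np.array([self.r_inner, 0.0, self.z_top])

    def footprint(self, theta: np.ndarray) -> np.ndarray:
        """(x, y) of the spiral footprint at angle(s) ``theta``."""
        theta = np.asarray(theta, dtype=float)
        r = self.r_inner + self.slope * theta
        ang = self.orientation * theta
        return np.stack([r * np.cos(ang), r * np.sin(ang)], axis=-1)


def build_spiral_geometry(
    turns: float = 1.75,
    r_inner: float = 12.0,
    r_outer: float = 30.0,
    film_height: float = 140.0,
    pitch: float = 20.0,
    pot_radius: float = 35.0,
    pot_depth: float = 150.0,
    routing: str = "serpentine",
    orientation: int = 1,
) -> DeviceGeometry:
    """Validate parameters and build a :class:`DeviceGeometry`.

    Defaults follow the completed device: a 1.75-turn spiral in a 70 mm
    diameter, 150 mm deep pot, fiber passes pitched 15-30 mm apart.
    """
    if not (turns > 0):
        raise ParameterError(f"turns must be positive, got {turns}")
    if not (5.0 <= pitch <= 100.0):
        raise ParameterError(f"pitch {pitch} mm outside the sane 5-100 mm range")
    if not (0 < r_inner <= r_outer):
        raise ParameterError(f"need 0 < r_inner <= r_outer, got {r_inner}, {r_outer}")
    if r_outer > pot_radius:
        raise GeometryError(
            f"spiral outer radius {r_outer} mm exceeds pot radius {pot_radius} mm"
        )
    if film_height > pot_depth:
        raise GeometryError(
            f"film height {film_height} mm exceeds pot depth {pot_depth} mm"
        )
    if film_height <= 0 or pot_depth <= 0:
        raise ParameterError("film_height and pot_depth must be positive")
    if routing not in ("serpentine", "helical"):
        raise ParameterError(f"unknown routing {routing!r}")
    if orientation not in (1, -1):
        raise ParameterError("orientation must be +1 or -1")
    geom = DeviceGeometry(
        turns=float(turns),
        r_inner=float(r_inner),
        r_outer=float(r_outer),
        film_height=float(film_height),
        pitch=float(pitch),
        pot_radius=float(pot_radius),
        pot_depth=float(pot_depth),
        routing=routing,
        orientation=int(orientation),
    )
    if not np.isfinite(geom.total_arc_length) or geom.total_arc_length <= 0:
        raise GeometryError("total arc length must be positive and finite")
    return geom


def spiral_pass_length(geom: DeviceGeometry) -> float:
    """Arc length of one horizontal spiral pass (closed form)."""
    return geom.pass_length


@lru_cache(maxsize=16)
def _theta_of_arclen_table(geom: DeviceGeometry, n: int = 8193):
    """Dense (cumlen, theta) table for inverting the footprint arc length.

    Cumulative lengths at the nodes are exact (closed form); linear
    interpolation between nodes keeps positional error far below the 0.1 mm
    discretization tolerance.
    """
    theta = np.linspace(0.0, geom.theta_span, n)
    cum = _spiral_cumlen(geom.r_inner, geom.slope, theta)
    return cum, theta


def _pass_point(geom: DeviceGeometry, local_s: np.ndarray, k: np.ndarray) -> np.ndarray:
    """3-D point ``local_s`` mm along spiral pass ``k`` (vectorised)."""
    cum, theta_grid = _theta_of_arclen_table(geom)
    L = geom.pass_length
    if geom.routing == "serpentine":
        # odd passes run the footprint backwards so the fiber is continuous
        eff = np.where(k % 2 == 0, local_s, L - local_s)
    else:
        eff = local_s
    theta = np.interp(eff, cum, theta_grid)
    xy = geom.footprint(theta)
    z = geom.z_top + k * geom.pitch
    return np.column_stack([xy[..., 0], xy[..., 1], z])


def arc_to_xyz(geom: DeviceGeometry, s) -> np.ndarray:
    """Map fiber arc-length coordinate(s) ``s`` (mm) to 3-D point(s) (mm).

    The map is continuous and piecewise smooth: within a pass it follows the
    Archimedean footprint, between passes it descends the vertical connector.
    Raises a range error for ``s`` outside ``[0, total_arc_length]``.
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    total = geom.total_arc_length
    if np.any(s_arr < -1e-9) or np.any(s_arr > total + 1e-9):
        raise ParameterError(
            f"arc coordinate outside [0, {total:.3f}] mm: "
            f"min {s_arr.min():.3f}, max {s_arr.max():.3f}"
        )
    s_arr = np.clip(s_arr, 0.0, total)
    L = geom.pass_length
    seg = L + geom.pitch  # one pass + its trailing connector
    k = np.minimum((s_arr / seg).astype(int), geom.n_loops - 1)
    local = s_arr - k * seg

    on_pass = local <= L
    out = np.empty((s_arr.size, 3))
    if np.any(on_pass):
        out[on_pass] = _pass_point(geom, local[on_pass], k[on_pass])
    if np.any(~on_pass):
        # vertical connector at the end point of pass k
        kk = k[~on_pass]
        drop = local[~on_pass] - L
        end = _pass_point(geom, np.full(kk.shape, L), kk)
        end[:, 2] += drop
        out[~on_pass] = end
    if np.isscalar(s) or np.ndim(s) == 0:
        return out[0]
    return out


@dataclass(frozen=True)
class SensorLayout:
    """Gauge segment centres along the fiber and their 3-D positions.

    ``spiral_radius`` is each gauge's horizontal distance from the pot axis,
    used to decide which side of the film a load acts on.
    """

    arc_positions: np.ndarray
    xyz: np.ndarray
    depth: np.ndarray = field(default=None)  # type: ignore[assignment]
    spiral_radius: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        arc = np.asarray(self.arc_positions, dtype=float)
        xyz = np.asarray(self.xyz, dtype=float)
        if arc.ndim != 1 or xyz.shape != (arc.size, 3):
            raise GeometryError("layout arc/xyz shapes inconsistent")
        if arc.size >= 2 and np.any(np.diff(arc) <= 0):
            raise GeometryError("arc positions must be strictly increasing")
        object.__setattr__(self, "arc_positions", arc)
        object.__setattr__(self, "xyz", xyz)
        object.__setattr__(self, "depth", xyz[:, 2].copy())
        object.__setattr__(self, "spiral_radius", np.hypot(xyz[:, 0], xyz[:, 1]))

    def __len__(self) -> int:
        return self.arc_positions.size


def make_sensor_layout(geom: DeviceGeometry, gauge_spacing: float = 30.0) -> SensorLayout:
    """Place gauge points at a regular spacing along the whole sensed fiber.

    The completed device aimed at one gauge per 30 mm of fiber, with adjacent
    segments 15-30 mm apart; spacings above 30 mm are rejected.
    """
    if not (0.0 < gauge_spacing <= 30.0):
        raise ParameterError(f"gauge spacing {gauge_spacing} mm outside (0, 30]")
    total = geom.total_arc_length
    if gauge_spacing > total:
        raise GeometryError(
            f"gauge spacing {gauge_spacing} mm exceeds total arc length {total:.1f} mm"
        )
    n = int(np.floor(total / gauge_spacing + 1e-9)) + 1
    arc = np.arange(n) * gauge_spacing
    xyz = arc_to_xyz(geom, arc)
    layout = SensorLayout(arc_positions=arc, xyz=xyz)
    if np.any(layout.spiral_radius > geom.pot_radius + 1e-9):
        raise GeometryError("layout escapes the pot cylinder")
    return layout


def layout_to_table(layout: SensorLayout) -> np.ndarray:
    """(n, 4) array of (arc_mm, x_mm, y_mm, z_mm) rows for export."""
    return np.column_stack([layout.arc_positions, layout.xyz])
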