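"""Depth-resolved tuber radius profiles from processed strain (secondary growth).

A thickening tuber at the pot centre displaces soil radially and stretches
the surrounding fiber loops; inverting the calibrated strain<->radius map per
depth bin turns a strain snapshot into a radius-vs-depth profile, and a
sequence of snapshots into a growth timeline.  The tuber is modelled as
axisymmetric about the pot axis (seeds are sown at the centre), and the
vertical bin width is floored at the 15 mm vertical resolution the stacked
fiber passes afford.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import DegenerateMeshError, ParameterError
from .forward_models import RadiusModelParams, radius_from_strain
from .geometry import SensorLayout
from .signal_processing import StrainRecord

__all__ = [
    "RadiusProfile",
    "reconstruct_tuber",
    "profile_to_mesh",
    "growth_timeline",
]


@dataclass(frozen=True)
class RadiusProfile:
    """Estimated root radius per contiguous depth bin at one timestamp."""

    bin_edges: np.ndarray  # (n_bins + 1,) mm, contiguous from 0
    radius: np.ndarray  # (n_bins,) mm, >= 0
    timestamp: float = np.nan
    coverage: np.ndarray | None = None  # gauges per bin

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        rad = np.asarray(self.radius, dtype=float)
        if edges.ndim != 1 or rad.size != edges.size - 1:
            raise ParameterError("bin_edges must bracket radius bins")
        if np.any(np.diff(edges) <= 0):
            raise ParameterError("bin edges must be increasing")
        if np.any(rad < 0):
            raise ParameterError("radii must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "radius", rad)

    @property
    def depth_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def max_radius(self) -> float:
        return float(self.radius.max()) if self.radius.size else 0.0


def reconstruct_tuber(
    processed: StrainRecord,
    layout: SensorLayout,
    params: RadiusModelParams = RadiusModelParams(),
    at_time: float | None = None,
    bin_width: float = 15.0,
    agg: str = "max",
) -> RadiusProfile:
    """Invert a strain snapshot into a radius-per-depth-bin profile.

    Gauges are grouped by depth into contiguous bins spanning the film
    height; each bin's strain is aggregated (``max`` by default -- the tuber
    presses hardest on the nearest gauge; ``mean`` optional), negatives are
    clamped to zero radius, and the calibrated map is inverted per bin.
    Bins containing no gauge get radius 0 with a coverage warning.
    """
    if bin_width < 15.0 - 1e-9:
        raise ParameterError(
            f"bin width {bin_width} mm below the 15 mm vertical resolution floor"
        )
    if agg not in ("max", "mean"):
        raise ParameterError(f"unknown aggregation {agg!r}")
    t = processed.times[-1] if at_time is None else at_time
    snap = processed.at_time(t)
    if snap.size != len(layout):
        raise ParameterError("record positions do not match layout")
    depth_top = float(layout.depth.max())
    n_bins = max(int(np.ceil(depth_top / bin_width - 1e-9)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.clip(np.digitize(layout.depth, edges) - 1, 0, n_bins - 1)
    radius = np.zeros(n_bins)
    coverage = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        coverage[b] = int(np.sum(sel))
        if coverage[b] == 0:
            continue
        val = snap[sel].max() if agg == "max" else snap[sel].mean()
        radius[b] = radius_from_strain(max(val, 0.0), params)
    if np.any(coverage == 0):
        warnings.warn(
            f"{int(np.sum(coverage == 0))} depth bin(s) contain no gauge; radius set to 0"
        )
    return RadiusProfile(bin_edges=edges, radius=radius, timestamp=t, coverage=coverage)


def profile_to_mesh(
    profile: RadiusProfile, sections: int = 64, on_empty: str = "raise"
) -> trimesh.Trimesh | None:
    """Revolve a step radius profile into a watertight surface about the pot axis.

    The mesh lives in the device frame (z = depth, mm).  An all-zero profile
    has nothing to revolve: raises :class:`DegenerateMeshError`, or returns
    ``None`` with ``on_empty="none"``.
    """
    if sections < 8:
        raise ParameterError("need at least 8 azimuthal sections")
    rad = profile.radius
    nz = np.nonzero(rad > 0)[0]
    if nz.size == 0:
        if on_empty == "none":
            return None
        raise DegenerateMeshError("all-zero radius profile cannot be meshed")
    first, last = nz[0], nz[-1]
    rad = rad[first : last + 1].copy()
    edges = profile.bin_edges[first : last + 2]
    rad[rad <= 0] = 1e-6  # internal empty bins: keep the surface connected

    # closed cross-section polyline in the (r, z) plane, both ends on the axis
    pts = [(0.0, edges[0])]
    for r, z0, z1 in zip(rad, edges[:-1], edges[1:]):
        pts.append((r, z0))
        pts.append((r, z1))
    pts.append((0.0, edges[-1]))
    mesh = trimesh.creation.revolve(np.array(pts), sections=sections)
    return mesh


def growth_timeline(
    processed: StrainRecord,
    layout: SensorLayout,
    params: RadiusModelParams = RadiusModelParams(),
    times=(),
    bin_width: float = 15.0,
    agg: str = "max",
) -> list[RadiusProfile]:
    """One radius profile per requested time (time-lapse reconstruction)."""
    return [
        reconstruct_tuber(processed, layout, params, at_time=t, bin_width=bin_width, agg=agg)
        for t in times
    ]
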