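"""Synthetic distributed-strain recordings with the structure of real data.

Every recording is the superposition of four terms, mirroring what the
device actually measures:

* **Thermal**: the growth chamber cycles sinusoidally over 24 h (17-21 degC
  for radish, 25-30 degC for rice); the soil attenuates and delays the cycle
  (first-order gain ~0.4 and lag ~2 h), and the film-mounted fiber converts
  temperature to strain at 125 microstrain/degC.  The term is spatially
  common across gauges.
* **Structural baseline**: winding the film pre-strains each gauge by a
  static, position-dependent amount; constant in time.
* **Root term**: tuber growth through the calibrated radius->strain map, or
  rice tips through the point-load kernel.  A tip whose horizontal radius
  exceeds a gauge's spiral radius presses the film from the far side, and
  its contribution at that gauge flips sign -- the device's documented
  failure mode for roots outside the inner spiral layer.
* **Noise**: i.i.d. Gaussian per gauge per sample (seed mandatory).

The returned truth object carries exact tip positions / radius profiles per
time, so recovery by the inverse models can be scored without hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SimulationError
from .forward_models import (
    ElasticParams,
    RadiusModelParams,
    RootTip,
    hoop_strain,
    strain_from_radius,
)
from .geometry import DeviceGeometry, SensorLayout
from .signal_processing import StrainRecord

__all__ = [
    "TipTrajectory",
    "TuberGrowth",
    "Scenario",
    "SimulationTruth",
    "simulate_recording",
    "rice_scenario",
    "radish_scenario",
    "wire_penetration_scenario",
]

_DAY_S = 86400.0


@dataclass(frozen=True)
class TipTrajectory:
    """A root tip descending vertically at constant rate after activation."""

    x: float
    y: float
    z_start: float = 5.0
    z_final: float = 80.0
    rate_mm_per_day: float = 15.0
    t_start_s: float = _DAY_S  # tips activate after the pre-germination day
    load: float | None = None

    def __post_init__(self):
        if self.rate_mm_per_day < 0:
            raise SimulationError("descent rate must be >= 0")
        if self.z_final < self.z_start:
            raise SimulationError("final depth must be >= start depth")

    def depth(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        dz = self.rate_mm_per_day * np.maximum(t - self.t_start_s, 0.0) / _DAY_S
        return np.minimum(self.z_start + dz, self.z_final)

    def active(self, t) -> np.ndarray:
        return np.asarray(t, dtype=float) >= self.t_start_s

    def tip_at(self, t: float) -> RootTip:
        return RootTip(
            position=np.array([self.x, self.y, float(self.depth(t))]),
            load=self.load,
            active=bool(self.active(t)),
        )


@dataclass(frozen=True)
class TuberGrowth:
    """Axisymmetric tuber: radius ramps in time, tapers with depth."""

    max_radius_mm: float = 20.0
    depth_extent_mm: float = 90.0
    t_start_s: float = _DAY_S
    t_full_s: float = 30.0 * _DAY_S

    def radius_at(self, t, depth) -> np.ndarray:
        """Radius (mm) at time(s) ``t`` and depth(s) ``depth``."""
        t = np.asarray(t, dtype=float)
        depth = np.asarray(depth, dtype=float)
        ramp = np.clip((t - self.t_start_s) / (self.t_full_s - self.t_start_s), 0.0, 1.0)
        taper = np.clip(1.0 - depth / self.depth_extent_mm, 0.0, 1.0)
        return self.max_radius_mm * ramp * taper


@dataclass(frozen=True)
class Scenario:
    """Study conditions for one synthetic cultivation run."""

    species: str = "none"  # rice | radish | none
    tips: tuple = ()
    tuber: TuberGrowth | None = None
    temp_mean_c: float = 25.0
    temp_range_c: float = 5.0  # peak-to-peak chamber swing (25-30 degC rice)
    temp_period_h: float = 24.0
    temp_phase_h: float = 0.0
    soil_gain: float = 0.4
    soil_lag_h: float = 2.0
    baseline_amp_ue: float = 200.0
    noise_sigma_ue: float = 1.0
    sampling_interval_s: float = 300.0
    duration_h: float = 96.0
    seed: int | None = None

    def __post_init__(self):
        if self.species not in ("rice", "radish", "none"):
            raise SimulationError(f"unknown species {self.species!r}")
        if self.duration_h * 3600.0 < _DAY_S:
            raise SimulationError("duration must cover the pre-germination day")
        if self.noise_sigma_ue < 0:
            raise SimulationError("noise sigma must be >= 0")


@dataclass(frozen=True)
class SimulationTruth:
    """Exact ground truth per sample time, for recovery scoring."""

    times: np.ndarray
    tip_positions: np.ndarray | None = None  # (n_times, n_tips, 3)
    tip_active: np.ndarray | None = None  # (n_times, n_tips) bool
    tuber: TuberGrowth | None = None
    components: dict = field(default_factory=dict)
    delta_t_soil_c: np.ndarray | None = None

    def tips_at(self, t: float) -> list[RootTip]:
        i = int(np.argmin(np.abs(self.times - t)))
        if self.tip_positions is None:
            return []
        return [
            RootTip(position=p.copy(), active=bool(a))
            for p, a in zip(self.tip_positions[i], self.tip_active[i])
        ]

    def radius_profile_at(self, t: float, bin_edges: np.ndarray) -> np.ndarray:
        if self.tuber is None:
            return np.zeros(len(bin_edges) - 1)
        centers = 0.5 * (np.asarray(bin_edges)[:-1] + np.asarray(bin_edges)[1:])
        return self.tuber.radius_at(t, centers)


def _structural_baseline(scenario: Scenario, layout: SensorLayout) -> np.ndarray:
    """Static winding strain: smooth along the fiber, tension grows with depth."""
    arc = layout.arc_positions
    L = arc[-1] if arc[-1] > 0 else 1.0
    return scenario.baseline_amp_ue * (
        0.6
        + 0.4 * np.sin(2.0 * np.pi * 3.0 * arc / L)
        + 0.3 * layout.depth / max(layout.depth.max(), 1.0)
    )


def _thermal_strain(
    scenario: Scenario, times: np.ndarray, alpha_ue_per_c: float = 125.0
):
    """Soil-side thermal strain trace and the underlying chamber Delta-T."""
    period_s = scenario.temp_period_h * 3600.0
    phase_s = scenario.temp_phase_h * 3600.0
    amp = 0.5 * scenario.temp_range_c
    dT_chamber = amp * np.sin(2.0 * np.pi * (times - phase_s) / period_s)
    lag_s = scenario.soil_lag_h * 3600.0
    dT_soil = scenario.soil_gain * amp * np.sin(
        2.0 * np.pi * (times - phase_s - lag_s) / period_s
    )
    return alpha_ue_per_c * dT_soil, dT_soil, dT_chamber


def _rice_root_term(
    scenario: Scenario,
    layout: SensorLayout,
    params: ElasticParams,
    times: np.ndarray,
):
    n_t, n_g = times.size, len(layout)
    term = np.zeros((n_t, n_g))
    n_tips = len(scenario.tips)
    positions = np.zeros((n_t, n_tips, 3))
    active = np.zeros((n_t, n_tips), dtype=bool)
    gauge_r = layout.spiral_radius
    for j, traj in enumerate(scenario.tips):
        depths = traj.depth(times)
        act = traj.active(times)
        positions[:, j, 0] = traj.x
        positions[:, j, 1] = traj.y
        positions[:, j, 2] = depths
        active[:, j] = act
        # far-side film contact flips the sign of the gauge response
        tip_r = float(np.hypot(traj.x, traj.y))
        side = np.where(tip_r <= gauge_r + 1e-12, 1.0, -1.0)
        for i in np.nonzero(act)[0]:
            tip = RootTip(position=positions[i, j], load=traj.load)
            term[i] += side * hoop_strain(tip, layout.xyz, params)
    return term, positions, active


def _radish_root_term(
    scenario: Scenario,
    layout: SensorLayout,
    radius_params: RadiusModelParams,
    times: np.ndarray,
):
    # radius at each gauge's depth, every sample time (axisymmetric tuber)
    radii = scenario.tuber.radius_at(times[:, None], layout.depth[None, :])
    return strain_from_radius(radii, radius_params)


def simulate_recording(
    scenario: Scenario,
    geometry: DeviceGeometry,
    layout: SensorLayout,
    params: ElasticParams = ElasticParams(),
    radius_params: RadiusModelParams = RadiusModelParams(),
    alpha_ue_per_c: float = 125.0,
):
    """Generate a (StrainRecord, SimulationTruth) pair for a scenario.

    ``record = baseline + thermal + root + noise``; the truth carries each
    component separately plus exact tip/tuber state per time.  Stochastic
    scenarios without a seed are refused.
    """
    if scenario.noise_sigma_ue > 0 and scenario.seed is None:
        raise SimulationError("stochastic scenario needs an explicit seed")
    dt = scenario.sampling_interval_s
    # sample [0, duration): whole diurnal cycles land exactly on DFT bins
    times = np.arange(0.0, scenario.duration_h * 3600.0 - 0.5 * dt, dt)
    n_t, n_g = times.size, len(layout)

    thermal_trace, dT_soil, _ = _thermal_strain(scenario, times, alpha_ue_per_c)
    thermal = np.broadcast_to(thermal_trace[:, None], (n_t, n_g)).copy()
    baseline = np.broadcast_to(
        _structural_baseline(scenario, layout)[None, :], (n_t, n_g)
    ).copy()

    positions = active = None
    if scenario.species == "rice" and scenario.tips:
        root, positions, active = _rice_root_term(scenario, layout, params, times)
    elif scenario.species == "radish" and scenario.tuber is not None:
        root = _radish_root_term(scenario, layout, radius_params, times)
    else:
        root = np.zeros((n_t, n_g))

    if scenario.noise_sigma_ue > 0:
        rng = np.random.default_rng(scenario.seed)
        noise = rng.normal(0.0, scenario.noise_sigma_ue, size=(n_t, n_g))
    else:
        noise = np.zeros((n_t, n_g))

    strain = baseline + thermal + root + noise
    record = StrainRecord(
        times=times,
        arc_positions=layout.arc_positions,
        strain=strain,
        meta={
            "sampling_interval_s": dt,
            "species": scenario.species,
            "seed": scenario.seed,
        },
    )
    truth = SimulationTruth(
        times=times,
        tip_positions=positions,
        tip_active=active,
        tuber=scenario.tuber if scenario.species == "radish" else None,
        components={
            "baseline": baseline,
            "thermal": thermal,
            "root": root,
            "noise": noise,
        },
        delta_t_soil_c=dT_soil,
    )
    return record, truth


def rice_scenario(
    n_tips: int = 3,
    seed: int = 0,
    *,
    inner_radius_mm: float = 12.0,
    outside_layer: bool = False,
    noise_sigma_ue: float = 1.0,
    duration_h: float = 288.0,
    load: float | None = None,
) -> Scenario:
    """Rice study conditions: 25-30 degC cycle, tips seeded inside (or,
    for the failure regime, outside) the inner spiral layer.

    The default 12-day record matches the growth stage at which crown roots
    were first resolvable in cultivation (10-15 days after sowing), with
    descent rates around 10 mm/day.
    """
    rng = np.random.default_rng(seed)
    tips = []
    # crown roots fan out from the stem base: stratified azimuths, and tips
    # kept >= 30 mm apart so each is a distinct, resolvable source (the
    # device's source-separation scale is set by the ~20 mm pass pitch)
    placed: list[np.ndarray] = []
    for j in range(n_tips):
        for _ in range(200):
            ang = 2.0 * np.pi * j / n_tips + rng.uniform(-np.pi / n_tips, np.pi / n_tips)
            if outside_layer:
                r = rng.uniform(inner_radius_mm + 6.0, inner_radius_mm + 16.0)
            else:
                r = rng.uniform(3.0, max(inner_radius_mm - 3.0, 4.0))
            z_final = rng.uniform(40.0, 110.0)
            pos = np.array([r * np.cos(ang), r * np.sin(ang), z_final])
            if all(np.linalg.norm(pos - p) >= 30.0 for p in placed):
                break
        placed.append(pos)
        rate = (z_final - 5.0) / ((duration_h - 36.0) / 24.0)  # reach depth before end
        tips.append(
            TipTrajectory(
                x=float(pos[0]),
                y=float(pos[1]),
                z_start=5.0,
                z_final=float(z_final),
                rate_mm_per_day=float(rate),
                t_start_s=_DAY_S * 1.5,
                load=load,
            )
        )
    return Scenario(
        species="rice",
        tips=tuple(tips),
        temp_mean_c=27.5,
        temp_range_c=5.0,
        noise_sigma_ue=noise_sigma_ue,
        duration_h=duration_h,
        seed=seed,
    )


def radish_scenario(
    seed: int = 0,
    *,
    max_radius_mm: float = 20.0,
    depth_extent_mm: float = 90.0,
    noise_sigma_ue: float = 1.0,
    duration_h: float = 96.0,
) -> Scenario:
    """Radish study conditions: 17-21 degC cycle, one axisymmetric tuber."""
    return Scenario(
        species="radish",
        tuber=TuberGrowth(
            max_radius_mm=max_radius_mm,
            depth_extent_mm=depth_extent_mm,
            t_start_s=_DAY_S,
            t_full_s=duration_h * 3600.0 * 0.9,
        ),
        temp_mean_c=19.0,
        temp_range_c=4.0,
        noise_sigma_ue=noise_sigma_ue,
        duration_h=duration_h,
        seed=seed,
    )


def wire_penetration_scenario(
    diameter_mm: float,
    speed_mm_s: float,
    duration_s: float | None = None,
    base_load: float = 2.0e5,
) -> Scenario:
    """Abiotic fixture: a metal wire descending along the pot axis.

    The load scales with the wire cross-section (diameter squared, relative
    to a 1.2 mm reference wire).  Deterministic (no noise) by construction.
    """
    if not (0.3 <= diameter_mm <= 3.0):
        raise SimulationError(f"wire diameter {diameter_mm} mm outside [0.3, 3] mm")
    if speed_mm_s < 0:
        raise SimulationError("penetration speed must be >= 0")
    load = base_load * (diameter_mm / 1.2) ** 2
    tip = TipTrajectory(
        x=0.0,
        y=0.0,
        z_start=0.0,
        z_final=150.0,
        rate_mm_per_day=speed_mm_s * _DAY_S,
        t_start_s=_DAY_S,  # penetration begins after the quiet baseline day
        load=load,
    )
    dur_h = 24.0 + (duration_s if duration_s is not None else 200.0) / 3600.0
    return Scenario(
        species="rice",
        tips=(tip,),
        noise_sigma_ue=0.0,
        sampling_interval_s=10.0,
        duration_h=dur_h,
        seed=None,
    )


def with_seed(scenario: Scenario, seed: int) -> Scenario:
    """Copy of a scenario with a different noise seed (replicate studies)."""
    return replace(scenario, seed=seed)
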