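# rootfos

Root system architecture from a single distributed fiber-optic strain sensor.

Layers of opaque soil make roots hard to watch.  A strain-sensing optical
fiber wound on a spiral backbone inside a cultivation pot, read out by
optical frequency-domain reflectometry, turns local soil deformation into a
time-resolved strain profile along ~2 m of fiber — and, because every
arc-length coordinate maps to a known 3-D point, into a volumetric root
monitor.  `rootfos` is the computational side of that instrument, for plant
phenotyping researchers who have (or want to prototype against) such
recordings:

- **geometry** — the Archimedean-spiral backbone and the arc-length → 3-D
  spatial encoding (1.75 turns, 70 mm pot, fiber passes pitched 15–30 mm).
- **signal_processing** — exact decomposition of a recording into
  reflectometer noise, the diurnal temperature cycle, static winding strain,
  and root-attributable strain; relative soil temperature falls out of the
  common mode via the 125 µε/°C film-mounted thermal response (~227× bare
  silica).
- **forward_models** — the two physical kernels.  A gravitropic root tip is
  a downward point load `P` in an elastic medium (`G` = 0.1 GPa, ν = 0.5),
  producing hoop strain ε_θθ = P·Δz/(16πG(1−ν)r³) at a gauge; a thickening
  tuber of radius `a` stretches an enclosing fiber loop by
  ε = √(1+(a/d)²) − 1, calibrated so a 0.3 mm diameter root reads 15 µε at
  the 30 mm design spacing.
- **rice_reconstruction** — 3-D crown-root tip localization: peak-finding
  initialization, least-squares refinement of tip coordinates against the
  point-load kernel (normalized residual R = Σ(ε_sim−ε_meas)²/Σε_meas²,
  reported before and after optimization), hyperbolic stem-to-tip paths,
  root counts by depth, and explicit flags for the known failure regimes.
- **radish_reconstruction** — depth-binned tuber radius profiles, growth
  timelines, and a watertight surface of revolution (OBJ export).
- **simulator** — seeded synthetic recordings with the full statistical
  structure of real data (diurnal forcing, soil lag, structural baseline,
  reflectometer noise, root terms from the forward models) plus exact
  ground truth, so every stage is testable without hardware.
- **io_cli** — wide/long strain CSV with provenance headers, RSML export of
  reconstructed root systems, YAML configs, and the `rootfos` command line.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate a 12-day rice pot with three crown roots, separate the signal, and
localize the tips:

```python
import numpy as np
from rootfos import (build_spiral_geometry, make_sensor_layout, ElasticParams,
                     process_pipeline, reconstruct_roots)
from rootfos.simulator import rice_scenario, simulate_recording

geom = build_spiral_geometry()          # 1.75 turns, 12-30 mm radii, 67 gauges
layout = make_sensor_layout(geom)
params = ElasticParams()                # P=2e5, G=0.1 GPa, nu=0.5

scenario = rice_scenario(n_tips=3, seed=5, noise_sigma_ue=2.0)
record, truth = simulate_recording(scenario, geom, layout, params)

processed = process_pipeline(record).processed
system = reconstruct_roots(processed, layout, params)

print(f"roots found: {system.n_roots}")
print(f"residual R:  {system.initial_residual:.4f} -> {system.final_residual:.2e}")
for true_tip in truth.tips_at(record.times[-1]):
    err = min(np.linalg.norm(t.position - true_tip.position) for t in system.tips)
    print(f"planted tip at {np.round(true_tip.position, 1)} recovered within {err:.2f} mm")
```

Output:

```
roots found: 3
residual R:  0.0105 -> 2.63e-04
planted tip at [ 6.3  4.7 76. ] recovered within 0.16 mm
planted tip at [-1.1  3.1 43.4] recovered within 0.13 mm
planted tip at [ -5.4  -7.  102.8] recovered within 0.11 mm
```

Three sources are recovered to sub-millimeter accuracy under 2 µε gauge
noise, and the fit residual drops two orders of magnitude from its
peak-finding initialization — the same pattern (final R below initial R)
that every fitted pot exhibits.

The same flow from a shell:

```sh
rootfos simulate --scenario examples/rice_demo.yaml --out raw.csv --truth truth.json
rootfos process --in raw.csv --out processed.csv
rootfos reconstruct-rice --in processed.csv --out roots.rsml --diagnostics fit.json
rootfos reconstruct-radish --in processed.csv --out profile.csv --mesh tuber.obj
```

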