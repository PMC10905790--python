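# Methods

`rootfos` reconstructs root system architecture from a single distributed
fiber-optic strain sensor (FOS) wound on a spiral backbone inside a
cultivation pot.  This note documents the models, the numerical choices, and
what the synthetic-data studies do and do not demonstrate.

## Device model and spatial encoding

The sensing film is an Archimedean spiral,
`r(θ) = r_inner + (r_outer − r_inner)·θ/(2π·turns)`, with the fiber fixed in
horizontal passes stacked at a constant vertical pitch and joined by short
vertical connectors (serpentine routing: alternate passes run the footprint
in reverse so the fiber is continuous).  Optical frequency-domain
reflectometry resolves strain along the fiber, so the arc-length → 3-D map is
what turns a 1-D sensor into a volumetric one.  Coordinates are cylindrical
about the pot axis with the origin at the soil surface and **z increasing
downward**; units are mm and microstrain (µε) throughout.

Defaults describe the completed device: 1.75 turns, spiral radii 12–30 mm in
a 70 mm diameter, 150 mm deep pot, film height 140 mm, pass pitch 20 mm,
one gauge per 30 mm of fiber (67 gauges over ~2 m).  Spiral arc length is
closed-form (`(b/2)[u√(1+u²) + asinh u]`); the inverse arc-length map uses an
8193-node table whose node values are exact, giving positional error far
below the 0.1 mm discretization tolerance.  The exact serpentine routing is
a declared convention of this package, not a measured property; it is
configurable (`serpentine` / `helical`).

## Signal separation

A raw recording superposes four terms; each pipeline stage removes one, and
each removal is exact (`kept + removed == input` to machine precision):

1. **Spatial smoothing** (reflectometer noise): zero-phase DFT masking along
   the fiber with a raised-cosine edge around the 1/(30 mm) cutoff
   (pass below 0.7·k_c, stop above 1.3·k_c); wavelengths ≥ 60 mm pass
   unchanged.  A zero-phase Butterworth (order 4) and a running median are
   alternatives — the median is the right tool for isolated spikes but is
   the one nonlinear stage.  On records whose gauge pitch is already
   15–30 mm the cutoff sits at or beyond Nyquist and the stage is a no-op by
   construction; it matters for finer-pitched records.
2. **Diurnal notch** (chamber temperature): per gauge, a raised-cosine bump
   of half-width 20 % of 1/(24 h) is removed in the temporal DFT.  The width
   covers chamber-cycle jitter (soil lags the chamber by up to ~2 h); DC and
   hour-scale transients pass (a 1 h Gaussian transient's peak changes by
   ≲2 %).  Notching a *growing* root signal necessarily removes its
   diurnal-band leakage; over a 12-day record this bias is a few µε out of
   hundreds and is the main accuracy limit of the noiseless end-to-end
   studies below.
3. **Pre-germination baseline** (structural winding strain): per-gauge
   temporal mean over the first 24 h is subtracted.
4. **Spatial-average subtraction** (residual common mode): the per-time mean
   across gauges is removed and retained; dividing it by the film-mounted
   thermal coefficient (125 µε/°C; bare silica 0.55 µε/°C, a ~227× ratio)
   yields the relative soil temperature trace.

All stages except the median option are linear, so the pipeline is linear.
Order is configurable; the default is as listed.  For tuber (radish)
inversion the spatial-average stage is **omitted**: the tuber loads most of
the fiber, so its own signal would dominate the "common mode" and be
subtracted away.  Records with gaps are linearly interpolated per gauge at
read time before any DFT stage.

## Forward models

**Primary growth (rice crown roots).**  A gravitropic tip is a downward
point load `P` in an infinite homogeneous elastic medium (shear modulus `G`,
Poisson ratio `ν` — Kelvin problem).  The gauge observable is the hoop
strain about the vertical axis through the tip:

    ε_θθ = P·Δz / (16π·G·(1−ν)·r³)

with `Δz` the sensor depth minus tip depth and `r` the 3-D distance.  It is
linear in `P`, axisymmetric, ∝ 1/G, decays as 1/r² along rays, is positive
below and negative above the tip, and is regular at the incompressible
limit ν = 0.5 (the default, with G = 0.1 GPa).  `P` is kept in the model
units of the per-pot fits (magnitudes 1e5–2.5e6); every downstream estimate
is linear in `P`, so the unit convention is immaterial.  Evaluations closer
than 1 mm to the tip are clamped to the 1 mm sphere (a point load is
unphysical below root-tip scale).  The analytic kernel is cross-checked
against central-difference differentiation of the Kelvin displacement field
to 1e-6 relative.

**Secondary growth (radish tuber).**  A tuber of radius `a` thickening at
the pot axis displaces incompressible soil; a fiber loop at effective radial
stand-off `d` must lengthen to enclose the added cross-section:

    ε(a) = √(1 + (a/d)²) − 1,

diluted by gauge length relative to the 30 mm design spacing.  `d` is
calibrated once from the device's design sensitivity point — a 0.3 mm
*diameter* root must read 15 µε at 30 mm spacing — giving d ≈ 27.39 mm,
comparable to the spiral radius.  The map is strictly increasing and
analytically invertible; inversion clamps sub-threshold and negative
strains to radius 0.

## Inverse models

**Rice tip localization.**  The objective is the normalized residual sum of
squares `R = Σ(ε_sim − ε_meas)² / Σ ε_meas²`, reported at initialization and
after optimization.  Because the pipeline demeaned (and optionally floored)
the measurement, the *same observation operator* — spatial smoothing,
spatial-mean removal, optional flooring — is applied to the forward
prediction inside the objective; without this the model and data live in
different spaces and noiseless recovery is impossible.

Initialization is peak finding along the fiber with a prominence threshold
(3× the noise scale estimated from the pre-germination window, never below
3 % of the tallest peak), followed by 3-D non-maximum suppression: the
serpentine fiber intersects one source's field on several passes, so peaks
within 25 mm of a taller one (45 mm if under 35 % of its height) are the
same source.  Candidates sit at the peak gauge nudged 5 mm toward the pot
axis.  For overlapping sources the driver uses matching pursuit: fit one
tip, subtract its predicted pattern, re-find peaks on the residual, stopping
when a new source improves `R` by less than 2 % (relative) or 0.005.

Refinement is block coordinate descent (per-tip Nelder–Mead restarted from
±15 mm depth offsets, because the strain peak along the fiber sits below
the true tip) interleaved with joint Levenberg–Marquardt polish, two rounds,
loads held fixed.  The best feasible iterate is retained throughout, so the
final `R` never exceeds the initial one.  Tips that converge within 5 mm are
merged, and a tip whose removal changes `R` by under 1 % is pruned as a
ghost (both reported via the `merged-duplicates` flag).  By default the fit
uses the *signed* demeaned snapshot: the kernel's negative lobe above each
tip carries much of the depth information, and flooring it degrades deep-tip
recovery; `floor=0` remains available and mirrors thresholding of far-side
artifacts.

Full roots are drawn from the stem base (pot axis at the surface) to each
tip as a hyperbola-shaped curve `ρ(z) = d·(f(0) − f(z))/(f(0) − b)` with
`f(z) = √(b² + (z_tip − z)²)` and `b = z_tip/2` by default: it passes
exactly through both endpoints and enters a vertical (gravitropic) asymptote
at the tip.  Root counts per depth bin count a root in every bin whose lower
edge is strictly above its tip depth.

Diagnostics are reported, never silently fixed: `poor-fit` when the final
residual exceeds max(10× the expected gauge-noise floor, 0.05);
`negative-strain-regime` when the negative portion of the snapshot is mostly
(> 50 %) unexplained by the fitted model — the signature of roots outside
the inner spiral layer pressing the film from the far side.

**Tuber profile.**  Gauges are grouped into contiguous depth bins (default
width 15 mm, the device's vertical resolution floor; 20 mm — the pass
pitch — is the recommended choice so every bin contains a pass), each bin's
strain is aggregated (max by default: the tuber presses hardest on the
nearest gauge; mean optional) and inverted through the calibrated map.  The
profile revolves into a watertight step surface about the pot axis
(64 azimuthal sections ⇒ volume within 0.2 % of Σπr²Δz).

## Synthetic recordings (what the simulator emulates)

`record = baseline + thermal + root + noise`, with exact per-component truth
retained for scoring:

- **Thermal**: sinusoidal chamber cycles (17–21 °C radish, 25–30 °C rice,
  24 h period); the soil response is first-order — gain 0.4, lag 2 h —
  rather than a heat-diffusion solve, which suffices to exercise the notch.
  Converted at 125 µε/°C, spatially common.
- **Baseline**: a smooth position-dependent winding strain (amplitude
  ~200 µε, tension increasing with depth), constant in time.
- **Root term**: rice tips descend vertically at constant rate after a
  1.5-day activation (defaults ≈ 10 mm/day over a 12-day record, the growth
  stage at which crown roots become resolvable); the radish tuber ramps
  linearly in time with a conical depth taper.  A tip whose horizontal
  radius exceeds a gauge's spiral radius presses the film from the far side
  and its contribution at that gauge is negated — the documented failure
  regime; inside-layer tips reduce exactly to the superposed Kelvin kernel.
- **Noise**: i.i.d. Gaussian per gauge per sample (σ defaults 1 µε); a seed
  is mandatory for stochastic runs and the same seed is bit-reproducible.
- Sampling every 300 s over `[0, duration)` — whole diurnal cycles land
  exactly on DFT bins.  Planted rice tips are stratified in azimuth and kept
  ≥ 30 mm apart: crown roots fan out from the stem, and the device's
  source-separation scale is set by the ~20 mm pass pitch, so closer tips
  are not distinct sources to any method.

What passing these studies does **not** show about real data: soil
constitutive nonlinearity and moisture dependence, non-sinusoidal chamber
cycles, spatially structured reflectometer noise, non-vertical root loads,
lateral-root branching, and the true film mechanics behind the far-side
sign flip are all outside the simulator.  The studies demonstrate internal
consistency of the inverse models with their forward physics under
realistic noise, not field accuracy.

## Study sizes and numerical tolerances

End-to-end recovery studies use 3 planted crown roots per pot (the 12-day
default record), 50 noise replicates at σ = 2 µε for rice and 100 for the
tuber; recovered tips land within 1 mm of truth noiseless and well under
5 mm median under noise, and tuber bins within 1 % noiseless.  Decomposition
identities are asserted at 1e-9, kernel-vs-oracle agreement at 1e-6
relative (oracle step 1e-4 mm), arc-length identities at 1e-9 relative.
Degenerate inputs: flat snapshots yield empty candidate lists and a skipped
reconstruction; an all-zero profile raises a degenerate-mesh error (or
returns nothing on request); a sensor coincident with a tip is evaluated at
the regularization sphere's lower pole.

## Known limitations

- The elastic medium is an infinite space; no traction-free soil surface
  correction is applied.  Near-surface tips (< ~15 mm) are therefore biased.
- Load amplitude `P` is fixed during coordinate fitting (per-pot values are
  treated as parameters); a joint (x, y, z, P) fit is not exposed.
- The tuber model is axisymmetric; azimuthal asymmetry is out of scope.
- Temperature recovery is relative (ΔT), not absolute.
- Two roots closer than ~25 mm are reconstructed as one source.
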