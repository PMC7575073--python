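# Methods

`reefcool` models the feasibility of cooling the seabed over a coral reef by
pumping cool water from a nearby deep channel and releasing it over the reef
flat. It combines three pieces of physics: a residence-time ("reef age")
tracer that identifies reefs where water lingers long enough for an
intervention to act; paired control/injection temperature simulations whose
time-mean difference is the attributed cooling footprint; and a pipe-flow
hydraulics model that prices the pumping energy. Everything runs on
synthetic, desk-scale reef and flow fields, so the pipeline is fully testable
without any ocean-model output.

## Tracer transport model

The solver integrates a depth-averaged passive tracer on a regular masked
grid:

    dc/dt + u . grad(c) = div(K grad(c)) + S

in flux form, with first-order upwind advective face fluxes, explicit
centred (Fickian) diffusion, and forward Euler in time with the operator
order advection → diffusion → source. The diffusion term is implemented in
the standard conservative Fickian form `div(K grad c)`; this is the only
form that conserves the tracer and matches the age-tracer literature.

*Reef age* τ [days] measures how long a water parcel has spent over the
reef: it accumulates at 1 d d⁻¹ in every cell of the *reef mask*
(0 < depth < 10 m), is transported like any passive tracer, and inflowing
open-ocean water carries τ = 0. In a sealed all-reef basin τ(t) = t exactly;
in a steady channel the age at the downstream edge of a reef strip of length
L swept at velocity u converges to L/u (upwind is exact for this piecewise
linear steady profile). Both limits are regression-tested.

*Temperature* is transported identically. A cool-water injection enters as
an in-cell mixing source

    dT/dt = Q (T_inj - T) / V_cell

while its schedule is active ("continuous" or a daily clock window such as
11:00–14:00; clock time is simulation time modulo 24 h from 00:00). The
volume flux displaces resident water rather than adding volume: the free
surface is untouched, and the scheme is contractive, so temperature can
never leave the convex hull of ambient, initial and source temperatures. In
a sealed well-mixed basin of volume V this reduces to exponential flushing
T(t) = T_inj + (T_a − T_inj)·exp(−Qt/V), which is verified against the
analytic solution to 1 %. The near-field plume dynamics of a real outlet
(momentum, buoyant spreading) are *not* modelled; the mixing-source form is
this package's contract.

First-order upwind was chosen over higher-order schemes deliberately: it is
monotone and conservative, so the control-minus-injection cooling signal can
never change sign through numerics — essential when the product is an area
above a small ΔT threshold. The price is numerical diffusion; the
grid-refinement test documents the first-order convergence.

### Stability and degenerate inputs

The explicit scheme enforces, per cell, a Courant number
Σ_faces |F| dt / V ≤ cfl_safety (default 0.9) and a diffusion number
K dt (1/dx² + 1/dy²) ≤ 0.5·cfl_safety; `step` refuses an unstable request
and reports the admissible dt, while the run drivers automatically shrink
dt so it divides the sampling interval. The injection source adds the
constraint Q dt / V_cell ≤ 1. Land cells are excluded from all stencils;
domain-edge faces are open (inflow carries the boundary value, outflow is
zero-gradient) unless the configuration closes them. Zero flow, zero
diffusivity and zero injection are all exact no-ops.

## Synthetic reef, tides and forcing

The generator emulates the geometry that makes a cool-water injection
worth considering: an island with a shallow (< 10 m) annular reef flat
(long residence time), a lagoon, open ocean ≥ 20 m deep, and a ~40 m deep
channel strip holding water about 1 °C cooler than the reef-flat ambient.
Defaults: reef-flat depth 2 m, lagoon 12 m, ocean 30 m, channel 40 m,
ambient 28 °C, source 27 °C. Mild random roughness (2 %) is applied only to
open-ocean cells so the mask-defining depths stay exact; grids are
bit-reproducible for a fixed seed.

Flow is prescribed, not solved: the depth-integrated transport comes from a
streamfunction on cell corners, so the discrete divergence is zero in every
cell *by construction* and finite-volume conservation tests are clean. The
far field is an elliptically rotating tidal transport (default semi-diurnal
period 12.42 h) with amplitude envelope 1 + m·cos(2πt/T_sn), spring-neap
period T_sn = 14.77 d, modulation m = 0.5 (spring:neap = 3:1), plus an
optional steady residual drift. Around land each streamfunction pattern is
replaced by the solution of a discrete Laplace problem with the shoreline
held at a constant — the depth-integrated analogue of potential flow past a
cylinder — which keeps shoreline faces transport-free without creating
spurious jets. The horizontal diffusivity K is a free parameter (default
1–2 m² s⁻¹ at 40 m resolution); no published value exists for the systems
this emulates.

What the generator does **not** reproduce: real bathymetry, wind- and
buoyancy-driven circulation, vertical structure (the water column is a
single layer, so "seabed temperature" means depth-averaged temperature),
surface heat fluxes, and wetting/drying. Consequently the synthetic
footprint areas are qualitative: tests establish *properties* (conservation,
analytic limits, monotonicity of cooled area in injection rate), not the
hectare values a calibrated hindcast-forced model would give for a real
reef.

## Residence statistics and footprint products

Age trajectories are pooled over every reef-mask cell at 3-hourly samples
and summarised by min/q1/median/q3/max and mean (quartiles by linear
interpolation — the convention is logged here because none is standard).
Reefs are ranked by descending mean age, ties broken by median then label.

The cooling footprint bins the per-cell time-mean of (control − injected)
temperature over one spring-neap cycle, across all *footprint-mask* cells
(0 < depth < 20 m), into half-open [lo, hi) bins of width 0.05 °C. Area is
in hectares; bins with ≤ 1 ha are flagged as not displayed but always
retained, so binned area is conserved exactly. Threshold areas sum the bins
at or above an edge-aligned threshold (no interpolation); thresholds quoted
as "> 0.05 °C" and "≥ 0.15 °C" are both implemented as ≥ bin edge, which is
indistinguishable at display precision for half-open bins. Warming cells go
into a single below-zero bin and never count toward threshold areas. The
Degree-Heating-Week relief of a cooling ΔT sustained for d days is
ΔT·d/7 °C-weeks.

## Pipe energy and costs

A site receiving V_total m³ s⁻¹ through n equal pipes of diameter D,
length L and roughness ε is evaluated per pipe (V = V_total/n,
U = V/(πD²/4)):

* Re = ρUD/μ; the rough-pipe correlation requires Re > 4000 and refuses
  laminar inputs.
* Friction factor (Haaland form): 1/√f = −1.8 log₁₀[((ε/D)/3.75)^1.11 + 6.9/Re].
  The constant 3.75 is retained as adopted (standard Haaland uses 3.7; the
  difference is below reporting precision at ε/D = 0.002). A variant that
  reads the right-hand side as 1/f is selectable for transparency, but only
  the square-root form reproduces Moody-chart values, as the cross-check
  against an iterative Colebrook–White solution (agreement within 3 % for
  Re ∈ [10⁴, 10⁸], ε/D ∈ [10⁻⁵, 0.05]) confirms.
* Δp = fρU²L/(2D); P_f = ΔpV; P_m = ½ρVU²; P_l = gV(ρ − ρ_w)h;
  P_c = c_pρV·ΔT. Site totals multiply per-pipe powers by n; P_c uses the
  full site flow.

Defaults: ρ = 1022.72 kg m⁻³ (35 psu seawater at 27 °C), μ = 1.08×10⁻³
kg s⁻¹ m⁻¹, c_p = 4.186 J g⁻¹ °C⁻¹ (converted internally to J kg⁻¹ °C⁻¹),
g = 9.81 m s⁻², D = 1 m, L = 3000 m, h = 40 m, ε = 2 mm, pump efficiency
0.80, energy price 1 currency unit per kWh. The ambient density ρ_w entering
the lift term has no canonical value for this problem; the default 1022.40
kg m⁻³ is the 35-psu density at 28 °C, making the lift term the buoyancy
cost of raising 27 °C water into 28 °C surroundings. P_l is therefore
reported but carries this choice explicitly. An optional `rho_cooling`
override exists because tabulated chilling loads in the engineering
literature are often computed with ρ ≈ 1025 kg m⁻³.

P_T = P_f + P_m + P_l is the pumping load; P_c is never added to cost — the
point of the exercise is that the source water is naturally cool, and P_c
exceeds P_T by more than an order of magnitude in every scenario considered.
Operating cost is P_T × hours / efficiency × price × sites; capital cost is
a flat rate (default 5,000 per metre) per pipe laid.

## Scenario orchestration

`run_scenario` chains generate → simulate → footprint → energy, wraps each
stage so failures identify their stage, and writes NetCDF/CSV/JSON artifacts
plus a manifest containing the package version, seed, a SHA-256 hash of the
canonical config, and a checksum per output file. Outputs contain no
timestamps, so identical configs produce byte-identical bundles. NetCDF is
written through xarray's scipy backend (NetCDF3 classic) with CF-style
coordinates and units attributes.

## Problem sizes

The package targets desk scale by design: demo and test scenarios use grids
of 36–80 cells per side at 40 m resolution and runs of 1.5–15 days; the
scenario sweep property (cooled area non-decreasing across 2/5/10 m³ s⁻¹)
runs a 50×50 grid for one full 14.77-d spring-neap cycle with two sites.
These sizes resolve the reef flat with several cells across and a full
spring-neap modulation while keeping a complete sweep in the minutes range
on one core.

## Known limitations

* Single layer: no stratification, so the benefit of releasing cool water
  "into the bottom layer" (it pools where corals are) is not represented;
  the depth-averaged ΔT dilutes the seabed signal in deep cells.
* Prescribed flow: no feedback of the injection on circulation, no
  wind-driven or baroclinic currents, static depth (no wetting/drying).
* First-order upwind smears plume edges; threshold areas on coarse grids
  are resolution-dependent (the refinement test quantifies convergence).
* The energy model excludes bends, fittings, biofouling, pump curves and
  network optimisation; it brackets feasibility, not engineering design.
* Footprint hectare values from synthetic scenarios characterise the
  method, not any real reef.
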