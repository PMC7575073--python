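# reefcool

Feasibility modelling of **cool-water injection** as a thermal-stress
intervention for coral reefs. Marine heatwaves bleach corals; one proposed
local intervention is to pump naturally cool water from a nearby deep
channel through pipes and release it over the reef flat. Whether that is
worth doing depends on two things this package quantifies:

1. **Does the cool water stay?** A "reef age" tracer τ [days] measures the
   residence time of water over the shallow reef (depth < 10 m):

       ∂τ/∂t + u·∇τ = ∇·(K∇τ) + Φ,   Φ = 1 d d⁻¹ over the reef, 0 elsewhere.

   Reefs whose water lingers (large τ) retain injected cool water; reefs
   flushed every tidal phase do not.

2. **What does it cost and achieve?** Paired control/injection temperature
   simulations give the cooling footprint — the reef area (depth < 20 m)
   whose spring-neap-mean temperature drops by at least a threshold ΔT —
   and a pipe-flow hydraulics model (Reynolds number, Haaland friction
   factor, pressure drop fρU²L/2D) gives the pumping power and cost. The
   thermal-stress relief of a sustained cooling is ΔT × days / 7
   Degree Heating Weeks (DHW).

Everything runs on synthetic island/reef bathymetry with non-divergent
tidal transports (streamfunction-based, spring-neap modulated), so the full
pipeline is testable on a laptop with no ocean-model output. It is aimed at
researchers scoping reef interventions and at anyone who needs a clean,
conservative finite-volume tracer sandbox on masked bathymetry.

## Worked example

Energy budget for supplying one site with 5 m³ s⁻¹ through four 1 m pipes
over 3 km (the `reefcool energy` subcommand prints the same table):

```
$ reefcool energy --rate 5 --pipes 4
      Case V/n  U (m/s)  P_f (kW)  P_m (kW)  P_l (kW)  P_T (kW)  P_c (kW)
    5 m3/s / 4     1.59       456         6         1       464     21406
daily cost per site: $ 13,907
campaign cost (4 sites x 90 d): $ 5,006,458
capital cost per pipe: $ 15,000,000
```

Each pipe carries 1.25 m³ s⁻¹ at 1.59 m s⁻¹; friction dominates the ~464 kW
pumping load. At an 80 % pump efficiency and $1 per kWh, running four such
sites for a 90-day summer costs about $5M in energy — and note P_c: chilling
the same flow by 1 °C with refrigeration would take ~21 MW, fifty times the
pumping load, which is the argument for moving naturally cool water instead.

The simulation side, on a synthetic island (50×50 cells at 40 m, one full
14.77-d spring-neap cycle, two outlets at 5 m³ s⁻¹ injecting 27 °C water
into a 28 °C ambient):

```python
from reefcool import *

grid = make_island_reef(50, 50, 40.0, island_radius=300.0,
                        reef_flat_width=200.0, seed=1)
flow = make_tidal_flow(grid, 0.3, 0.1, residual=(0.02, 0.0), K=2.0)
forcing = make_forcing(28.0, source_temp=27.0)
sites = default_sites(grid, 2, 5.0, forcing.source_temp)
ctrl, inj = run_injection(grid, flow, SolverConfig(dt=60.0), forcing, sites,
                          duration=14.77 * 86400.0, sample_interval=3 * 3600.0)
dT = mean_reduction_field(ctrl, inj)
fp = footprint_histogram(dT, grid)
print(area_at_threshold(fp, 0.05))   # 12.48 ha cooled by >= 0.05 degC
print(area_at_threshold(fp, 0.15))   # 0.32 ha cooled by >= 0.15 degC
print(dhw_reduction(0.15, 90).reduction)  # 1.93 DHW if sustained 90 d
```

Of this island's 158 ha footprint, 12.5 ha end up cooled by at least
0.05 °C — the footprint is small and concentrated near the outlets, and it
grows monotonically with injection rate (a tested invariant). Where the
0.15 °C level is sustained for a 90-day summer, the local thermal-stress
relief is ~1.9 DHW.

The `reefcool` CLI also provides `generate`, `simulate`, `footprint`,
`run-all` (a 2/5/10 m³ s⁻¹ sweep with a comparison table) and `compare`;
all accept a YAML scenario config and write NetCDF/CSV/JSON artifacts with
a checksummed manifest, byte-reproducible for a fixed config and seed.

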