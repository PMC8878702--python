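# stenoflow

Hemodynamics of idealized stenosed abdominal-aortic segments.

Stenosis — the local narrowing of a vessel lumen — reshapes blood flow
in ways that feed back on vascular disease: accelerated jets and high
wall shear stress (WSS) can damage endothelium, while recirculation and
stagnation regions downstream of the throat let platelets reside and
favor thrombus formation and aneurysm growth. `stenoflow` is a small,
tested simulator + analysis pipeline for studying these effects in a
controlled geometry: a planar channel (height D = 15 mm, length
L = 110 mm) carrying an idealized stenosis of ratio `s` with a cosine
profile of width z0 = 15 mm, in three shape models (symmetric,
one-sided, and double/asymmetric), all sharing the throat height
`D(1 − s/100)` at equal `s`.

The core is a 2D incompressible Navier–Stokes solver (projection /
pressure-correction method on a boundary-fitted staggered grid) for
blood as a Newtonian fluid (ρ = 1060 kg/m³, μ = 3.5 mPa·s), driven by a
fully developed inlet at Re ∈ {500, 800, 1200}, steady or pulsatile,

    U(t) = Ū · (1 + 0.5 sin 2πt)   (1 Hz; systole at t = 0.25 s, diastole at 0.75 s),

with no-slip walls and an outlet-gauge pressure reference. On top of
the solver sit the derived quantities of interest: sectional
velocity/pressure averages at the named probe stations (P1, Ps1–Ps3,
P2; Ps4/Ps5 for the double stenosis), pressure drop, signed WSS
τ_w = μ ∂u_t/∂n, wall load (traction magnitude |−p n + 2μ e·n|),
separation/reattachment events, recirculation zones and stagnation
points, plus one-way thin-wall mechanics (Laplace hoop stress
σ_θ = pR/h and radial displacement) with the wall constants E = 0.7 MPa,
ν = 0.49. Closed-form references — plane Poiseuille and Womersley-type
oscillatory channel flow (α ≈ 10.3 at 1 Hz) — are built in as
validation oracles. See `docs/methods.md` for the full model account.

## Worked example

Steady flow through a 50% one-sided stenosis at Re = 1200:

```python
from stenoflow import (FlowConditions, FluidProperties, ProjectionSolver,
                       SolverSettings, StenosisSpec, VesselSpec, build_mesh,
                       probe_locations, sectional_series, wall_fields,
                       detect_separation, pressure_drop)

vessel, fluid = VesselSpec(), FluidProperties()
sten  = StenosisSpec(model=2, s=50)
mesh  = build_mesh(sten, vessel, nz=96, ny=24)
solver = ProjectionSolver(mesh, fluid, FlowConditions(Re=1200),
                          SolverSettings(max_steady_time=6.0))
state, report = solver.solve_steady()

series = sectional_series(state, mesh)
probes = probe_locations(sten, vessel)
dp, _  = pressure_drop(series, probes)
wall   = wall_fields(state, mesh, fluid.mu)
sep    = detect_separation(wall)

print(f"converged={report.converged}  dp={dp:.1f} Pa")
print({k: round(v, 3) for k, v in series.probe_values(probes, 'mean_vmag').items()})
print("separation onsets (upper wall, mm):",
      [round(e.z_separation * 1e3, 1) for e in sep.events if e.side == 'upper'])
```

prints

```
converged=True  dp=195.2 Pa
{'P1': 0.264, 'Ps1': 0.271, 'Ps2': 0.525, 'Ps3': 0.291, 'P2': 0.297}
separation onsets (upper wall, mm): [42.6, 56.3]
```

— the sectional average velocity peaks at the throat Ps2 (0.525 m/s,
about twice the inlet bulk velocity of 0.264 m/s), the stenosis costs
195 Pa of driving pressure over the segment, and the flow separates
from the upper wall just before the stenosis end Ps3 (62.5 mm), feeding
the post-stenotic recirculation region.

Command-line equivalents:

```bash
stenoflow run --model 2 --stenosis-pct 50 --re 1200 --flow steady --out runs/
stenoflow grid --out configs/          # all 54 study scenarios as YAML
stenoflow batch --configs configs/ --out runs/ --workers 2
stenoflow summarize --runs runs/ --out summary.csv
stenoflow validate                     # Poiseuille + Womersley benchmarks
```

The `analysis/` scripts drive the study end to end:
`01_validate_oracles.py` (benchmark error table),
`02_steady_grid.py` (the steady grid and its pressure-drop/WSS trends),
`03_pulsatile_case.py` (three cardiac cycles of a stenosed case,
systole/diastole tables), `04_figures.py` (axial-profile figures with
probe markers). Outputs land under `results/`.

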