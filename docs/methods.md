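# Methods

## Problem and model

`stenoflow` simulates blood flow through an idealized stenosed segment of
the abdominal aorta and computes the wall quantities that matter for
atherogenesis and aneurysm risk: wall shear stress (WSS), wall load
(fluid traction), pressure drop, and the separation / recirculation /
stagnation structure of the flow.

The segment is a planar 2D channel: height `D = 15 mm` ("diameter"),
length `L = 110 mm`, wall thickness `h_wall = 2 mm`. The planar (rather
than axisymmetric) setting is deliberate — two of the three stenosis
shapes are asymmetric about the centerline and have no axisymmetric
counterpart, and the geometry idea comes from 2D angiographic
projections. A stenosis of ratio `s` (percent lumen reduction) is a
cosine indentation of total axial width `z0 = 15 mm`:

    indentation(zeta) = (delta/2) * (1 + cos(2*pi*zeta/z0)),  |zeta| <= z0/2,

with `delta = s/100`, so the profile joins the straight wall with
continuous slope and the throat height is `D*(1 - s/100)` for every
shape model:

* **model 1** (symmetric): both walls indented by `delta*D/2` each;
* **model 2** (one-sided): the full `delta*D` on the upper wall;
* **model 3** (double, asymmetric): two serial full-depth stenoses,
  upper wall on `[zc - z0, zc]`, then lower wall on `[zc, zc + z0]`.

All models at equal `s` therefore share the same minimal lumen, which is
what makes the cross-model comparisons at fixed `s` meaningful. The
stenosis is centered at `zc = L/2` by default (configurable). Named
probe stations follow the field convention: `P1` (pre-stenosis
midpoint), `Ps1`/`Ps2`/`Ps3` (start/throat/end), `P2` (post-stenosis
midpoint); model 3 continues with `Ps4`/`Ps5` for the second stenosis.

Blood is a uniform incompressible Newtonian fluid, `rho = 1060 kg/m^3`,
`mu = 3.5e-3 Pa s`. The inlet is fully developed (parabolic) with bulk
velocity set by the Reynolds number `Re = rho*U*D/mu` over
`Re in {500, 800, 1200}`; pulsatile runs modulate the bulk velocity as

    U(t) = U_mean * (1 + a*sin(2*pi*f*t)),   f = 1 Hz, a = 0.5,

which peaks at cycle phase 0.25 (systole) and bottoms at 0.75
(diastole); `a < 1` guarantees the inlet never refluxes. The study grid
is 3 shape models x s in {30, 50, 70}% x 3 Reynolds numbers x
{steady, pulsatile} = 54 scenarios. (A {20, 50, 70}% ratio variant is
available; the default follows the grid actually exercised in the
comparisons.)

The lumen is rigid for the flow solve. Wall response is one-way: the
computed wall pressure drives thin-wall (Laplace) estimates of hoop
stress `sigma_theta = p*R_local/h_wall` and radial displacement
`dr = p*R_local^2*(1 - nu^2)/(E*h_wall)` with `E = 0.7 MPa`,
`nu = 0.49`, `rho_w = 2000 kg/m^3`. Every run reports `max dr/D`; at
the pressures this grid produces it stays O(1e-4..1e-2), far below the
5% level at which one-way coupling would be questionable — which is the
quantitative justification for the rigid-lumen simplification.

## Discretization

The lumen maps onto the unit-square computational domain by
`y = y_lo(xi) + eta*h(xi)`, `h = y_up - y_lo` (Jacobian `h(xi)`,
positive everywhere; wall nodes sit exactly on the analytic profile).
Physical derivatives follow from `d/dx = d/dxi - (y_xi/h) d/deta`,
`d/dy = (1/h) d/deta`. Default mesh 256 x 64 cells (nz x ny); the
matched test and acceptance runs use desk-scale meshes (96 x 24 and
160 x 40) chosen so every validated quantity is grid-robust at those
sizes — the Poiseuille benchmark documents the observed convergence
rate.

Staggered (MAC) layout in mapped coordinates: `u` on xi-faces, `v` on
eta-faces, `p` at cell centers. Continuity in conservative mapped form,

    d(h u)/dxi + d(v - y_xi*u)/deta = 0,

is differenced exactly over cell faces; the wall faces carry zero
contravariant flux, so the discrete sectional flux `h_u * mean(u)` is
conserved to solver round-off — the conservation checks in the test
suite assert ~1e-12 spread, far inside the 0.5% bound they guard.

Each time level is one incremental pressure-correction (projection)
step:

1. predictor with explicit 2nd-order upwind-biased advection in
   advective form (`u u_xi + W u_eta`, `W = (v - y_xi u)/h` the mapped
   transverse advection speed) and semi-implicit diffusion — the stiff
   wall-normal term `nu*(y_xi^2/h^2 + 1/h^2) d2/deta2` is implicit
   (block-tridiagonal, factorized once per dt), the axial and
   metric-cross terms explicit;
2. pressure Poisson solve with the matrix assembled as the exact
   product `A = D@G` of the discrete divergence and gradient operators
   (sparse LU, factorized once per mesh), so the corrected velocity is
   discretely divergence-free to direct-solver round-off (the per-step
   invariant is < 1e-8 scaled; in practice ~1e-13);
3. velocity/pressure correction.

Boundary conditions: prescribed parabolic inlet; no-slip walls (`v`
wall rows exactly zero, `u` ghosts by no-slip reflection); outlet
zero-gradient velocity rescaled to the instantaneous inlet flux, with
the pressure pinned to 0 at the outlet face (gauge reference). All
reported pressures are outlet-gauge — wall-load magnitudes therefore
exclude any systemic baseline pressure, which shifts `sqrt(p^2+tau^2)`
uniformly but not its spatial structure.

The time step respects an advective CFL bound `<= 0.8` in both mapped
directions, `dt <= 0.8*min(dxi/|u|max, deta/|W|max)`; it is chosen a
priori from a jet-velocity estimate and halved adaptively (pulsatile
runs restart the cycle integration if a mid-run reduction would
misalign the phase snapshots, so snapshots always land exactly on the
requested phases). Pulsatile runs integrate 3 cycles at a base
`dt = 0.4 ms` from rest with the inlet ramped over 0.1 s; the final
cycle is retained at 8 phases. Steady solves are pseudo-time marches
with the same kernel, initialized from a flux-conserving parabolic
guess with a quasi-1D lubrication pressure (the pseudo-transient has no
physical meaning, and this start avoids exciting the slow transverse
viscous mode); convergence is declared when the relative L2 velocity
change per unit time drops below 1e-6. Runs that have not converged by
`max_steady_time` (10 s default) — the expected physical behavior at
high Re and severe stenosis, where the post-stenotic jet sheds — return
the fields time-averaged over the last `steady_window` seconds with an
explicit `unsteady` flag rather than failing.

`SolverSettings.max_inner_iters` exists for configuration compatibility
only: the IMEX projection step is linear, so no inner nonlinear
iterations are performed. The `seed` setting feeds any randomized
initialization; the default initializations are deterministic, so equal
scenarios reproduce bitwise.

## Post-processing definitions

* **Sectional series**: per axial station, area-weighted mean axial
  velocity, mean velocity magnitude, mean pressure, peak velocity
  magnitude, and the (face-exact) flux; probe values by linear
  interpolation.
* **Pressure drop**: inlet-station minus outlet-station mean pressure;
  per-probe drops relative to the inlet station.
* **WSS**: `tau_w = mu * du_t/dn`, the wall-tangential velocity
  differentiated along the wall normal by a one-sided 2nd-order
  difference (quadratic through the wall zero and the first two
  off-wall samples, with the sample distances corrected for wall
  slope). Positive = streamwise on both walls. On the analytic
  Poiseuille field this evaluation is exact to round-off, which is the
  basis of the oracle-equivalence tests.
* **Wall load**: the magnitude of the fluid traction
  `t = -p n + mu (grad u + grad u^T) n`, with the wall velocity
  gradient reconstructed from the no-slip condition (tangential
  derivatives vanish along the wall).
* **Separation/reattachment**: streamwise +/- and -/+ zero crossings of
  the WSS, located by linear interpolation; events shorter than 2 axial
  cells are discarded as discretization noise; reversed flow persisting
  to the domain end is reported as a truncated event.
* **Recirculation zones**: 4-connected components of cells with
  strictly negative axial velocity touching a wall-adjacent row; each
  zone reports side, axial extent and area. **Stagnation points**:
  wall-adjacent cells with `|V| < 1e-3 * U_mean` upstream of the
  stenosis start. Both thresholds are package choices (no tolerance
  band on reversal; 1e-3 on stagnation).

## Analytic oracles

Plane Poiseuille (steady) and oscillatory channel flow of Womersley
type (`alpha = (D/2)*sqrt(omega*rho/mu) ≈ 10.3` at 1 Hz) are exact
parallel-flow solutions of the Navier-Stokes equations and serve as
independent references. The Womersley solution is flux-matched to the
pulsatile inlet waveform; because parallel channel flow is an exact
solution at any amplitude (advection vanishes identically), the
comparison is valid at the full a = 0.5 modulation. The pulsatile
benchmark probes the profile at z = 0.75 L, past the oscillatory
entrance length `~U/omega`, where the parabolic-inlet transient of the
oscillatory component has relaxed onto the Womersley profile. The
Poiseuille field injected into the solver's interior stencils balances
momentum to < 1e-8 (every stencil is exact on a parabola with linear
pressure); the Womersley oracle satisfies its PDE with closed-form
derivatives to round-off — a discrete 2nd-order operator applied to the
cosh-shaped profile would instead show its O(deta^2) truncation error,
so operator-consistency at 1e-8 is asserted on the polynomial oracle.

## What the scenario generator does and does not emulate

The study inputs are entirely analytic, so the scenario module *is* the
data source: it enumerates the factorial grid above and draws
randomized geometries (s ~ U[10,80]%, Re ~ U[100,1200], jittered
center) for property tests. It does not emulate: 3D/axisymmetric
geometry, curved centerlines or patient-specific lumens, non-Newtonian
rheology, physiological (non-sinusoidal) waveforms, compliant-wall
feedback on the flow, or measurement noise — passing tests demonstrate
internal correctness of the model class, not fidelity to any individual
patient's hemodynamics.

## Behavior worth knowing about (and limitations)

* **Vena contracta**: the *peak* velocity of a resolved solution sits
  slightly downstream of the geometric throat (the jet keeps
  contracting past it), so throat landmarks are stated on the sectional
  *average* velocity, which is maximal at the throat (Ps2 for models
  1-2, Ps4 for model 3) — the quantity the cross-model comparisons use.
* **Pressure recovery**: with a separated post-stenotic jet the
  recovery is largely suppressed, so the sectional-pressure minimum
  sits at or downstream of the stenosis end rather than exactly at the
  throat.
* **Symmetry breaking**: the symmetric model-1 expansion at s = 70%
  passes through a pitchfork as Re grows — the jet attaches to one wall
  (Coanda) — and near the transition the flow settles slowly; the s=70
  steady runs are marched 16 s of pseudo-time so the asymmetric steady
  states (and the growth of the recirculation area with Re) are
  resolved rather than averaged mid-transient.
* **Serial stenoses (model 3)**: the second, opposite-wall stenosis
  re-deflects a jet that is already biased by the first one, so model 3
  exhibits a *higher* peak throat velocity and a larger total pressure
  drop than the single-throat models at equal s — two equal throats in
  series dissipate more than one. This is a robust property of the
  rigid-wall serial-throat geometry.
* The solver is laminar/transitional by construction (direct time
  integration, no turbulence model); at the highest Re x s corners the
  reported "continuous flow" fields are time averages with the unsteady
  flag set, as reported in each run's convergence record.
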