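#!/usr/bin/env python
"""Validate the solver against the analytic oracles.

Runs the unobstructed channel steady (plane Poiseuille) and pulsatile
(Womersley) benchmarks and writes the error table to
results/validation.csv.  Expected outcome: profile/pressure/WSS errors
well under 2% steady, centerline profile within 5% pulsatile.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from stenoflow.flow import FlowConditions, FluidProperties, ProjectionSolver, SolverSettings
from stenoflow.geometry import StenosisSpec, VesselSpec, build_mesh
from stenoflow.oracles import WomersleyChannel, poiseuille_wss
from stenoflow.postprocess import wall_fields


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--nz", type=int, default=128)
    ap.add_argument("--ny", type=int, default=32)
    ap.add_argument("--out", default="results/validation.csv")
    args = ap.parse_args()

    vessel, fluid = VesselSpec(), FluidProperties()
    mesh = build_mesh(StenosisSpec(model=1, s=0.0), vessel, args.nz, args.ny)
    rows = []

    cond = FlowConditions(Re=500)
    solver = ProjectionSolver(mesh, fluid, cond, SolverSettings(max_steady_time=4.0))
    state, rep = solver.solve_steady()
    ub = cond.u_mean(fluid, vessel)
    exact = 1.5 * ub * (1 - (2 * mesh.eta_c - 1) ** 2)
    prof_err = float(np.abs(state.u[mesh.nz // 2] - exact).max() / (1.5 * ub))
    wall = wall_fields(state, mesh, fluid.mu)
    tau_err = abs(wall.wss["lower"][mesh.nz // 2] / poiseuille_wss(fluid, cond, vessel) - 1)
    p_mean = state.p.mean(axis=1)
    slope = np.polyfit(mesh.z_c[10:-10], p_mean[10:-10], 1)[0]
    dp_err = abs(slope / (-12 * fluid.mu * ub / vessel.D**2) - 1)
    rows += [
        {"benchmark": "poiseuille", "quantity": "profile_max_rel_err", "value": prof_err},
        {"benchmark": "poiseuille", "quantity": "wss_rel_err", "value": float(tau_err)},
        {"benchmark": "poiseuille", "quantity": "dpdz_rel_err", "value": float(dp_err)},
        {"benchmark": "poiseuille", "quantity": "converged", "value": float(rep.converged)},
    ]
    print(f"Poiseuille: profile {prof_err:.2e}, WSS {tau_err:.2e}, dp/dz {dp_err:.2e}")

    cond_p = FlowConditions(Re=500, waveform="sinusoidal")
    solver = ProjectionSolver(mesh, fluid, cond_p, SolverSettings(n_cycles=3, snapshot_phases=8))
    result = solver.solve_pulsatile()
    oracle = WomersleyChannel(vessel, fluid, cond_p)
    i = int(0.75 * mesh.nz)
    y = mesh.eta_c * vessel.D
    for k, ph in enumerate(result.phases):
        st = result.snapshots[k]
        uc = 0.5 * (st.u[i] + st.u[i + 1])
        ex = oracle.velocity(y, ph / cond_p.f)
        err = float(np.linalg.norm(uc - ex) / np.linalg.norm(ex))
        rows.append({"benchmark": "womersley", "quantity": f"profile_rel_err_phase_{ph:.3f}", "value": err})
    rows.append({"benchmark": "womersley", "quantity": "cycle_periodicity", "value": result.periodicity_error()})
    errs = [r["value"] for r in rows if r["benchmark"] == "womersley" and "profile" in r["quantity"]]
    print(f"Womersley: worst phase profile error {max(errs):.2e}, periodicity {result.periodicity_error():.2e}")

    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
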