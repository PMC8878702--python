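"""File interfaces: CSV outputs, VTK structured-grid export, YAML configs."""
from __future__ import annotations

import hashlib
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .flow import FieldState, FlowConditions, FluidProperties, SolverSettings
from .geometry import Mesh, StenosisSpec, VesselSpec
from .scenarios import StenosisScenario
from .wall_mechanics import WallProperties


def write_geometry_csv(mesh: Mesh, path: str | Path) -> None:
    """Two-column wall profile (z, y_lo, y_up) in meters."""
    df = pd.DataFrame({"z": mesh.z_c, "y_lo": mesh.y_lo_c, "y_up": mesh.y_up_c})
    df.to_csv(path, index=False)


def write_vts(mesh: Mesh, state: FieldState, path: str | Path) -> None:
    """ASCII VTK XML StructuredGrid (.vts) with point arrays u, v, p.

    Fields are sampled at mesh nodes by averaging the adjacent staggered
    values; plain-text output readable by ParaView/VTK.
    """
    nz, ny = mesh.nz, mesh.ny
    Z, Y = mesh.node_coordinates()
    # node-sampled fields
    u_n = np.zeros((nz + 1, ny + 1))
    u_n[:, 1:-1] = 0.5 * (state.u[:, :-1] + state.u[:, 1:])
    v_n = np.zeros((nz + 1, ny + 1))
    v_n[1:-1, :] = 0.5 * (state.v[:-1, :] + state.v[1:, :])
    v_n[0, :] = state.v[0, :]
    v_n[-1, :] = state.v[-1, :]
    p_pad = np.pad(state.p, ((1, 1), (1, 1)), mode="edge")
    p_n = 0.25 * (p_pad[:-1, :-1] + p_pad[1:, :-1] + p_pad[:-1, 1:] + p_pad[1:, 1:])

    def ascii_block(arr: np.ndarray) -> str:
        return " ".join(f"{x:.9g}" for x in arr.ravel(order="F"))

    pts = np.stack([Z, Y, np.zeros_like(Z)], axis=-1)
    pts_flat = " ".join(
        f"{pts[i, j, 0]:.9g} {pts[i, j, 1]:.9g} 0"
        for j in range(ny + 1)
        for i in range(nz + 1)
    )
    ext = f"0 {nz} 0 {ny} 0 0"
    xml = f"""<?xml version="1.0"?>
<VTKFile type="StructuredGrid" version="0.1" byte_order="LittleEndian">
  <StructuredGrid WholeExtent="{ext}">
    <Piece Extent="{ext}">
      <PointData Scalars="p" Vectors="velocity">
        <DataArray type="Float64" Name="u" format="ascii">{ascii_block(u_n)}</DataArray>
        <DataArray type="Float64" Name="v" format="ascii">{ascii_block(v_n)}</DataArray>
        <DataArray type="Float64" Name="p" format="ascii">{ascii_block(p_n)}</DataArray>
      </PointData>
      <Points>
        <DataArray type="Float64" Name="points" NumberOfComponents="3" format="ascii">{pts_flat}</DataArray>
      </Points>
    </Piece>
  </StructuredGrid>
</VTKFile>
"""
    Path(path).write_text(xml)


def write_field_series(
    mesh: Mesh,
    states: list,
    phases: list,
    outdir: str | Path,
    prefix: str = "field",
) -> Path:
    """Write a time series of field snapshots: one .vts per phase plus an
    index CSV (phase, filename)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for phase, state in zip(phases, states):
        name = f"{prefix}_phase{float(phase):.4f}.vts"
        write_vts(mesh, state, outdir / name)
        rows.append({"phase": float(phase), "filename": name})
    index = outdir / f"{prefix}_series.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def scenario_to_config(sc: StenosisScenario) -> dict:
    return {
        "vessel": {"D": sc.vessel.D, "L": sc.vessel.L, "h_wall": sc.vessel.h_wall},
        "stenosis": {
            "model": sc.stenosis.model,
            "s": sc.stenosis.s,
            "z0": sc.stenosis.z0,
            "zc": sc.stenosis.zc,
        },
        "fluid": {"rho": sc.fluid.rho, "mu": sc.fluid.mu},
        "flow": {
            "Re": sc.conditions.Re,
            "waveform": sc.conditions.waveform,
            "f": sc.conditions.f,
            "amplitude": sc.conditions.amplitude,
        },
        "wall": {
            "E": sc.wall.E,
            "nu": sc.wall.nu,
            "rho_w": sc.wall.rho_w,
            "h_wall": sc.wall.h_wall,
        },
        "solver": {
            "dt": sc.settings.dt,
            "n_cycles": sc.settings.n_cycles,
            "max_inner_iters": sc.settings.max_inner_iters,
            "steady_tol": sc.settings.steady_tol,
            "max_steady_time": sc.settings.max_steady_time,
            "steady_window": sc.settings.steady_window,
            "cfl": sc.settings.cfl,
            "ramp_time": sc.settings.ramp_time,
            "snapshot_phases": sc.settings.snapshot_phases,
            "seed": sc.settings.seed,
        },
        "mesh": {"nz": sc.nz, "ny": sc.ny},
        "label": sc.label,
    }


def scenario_from_config(cfg: dict) -> StenosisScenario:
    v = cfg.get("vessel", {})
    st = cfg.get("stenosis", {})
    fl = cfg.get("fluid", {})
    fw = cfg.get("flow", {})
    wl = cfg.get("wall", {})
    sv = cfg.get("solver", {})
    ms = cfg.get("mesh", {})
    return StenosisScenario(
        vessel=VesselSpec(**v),
        stenosis=StenosisSpec(**st),
        fluid=FluidProperties(**fl),
        conditions=FlowConditions(**fw),
        wall=WallProperties(**wl),
        settings=SolverSettings(**sv),
        nz=int(ms.get("nz", 256)),
        ny=int(ms.get("ny", 64)),
        label=cfg.get("label", ""),
    ).with_label()


def save_scenario_yaml(sc: StenosisScenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_config(sc), sort_keys=False))


def load_scenario_yaml(path: str | Path) -> StenosisScenario:
    return scenario_from_config(yaml.safe_load(Path(path).read_text()))


def config_hash(sc: StenosisScenario) -> str:
    blob = yaml.safe_dump(scenario_to_config(sc), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
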