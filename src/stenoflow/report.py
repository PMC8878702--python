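"""Batch execution and summary tables over the scenario grid.

``run_scenario`` executes one case end to end (solve, post-process,
wall mechanics) and optionally writes the standard CSV set; ``run_batch``
maps it over a grid with per-scenario failure isolation; ``summarize``
collects the per-run CSVs into a tidy long-format table.
"""
from __future__ import annotations

import time
import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .flow import ProjectionSolver, PulsatileResult, SteadyReport
from .geometry import build_mesh, probe_locations
from .postprocess import (
    SectionSeries,
    SeparationReport,
    WallProfile,
    detect_recirculation,
    detect_separation,
    pressure_drop,
    sectional_series,
    total_recirculation_area,
    wall_fields,
)
from .scenarios import StenosisScenario
from .wall_mechanics import compliance_report, hoop_stress, radial_displacement


@dataclass
class PhaseResult:
    """Post-processed quantities for one field snapshot (phase or steady)."""

    phase: str                      # "steady" | "systole" | "diastole" | "phase_<x>"
    state: object                   # the FieldState that was post-processed
    series: SectionSeries
    wall: WallProfile
    separation: SeparationReport
    recirculation: SeparationReport
    dp_total: float
    dp_probes: Dict[str, float]


@dataclass
class RunResult:
    scenario: StenosisScenario
    mesh: object
    phases: List[PhaseResult]
    steady_report: Optional[SteadyReport] = None
    pulsatile: Optional[PulsatileResult] = None
    wall_mech: Optional[pd.DataFrame] = None
    compliance: Optional[dict] = None
    runtime_s: float = 0.0

    @property
    def steady(self) -> PhaseResult:
        return self.phases[0]


@dataclass
class RunManifest:
    label: str
    config_hash: str
    converged: bool
    unsteady: bool
    compliance_flag: bool
    runtime_s: float
    outputs: List[str] = field(default_factory=list)
    error: str = ""


def _postprocess_state(state, mesh, mu, probes, phase) -> PhaseResult:
    series = sectional_series(state, mesh)
    wall = wall_fields(state, mesh, mu)
    sep = detect_separation(wall)
    rec = detect_recirculation(state, mesh)
    dp, dpp = pressure_drop(series, probes)
    return PhaseResult(
        phase=phase,
        state=state,
        series=series,
        wall=wall,
        separation=sep,
        recirculation=rec,
        dp_total=dp,
        dp_probes=dpp,
    )


def run_scenario(
    sc: StenosisScenario,
    nz: int | None = None,
    ny: int | None = None,
    outdir: str | Path | None = None,
) -> RunResult:
    """Solve one scenario end to end and post-process every phase."""
    sc = sc.with_label()
    t0 = time.time()
    mesh = build_mesh(sc.stenosis, sc.vessel, nz or sc.nz, ny or sc.ny)
    probes = probe_locations(sc.stenosis, sc.vessel)
    solver = ProjectionSolver(mesh, sc.fluid, sc.conditions, sc.settings)
    phases: List[PhaseResult] = []
    steady_report = None
    pulsatile = None
    if sc.conditions.waveform == "steady":
        state, steady_report = solver.solve_steady()
        phases.append(_postprocess_state(state, mesh, sc.fluid.mu, probes, "steady"))
        ref_state = state
    else:
        pulsatile = solver.solve_pulsatile()
        for name, ph in (("systole", 0.25), ("diastole", 0.75)):
            phases.append(
                _postprocess_state(
                    pulsatile.at_phase(ph), mesh, sc.fluid.mu, probes, name
                )
            )
        ref_state = pulsatile.systole
    # one-way wall mechanics from the reference-phase wall pressure
    wall = phases[0].wall
    r_local = mesh.h_c / 2.0
    rows = []
    for side in ("lower", "upper"):
        pw = wall.p_wall[side]
        rows.append(
            pd.DataFrame(
                {
                    "z": mesh.z_c,
                    "side": side,
                    "sigma_theta": hoop_stress(pw, r_local, sc.vessel),
                    "delta_r": radial_displacement(pw, r_local, sc.vessel, sc.wall),
                }
            )
        )
    wall_mech = pd.concat(rows, ignore_index=True)
    comp = compliance_report(
        np.concatenate([wall.p_wall["lower"], wall.p_wall["upper"]]),
        np.concatenate([r_local, r_local]),
        sc.vessel,
        sc.wall,
    )
    result = RunResult(
        scenario=sc,
        mesh=mesh,
        phases=phases,
        steady_report=steady_report,
        pulsatile=pulsatile,
        wall_mech=wall_mech,
        compliance=comp,
        runtime_s=time.time() - t0,
    )
    if outdir is not None:
        write_run_csvs(result, Path(outdir))
    return result


def write_run_csvs(result: RunResult, outdir: Path) -> List[str]:
    """Write the standard CSV set for one run; returns the paths."""
    outdir = Path(outdir) / result.scenario.label
    outdir.mkdir(parents=True, exist_ok=True)
    mesh = result.mesh
    probes = probe_locations(result.scenario.stenosis, result.scenario.vessel)
    paths: List[str] = []

    def _save(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False)
        paths.append(str(p))

    for ph in result.phases:
        tag = "" if ph.phase == "steady" else f"_{ph.phase}"
        s = ph.series
        _save(
            pd.DataFrame(
                {
                    "z": s.z,
                    "mean_u": s.mean_u,
                    "mean_vmag": s.mean_vmag,
                    "mean_p": s.mean_p,
                    "flux": s.flux,
                    "max_vmag": s.max_vmag,
                }
            ),
            f"sections{tag}.csv",
        )
        for side in ("lower", "upper"):
            _save(
                pd.DataFrame(
                    {
                        "z": ph.wall.z,
                        "wss": ph.wall.wss[side],
                        "traction": ph.wall.traction[side],
                        "p_wall": ph.wall.p_wall[side],
                    }
                ),
                f"wall_{side}{tag}.csv",
            )
        ev = pd.DataFrame(
            [
                {
                    "kind": "separation",
                    "side": e.side,
                    "z_start": e.z_separation,
                    "z_end": e.z_reattachment,
                    "area": np.nan,
                }
                for e in ph.separation.events
            ]
            + [
                {
                    "kind": "recirculation",
                    "side": zn.side,
                    "z_start": zn.z_min,
                    "z_end": zn.z_max,
                    "area": zn.area,
                }
                for zn in ph.recirculation.zones
            ]
        )
        _save(ev, f"events{tag}.csv")
        probe_rows = []
        for q in ("mean_u", "mean_vmag", "mean_p", "max_vmag"):
            for name, val in s.probe_values(probes, q).items():
                probe_rows.append({"probe": name, "quantity": q, "value": val})
        _save(pd.DataFrame(probe_rows), f"probes{tag}.csv")
    _save(result.wall_mech, "wall_mech.csv")
    sio.write_geometry_csv(mesh, outdir / "geometry.csv")
    paths.append(str(outdir / "geometry.csv"))
    return paths


def _run_one(args) -> RunManifest:
    sc, outdir, nz, ny = args
    sc = sc.with_label()
    try:
        res = run_scenario(sc, nz=nz, ny=ny)
        outputs = write_run_csvs(res, Path(outdir)) if outdir else []
        rep = res.steady_report
        return RunManifest(
            label=sc.label,
            config_hash=sio.config_hash(sc),
            converged=bool(rep.converged) if rep else True,
            unsteady=bool(rep.unsteady) if rep else False,
            compliance_flag=bool(res.compliance["exceeds_threshold"]),
            runtime_s=res.runtime_s,
            outputs=outputs,
        )
    except Exception:
        return RunManifest(
            label=sc.label,
            config_hash=sio.config_hash(sc),
            converged=False,
            unsteady=False,
            compliance_flag=False,
            runtime_s=0.0,
            error=traceback.format_exc(limit=3),
        )


def run_batch(
    scenarios: Sequence[StenosisScenario],
    outdir: str | Path | None = None,
    parallel_workers: int = 1,
    nz: int | None = None,
    ny: int | None = None,
) -> List[RunManifest]:
    """Execute a list of scenarios; per-scenario failures are isolated.

    With ``parallel_workers > 1`` independent scenarios run in separate
    processes; results are identical to serial execution because every
    run is deterministic given its scenario.
    """
    jobs = [(sc, str(outdir) if outdir else None, nz, ny) for sc in scenarios]
    if parallel_workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=parallel_workers) as ex:
            manifests = list(ex.map(_run_one, jobs))
    else:
        manifests = [_run_one(j) for j in jobs]
    if outdir is not None and manifests:
        pd.DataFrame([m.__dict__ for m in manifests]).drop(columns=["outputs"]).to_csv(
            Path(outdir) / "manifest.csv", index=False
        )
    return manifests


def summarize(results: Sequence[RunResult]) -> pd.DataFrame:
    """Tidy long-format comparison table across runs.

    Columns: model, s, Re, waveform, phase, probe, quantity, value.
    Besides per-probe extractions it includes scalar rows (probe='-')
    for dp_total, max/min WSS and total recirculation area.
    """
    rows = []
    for res in results:
        sc = res.scenario
        probes = probe_locations(sc.stenosis, sc.vessel)
        base = {
            "model": sc.stenosis.model,
            "s": sc.stenosis.s,
            "Re": sc.conditions.Re,
            "waveform": sc.conditions.waveform,
        }
        for ph in res.phases:
            for q in ("mean_u", "mean_vmag", "mean_p", "max_vmag"):
                for name, val in ph.series.probe_values(probes, q).items():
                    rows.append(
                        {**base, "phase": ph.phase, "probe": name, "quantity": q, "value": val}
                    )
            wss_all = np.concatenate([ph.wall.wss["lower"], ph.wall.wss["upper"]])
            scalars = {
                "dp_total": ph.dp_total,
                "wss_max": float(wss_all.max()),
                "wss_min": float(wss_all.min()),
                "recirc_area": total_recirculation_area(ph.recirculation),
            }
            for q, val in scalars.items():
                rows.append(
                    {**base, "phase": ph.phase, "probe": "-", "quantity": q, "value": val}
                )
    return pd.DataFrame(rows)


def summary_pivot(table: pd.DataFrame, quantity: str, phase: str = "steady") -> pd.DataFrame:
    sel = table[(table.quantity == quantity) & (table.phase == phase)]
    return sel.pivot_table(index=["model", "s"], columns="Re", values="value")
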