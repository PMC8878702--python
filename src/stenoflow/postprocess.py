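"""Derived quantities: sectional averages, pressure drop, wall shear
stress, wall load (traction), and separation/recirculation/stagnation
detection.

Sign convention for wall shear stress: tau_w = mu * du_t/dn with the
tangent pointing in +z and the normal pointing into the fluid, so
tau_w > 0 where the near-wall flow is streamwise, on both walls; a
streamwise zero crossing + -> - marks flow separation, - -> + marks
reattachment.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .flow import FieldState
from .geometry import Mesh, ProbeSet


def _center_velocity(state: FieldState) -> Tuple[np.ndarray, np.ndarray]:
    """Velocity components interpolated to cell centers (nz, ny)."""
    uc = 0.5 * (state.u[:-1, :] + state.u[1:, :])
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    return uc, vc


@dataclass
class SectionSeries:
    """Per-axial-station averages and extrema over the lumen cross-section."""

    z: np.ndarray           # cell-center stations, m
    mean_u: np.ndarray      # area-weighted mean axial velocity, m/s
    mean_vmag: np.ndarray   # area-weighted mean velocity magnitude, m/s
    mean_p: np.ndarray      # mean pressure, Pa
    flux: np.ndarray        # volumetric flux per unit width, m^2/s
    max_vmag: np.ndarray    # peak velocity magnitude on the section, m/s

    def probe_values(self, probes: ProbeSet, quantity: str = "mean_vmag") -> Dict[str, float]:
        arr = getattr(self, quantity)
        return {name: float(np.interp(z, self.z, arr)) for name, z in probes.items()}

    def at(self, z: float, quantity: str = "mean_vmag") -> float:
        return float(np.interp(z, self.z, getattr(self, quantity)))


def sectional_series(state: FieldState, mesh: Mesh) -> SectionSeries:
    """Area-weighted sectional averages along every transverse mesh line.

    With the linear wall-to-wall stretching the transverse spacing is
    uniform within each station, so the area weighting reduces to plain
    means over eta.
    """
    uc, vc = _center_velocity(state)
    vmag = np.hypot(uc, vc)
    # flux from the xi-face values: these are the discretely conserved
    # volume fluxes, exactly constant in z for a projected field
    flux_faces = mesh.h_u * state.u.mean(axis=1)
    return SectionSeries(
        z=mesh.z_c.copy(),
        mean_u=uc.mean(axis=1),
        mean_vmag=vmag.mean(axis=1),
        mean_p=state.p.mean(axis=1),
        flux=0.5 * (flux_faces[:-1] + flux_faces[1:]),
        max_vmag=vmag.max(axis=1),
    )


def pressure_drop(
    series: SectionSeries, probes: Optional[ProbeSet] = None
) -> Tuple[float, Dict[str, float]]:
    """Inlet-to-outlet mean pressure drop (Pa) and per-probe drops.

    Per-probe values are the drop from the inlet station to each probe.
    """
    p_in = float(series.mean_p[0])
    total = p_in - float(series.mean_p[-1])
    per_probe: Dict[str, float] = {}
    if probes is not None:
        for name, z in probes.items():
            per_probe[name] = p_in - series.at(z, "mean_p")
    return total, per_probe


@dataclass
class WallProfile:
    """Axial profiles of WSS, traction magnitude and pressure on each wall."""

    z: np.ndarray
    wss: Dict[str, np.ndarray]        # side -> signed tau_w, Pa
    traction: Dict[str, np.ndarray]   # side -> |t|, Pa
    p_wall: Dict[str, np.ndarray]     # side -> pressure at the wall, Pa
    sides: Tuple[str, str] = ("lower", "upper")


def _one_sided_wall_gradient(f1: np.ndarray, f2: np.ndarray, d1: np.ndarray, d2: np.ndarray):
    """d/dn at the wall from two off-wall samples of a field vanishing at
    the wall; 2nd-order one-sided (quadratic through 0, f1, f2)."""
    return (d2**2 * f1 - d1**2 * f2) / (d1 * d2 * (d2 - d1))


def wall_fields(state: FieldState, mesh: Mesh, fluid_mu: float) -> WallProfile:
    """WSS, traction magnitude and wall pressure on both walls.

    tau_w = mu * du_t/dn from a one-sided 2nd-order difference of the
    wall-tangential velocity along the wall-normal; traction is
    t = -p n + mu (grad u + grad u^T) n with the full velocity gradient
    reconstructed from the no-slip condition (tangential derivatives of
    velocity vanish along the wall).
    """
    uc, vc = _center_velocity(state)
    m = mesh
    wss: Dict[str, np.ndarray] = {}
    trac: Dict[str, np.ndarray] = {}
    pw: Dict[str, np.ndarray] = {}
    nzi = m.nz
    for side in ("lower", "upper"):
        if side == "lower":
            slope = m.dylo_c
            u1, u2 = uc[:, 0], uc[:, 1]
            v1, v2 = vc[:, 0], vc[:, 1]
            eta1, eta2 = m.eta_c[0], m.eta_c[1]
            dist = lambda eta: eta * m.h_c           # wall-normal distance factor
            p1, p2 = state.p[:, 0], state.p[:, 1]
            n_sign = 1.0
        else:
            slope = m.dyup_c
            u1, u2 = uc[:, -1], uc[:, -2]
            v1, v2 = vc[:, -1], vc[:, -2]
            eta1, eta2 = 1.0 - m.eta_c[-1], 1.0 - m.eta_c[-2]
            dist = lambda eta: eta * m.h_c
            p1, p2 = state.p[:, -1], state.p[:, -2]
            n_sign = -1.0
        root = np.sqrt(1.0 + slope**2)
        # wall-normal distances of the two sample lines
        d1 = dist(eta1) / root
        d2 = dist(eta2) / root
        ut1 = (u1 + v1 * slope) / root
        ut2 = (u2 + v2 * slope) / root
        dut_dn = _one_sided_wall_gradient(ut1, ut2, d1, d2)
        wss[side] = fluid_mu * dut_dn
        # wall pressure: linear extrapolation from the first two cells
        pw[side] = 1.5 * p1 - 0.5 * p2
        # full velocity gradient at the wall from eta-derivatives:
        # d/dx = -(y_xi/h) d/deta (tangential derivative of wall velocity is 0),
        # d/dy = (1/h) d/deta
        du_deta = _one_sided_wall_gradient(u1, u2, eta1 * np.ones(nzi), eta2 * np.ones(nzi))
        dv_deta = _one_sided_wall_gradient(v1, v2, eta1 * np.ones(nzi), eta2 * np.ones(nzi))
        sgn = 1.0 if side == "lower" else -1.0
        du_deta *= sgn     # one-sided gradients flip with the eta direction
        dv_deta *= sgn
        a = slope / m.h_c  # y_xi/h evaluated on the wall
        ux = -a * du_deta
        uy = du_deta / m.h_c
        vx = -a * dv_deta
        vy = dv_deta / m.h_c
        nx = -slope / root * n_sign
        nyc = 1.0 / root * n_sign
        sxx = 2.0 * fluid_mu * ux
        syy = 2.0 * fluid_mu * vy
        sxy = fluid_mu * (uy + vx)
        tx = -pw[side] * nx + sxx * nx + sxy * nyc
        ty = -pw[side] * nyc + sxy * nx + syy * nyc
        trac[side] = np.hypot(tx, ty)
    return WallProfile(z=m.z_c.copy(), wss=wss, traction=trac, p_wall=pw)


def wall_shear_stress(state: FieldState, mesh: Mesh, fluid_mu: float = 0.0035) -> WallProfile:
    """Signed WSS profile on both walls (traction included for convenience)."""
    return wall_fields(state, mesh, fluid_mu)


def wall_traction(state: FieldState, mesh: Mesh, fluid_mu: float = 0.0035) -> WallProfile:
    """Wall load profile: fluid traction magnitude on both walls."""
    return wall_fields(state, mesh, fluid_mu)


@dataclass
class SeparationEvent:
    side: str
    z_separation: float
    z_reattachment: float
    truncated: bool = False  # reversed flow persists to the domain end


@dataclass
class RecirculationZone:
    side: str
    z_min: float
    z_max: float
    area: float  # m^2


@dataclass
class SeparationReport:
    events: List[SeparationEvent] = field(default_factory=list)
    zones: List[RecirculationZone] = field(default_factory=list)
    stagnation_points: List[Tuple[float, str]] = field(default_factory=list)


def detect_separation(
    wall: WallProfile, min_cells: int = 2, dz: Optional[float] = None
) -> SeparationReport:
    """Separation/reattachment events from streamwise WSS zero crossings.

    Separation = + -> - crossing, reattachment = - -> +, located by
    linear interpolation between stations; events shorter than
    ``min_cells`` axial cells are discarded as discretization noise.
    """
    z = wall.z
    dz = dz if dz is not None else float(z[1] - z[0])
    report = SeparationReport()
    for side in wall.sides:
        tau = wall.wss[side]
        sign = np.sign(tau)
        z_sep = None
        for k in range(len(z) - 1):
            if sign[k] > 0 and sign[k + 1] < 0:
                zc = z[k] + (z[k + 1] - z[k]) * tau[k] / (tau[k] - tau[k + 1])
                z_sep = zc
            elif sign[k] < 0 and sign[k + 1] > 0 and z_sep is not None:
                zc = z[k] + (z[k + 1] - z[k]) * tau[k] / (tau[k] - tau[k + 1])
                if zc - z_sep >= min_cells * dz:
                    report.events.append(SeparationEvent(side, float(z_sep), float(zc)))
                z_sep = None
        if z_sep is not None and z[-1] - z_sep >= min_cells * dz:
            # boundary-truncated event: reversed flow persists to the outlet
            z_end = float(z[-1] + dz / 2.0)
            report.events.append(SeparationEvent(side, float(z_sep), z_end, truncated=True))
    return report


def detect_recirculation(
    state: FieldState,
    mesh: Mesh,
    u_ref: Optional[float] = None,
    stagnation_zmax: Optional[float] = None,
    stagnation_tol: float = 1.0e-3,
) -> SeparationReport:
    """Recirculation zones and near-wall stagnation points.

    Zones are 4-connected components of cells with strictly negative
    axial velocity that touch a wall-adjacent cell row.  Stagnation
    points are wall-adjacent cells with |V| < stagnation_tol * u_ref
    upstream of ``stagnation_zmax`` (defaults to the stenosis start).
    ``u_ref`` defaults to the bulk velocity implied by the inlet flux.
    """
    uc, vc = _center_velocity(state)
    if u_ref is None:
        u_ref = float(state.u[0, :].mean())
    if stagnation_zmax is None:
        zc_val = mesh.stenosis.center(mesh.vessel)
        half = mesh.stenosis.z0 if mesh.stenosis.model == 3 else mesh.stenosis.z0 / 2.0
        stagnation_zmax = zc_val - half
    report = SeparationReport()
    mask = uc < 0.0
    labels, n_lab = ndimage.label(mask)  # default structure = 4-connectivity
    areas = mesh.cell_areas()
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        touches_lower = bool(sel[:, 0].any())
        touches_upper = bool(sel[:, -1].any())
        if not (touches_lower or touches_upper):
            continue
        side = "both" if (touches_lower and touches_upper) else (
            "lower" if touches_lower else "upper"
        )
        zi = np.nonzero(sel.any(axis=1))[0]
        report.zones.append(
            RecirculationZone(
                side=side,
                z_min=float(mesh.z_c[zi[0]] - mesh.dxi / 2),
                z_max=float(mesh.z_c[zi[-1]] + mesh.dxi / 2),
                area=float(areas[sel].sum()),
            )
        )
    vmag = np.hypot(uc, vc)
    upstream = mesh.z_c < stagnation_zmax
    for side, col in (("lower", 0), ("upper", mesh.ny - 1)):
        slow = upstream & (vmag[:, col] < stagnation_tol * abs(u_ref))
        for i in np.nonzero(slow)[0]:
            report.stagnation_points.append((float(mesh.z_c[i]), side))
    return report


def total_recirculation_area(report: SeparationReport) -> float:
    return float(sum(zone.area for zone in report.zones))
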