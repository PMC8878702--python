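"""Closed-form reference flows for validation: plane Poiseuille and
oscillatory (Womersley-type) channel flow.

Both satisfy the incompressible Navier-Stokes equations between parallel
plates exactly; tests inject them into the solver's discrete operators
and into the post-processing chain as analytic oracles.
"""
from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .flow import FieldState, FlowConditions, FluidProperties
from .geometry import Mesh, VesselSpec


@dataclass
class OracleField:
    """A FieldState produced by a closed form, tagged with its parameters."""

    state: FieldState
    tag: str
    params: dict


def womersley_number(vessel: VesselSpec, fluid: FluidProperties, f: float = 1.0) -> float:
    """alpha = (D/2) * sqrt(2*pi*f * rho/mu)."""
    omega = 2.0 * np.pi * f
    return (vessel.D / 2.0) * np.sqrt(omega * fluid.rho / fluid.mu)


def poiseuille_profile(eta: np.ndarray, u_mean: float) -> np.ndarray:
    """Parabolic profile with bulk u_mean on eta in [0, 1]."""
    return 1.5 * u_mean * (1.0 - (2.0 * np.asarray(eta) - 1.0) ** 2)


def poiseuille(
    mesh: Mesh, fluid: FluidProperties, cond: FlowConditions
) -> OracleField:
    """Exact steady plane-Poiseuille field on an unobstructed mesh.

    u(y) = 1.5*U*(1 - (2(y-y_mid)/D)^2), v = 0, p linear with slope
    -12*mu*U/D^2, gauge 0 at the outlet face.
    """
    if mesh.stenosis.s != 0:
        raise ValueError("the Poiseuille oracle requires an unobstructed channel (s = 0)")
    vessel = mesh.vessel
    ub = cond.u_mean(fluid, vessel)
    u = np.empty((mesh.nz + 1, mesh.ny))
    u[:] = poiseuille_profile(mesh.eta_c, ub)[None, :]
    v = np.zeros((mesh.nz, mesh.ny + 1))
    gz = 12.0 * fluid.mu * ub / vessel.D**2
    p = np.repeat((gz * (vessel.L - mesh.z_c))[:, None], mesh.ny, axis=1)
    state = FieldState(u=u, v=v, p=p, t=0.0)
    return OracleField(state=state, tag="poiseuille", params={"u_mean": ub, "dpdz": -gz})


def poiseuille_wss(fluid: FluidProperties, cond: FlowConditions, vessel: VesselSpec) -> float:
    """tau_w = 6*mu*U_mean/D, equal on both walls."""
    return 6.0 * fluid.mu * cond.u_mean(fluid, vessel) / vessel.D


def poiseuille_pressure_drop(
    fluid: FluidProperties, cond: FlowConditions, vessel: VesselSpec
) -> float:
    """dp over the full length: 12*mu*U_mean*L/D^2."""
    ub = cond.u_mean(fluid, vessel)
    return 12.0 * fluid.mu * ub * vessel.L / vessel.D**2


class WomersleyChannel:
    """Oscillatory + steady pressure-driven flow between parallel plates.

    The flux per unit width is matched to the pulsatile inlet waveform
    Q(t) = U_mean*D*(1 + a*sin(2*pi*f*t)): the steady part is plane
    Poiseuille and the oscillatory part is the exact solution
    u1(y, t) = Re{ (i P/(rho*omega)) * (1 - cosh(k y')/cosh(k H)) e^{i omega t} }
    with k = sqrt(i*omega/nu), y' = y - D/2, H = D/2, and the complex
    pressure-gradient amplitude P chosen so the oscillatory flux equals
    a*U_mean*D*sin(omega t).
    """

    def __init__(
        self,
        vessel: VesselSpec,
        fluid: FluidProperties,
        cond: FlowConditions,
    ) -> None:
        if cond.waveform != "sinusoidal":
            raise ValueError("the Womersley oracle requires the sinusoidal waveform")
        self.vessel = vessel
        self.fluid = fluid
        self.cond = cond
        self.omega = 2.0 * np.pi * cond.f
        self.H = vessel.D / 2.0
        nu = fluid.nu
        self.k = np.sqrt(1j * self.omega / nu)
        self.u_mean = cond.u_mean(fluid, vessel)
        kH = self.k * self.H
        # flux of the unit-amplitude shape: 2H*(1 - tanh(kH)/kH)
        shape_flux = 2.0 * self.H * (1.0 - np.tanh(kH) / kH)
        # oscillatory flux amplitude: Q1 = -i * a * U_mean * D  (so that
        # Re{Q1 e^{i w t}} = a*U_mean*D*sin(w t))
        q1 = -1j * cond.amplitude * self.u_mean * vessel.D
        self.c_amp = q1 / shape_flux            # = i*P/(rho*omega)
        self.p_amp = self.c_amp * fluid.rho * self.omega / 1j  # complex P

    def velocity(self, y: np.ndarray, t: float) -> np.ndarray:
        """Axial velocity u(y, t); y measured from the lower wall."""
        yp = np.asarray(y) - self.H
        steady = 1.5 * self.u_mean * (1.0 - (yp / self.H) ** 2)
        shape = 1.0 - np.cosh(self.k * yp) / np.cosh(self.k * self.H)
        osc = np.real(self.c_amp * shape * np.exp(1j * self.omega * t))
        return steady + osc

    def centerline(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        shape = 1.0 - 1.0 / np.cosh(self.k * self.H)
        osc = np.real(self.c_amp * shape * np.exp(1j * self.omega * t))
        return 1.5 * self.u_mean + osc

    def pressure_gradient(self, t: float) -> float:
        """Total dp/dz(t): steady Poiseuille part + oscillatory part."""
        gz = -12.0 * self.fluid.mu * self.u_mean / self.vessel.D**2
        return gz + float(np.real(self.p_amp * np.exp(1j * self.omega * t)))

    def pde_residual(self, y: np.ndarray, t: float) -> np.ndarray:
        """Momentum residual rho*u_t - mu*u_yy + dp/dz of the analytic
        solution, evaluated with closed-form derivatives (round-off)."""
        yp = np.asarray(y) - self.H
        e = np.exp(1j * self.omega * t)
        shape = 1.0 - np.cosh(self.k * yp) / np.cosh(self.k * self.H)
        u_t = np.real(1j * self.omega * self.c_amp * shape * e)
        u_yy_osc = np.real(
            -self.c_amp * self.k**2 * np.cosh(self.k * yp) / np.cosh(self.k * self.H) * e
        )
        u_yy_steady = -3.0 * self.u_mean / self.H**2
        dpdz_osc = float(np.real(self.p_amp * e))
        dpdz_steady = -12.0 * self.fluid.mu * self.u_mean / self.vessel.D**2
        mu, rho = self.fluid.mu, self.fluid.rho
        return rho * u_t - mu * (u_yy_steady + u_yy_osc) + (dpdz_steady + dpdz_osc)


def womersley_channel(
    mesh: Mesh,
    fluid: FluidProperties,
    cond: FlowConditions,
    t: float,
) -> OracleField:
    """Womersley oracle sampled on a mesh at time t (requires s = 0)."""
    if mesh.stenosis.s != 0:
        raise ValueError("the Womersley oracle requires an unobstructed channel (s = 0)")
    w = WomersleyChannel(mesh.vessel, fluid, cond)
    y_u = mesh.eta_c * mesh.vessel.D
    u = np.repeat(w.velocity(y_u, t)[None, :], mesh.nz + 1, axis=0)
    v = np.zeros((mesh.nz, mesh.ny + 1))
    p = np.repeat((-w.pressure_gradient(t) * (mesh.vessel.L - mesh.z_c))[:, None], mesh.ny, axis=1)
    state = FieldState(u=u, v=v, p=p, t=t)
    return OracleField(
        state=state,
        tag="womersley_channel",
        params={"alpha": womersley_number(mesh.vessel, fluid, cond.f), "t": t},
    )


def steady_momentum_residual_interior(
    state: FieldState, mesh: Mesh, fluid: FluidProperties
) -> float:
    """Max |steady x-momentum residual| on interior cells, central stencils.

    Evaluates u*u_x + v*u_y + p_x/rho - nu*lap(u) with mapped-coordinate
    central differences at cell centers at least two cells from every
    boundary, using the supplied field's own values (no ghost modeling).
    For fields that are exact polynomial/linear solutions of the PDE
    (plane Poiseuille) every stencil is exact and the residual is
    round-off.
    """
    m = mesh
    uc = 0.5 * (state.u[:-1, :] + state.u[1:, :])
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    p = state.p
    dxi, deta = m.dxi, m.deta
    nu = fluid.nu

    def dxi_c(f):
        return (f[2:, 1:-1] - f[:-2, 1:-1]) / (2 * dxi)

    def deta_c(f):
        return (f[1:-1, 2:] - f[1:-1, :-2]) / (2 * deta)

    def dxixi(f):
        return (f[2:, 1:-1] - 2 * f[1:-1, 1:-1] + f[:-2, 1:-1]) / dxi**2

    def detaeta(f):
        return (f[1:-1, 2:] - 2 * f[1:-1, 1:-1] + f[1:-1, :-2]) / deta**2

    def dxieta(f):
        return (f[2:, 2:] - f[2:, :-2] - f[:-2, 2:] + f[:-2, :-2]) / (4 * dxi * deta)

    eta = m.eta_c
    yxi = m.dylo_c[:, None] + eta[None, :] * m.dh_c[:, None]
    a = (yxi / m.h_c[:, None])[1:-1, 1:-1]
    h = m.h_c[1:-1, None] * np.ones_like(a)
    d2h = (m.d2yup_c - m.d2ylo_c)
    yxixi = m.d2ylo_c[:, None] + eta[None, :] * d2h[:, None]
    a_xi = (yxixi / m.h_c[:, None] - yxi * m.dh_c[:, None] / m.h_c[:, None] ** 2)[1:-1, 1:-1]
    a_eta = (m.dh_c / m.h_c)[1:-1, None] * np.ones_like(a)

    u_x = dxi_c(uc) - a * deta_c(uc)
    u_y = deta_c(uc) / h
    p_x = dxi_c(p) - a * deta_c(p)
    lap_u = (
        dxixi(uc)
        - 2.0 * a * dxieta(uc)
        + (a**2 + 1.0 / h**2) * detaeta(uc)
        + (a * a_eta - a_xi) * deta_c(uc)
    )
    ui = uc[1:-1, 1:-1]
    vi = vc[1:-1, 1:-1]
    res = ui * u_x + vi * u_y + p_x / fluid.rho - nu * lap_u
    # drop one more ring to stay clear of boundary-adjacent stencils
    return float(np.abs(res[1:-1, 1:-1]).max())
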