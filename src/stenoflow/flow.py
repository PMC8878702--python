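"""Incompressible Newtonian flow in the stenosed lumen.

Solves the 2D Navier-Stokes equations on the boundary-fitted mesh with a
fully developed (parabolic) inlet -- steady or sinusoidally pulsatile --
no-slip walls and a zero-gradient outlet referenced to p = 0.

Discretization: MAC staggering in the mapped (xi, eta) coordinates with
an incremental pressure-correction (projection) step per time level:

* explicit 2nd-order upwind-biased advection in advective form,
* semi-implicit diffusion (the stiff wall-normal eta-eta term implicit,
  axial and metric cross terms explicit),
* a pressure Poisson solve built as the exact product D@G of the
  discrete divergence and gradient operators, so the corrected field is
  discretely divergence-free to direct-solver round-off.

The mapping y = y_lo(xi) + eta*h(xi) has Jacobian h(xi); with
a = y_xi/h the physical derivatives are d/dx = d/dxi - a d/deta and
d/dy = (1/h) d/deta, and continuity takes the conservative form
d(h u)/dxi + d(v - y_xi u)/deta = 0 whose face fluxes the divergence
operator differences exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import Mesh, VesselSpec


class SolverInstabilityError(RuntimeError):
    """Raised when the time integration produces non-finite fields."""


class _TimestepReduced(Exception):
    """Internal: the CFL guard shrank dt mid-run; the caller restarts."""


class LinearSolverError(RuntimeError):
    """Raised when a linear sub-solve fails to produce finite results."""


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as a uniform, incompressible, isothermal Newtonian fluid."""

    rho: float = 1060.0   # kg/m^3
    mu: float = 0.0035    # kg/(m s)

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho


@dataclass(frozen=True)
class FlowConditions:
    """Inlet regime: Reynolds number and waveform.

    Re = rho*U_mean*D/mu with U_mean the bulk inlet velocity and D the
    unobstructed channel height.  The sinusoidal waveform is
    U(t) = U_mean*(1 + a*sin(2*pi*f*t)) with a < 1 so the inlet never
    refluxes; peak at cycle phase 0.25, trough at 0.75.
    """

    Re: float = 500.0
    waveform: str = "steady"      # "steady" | "sinusoidal"
    f: float = 1.0                # Hz
    amplitude: float = 0.5

    def __post_init__(self) -> None:
        if self.Re <= 0:
            raise ValueError("Reynolds number must be positive")
        if self.waveform not in ("steady", "sinusoidal"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if not (0 <= self.amplitude < 1):
            raise ValueError("amplitude must lie in [0, 1) to avoid inlet reflux")
        if self.f <= 0:
            raise ValueError("frequency must be positive")

    def u_mean(self, fluid: FluidProperties, vessel: VesselSpec) -> float:
        """Bulk inlet velocity implied by Re."""
        return self.Re * fluid.mu / (fluid.rho * vessel.D)

    def bulk_velocity(self, t: float, fluid: FluidProperties, vessel: VesselSpec) -> float:
        """Instantaneous bulk inlet velocity U(t)."""
        ub = self.u_mean(fluid, vessel)
        if self.waveform == "steady":
            return ub
        return ub * (1.0 + self.amplitude * np.sin(2.0 * np.pi * self.f * t))


def inlet_profile(
    t: float,
    cond: FlowConditions,
    vessel: VesselSpec,
    fluid: FluidProperties,
    eta: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Fully developed transverse profile u(eta) at time t.

    Parabolic with bulk U(t): u = 1.5*U(t)*(1 - (2*eta - 1)^2), zero at
    the walls; eta defaults to 64 cell centers on [0, 1].
    """
    if eta is None:
        eta = (np.arange(64) + 0.5) / 64.0
    U = cond.bulk_velocity(t, fluid, vessel)
    return 1.5 * U * (1.0 - (2.0 * np.asarray(eta) - 1.0) ** 2)


@dataclass(frozen=True)
class SolverSettings:
    """Time discretization and convergence controls.

    ``dt`` is the pulsatile physical step (reduced automatically if the
    CFL bound is violated); steady pseudo-time marching picks its own
    CFL-limited step.  ``max_inner_iters`` is retained for configuration
    compatibility: the linear IMEX projection step needs no inner
    nonlinear iterations.
    """

    dt: float = 4.0e-4
    n_cycles: int = 3
    max_inner_iters: int = 5
    steady_tol: float = 1.0e-6
    max_steady_time: float = 10.0
    steady_window: float = 2.0
    cfl: float = 0.8
    ramp_time: float = 0.1
    snapshot_phases: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 < self.cfl <= 0.9):
            raise ValueError("cfl must lie in (0, 0.9]")


@dataclass
class FieldState:
    """Discrete velocity/pressure fields at one time instant.

    u: (nz+1, ny) at xi-faces; v: (nz, ny+1) at eta-faces (wall rows are
    exactly zero); p: (nz, ny) gauge pressure at cell centers, referenced
    to 0 at the outlet face.
    """

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.u.copy(), self.v.copy(), self.p.copy(), self.t)


@dataclass
class SteadyReport:
    converged: bool
    unsteady: bool
    residual: float
    t_final: float
    n_steps: int
    dt: float
    max_divergence: float


@dataclass
class PulsatileResult:
    """Final-cycle snapshots plus per-cycle periodicity records."""

    snapshots: List[FieldState]       # final cycle, at snapshot phases
    phases: np.ndarray                # cycle phases in [0, 1)
    cycle_peak_velocity: np.ndarray   # (n_cycles, n_phases, nz) sectional peak |V|
    dt: float
    n_steps: int

    def at_phase(self, phase: float) -> FieldState:
        k = int(np.argmin(np.abs(self.phases - phase)))
        return self.snapshots[k]

    @property
    def systole(self) -> FieldState:
        return self.at_phase(0.25)

    @property
    def diastole(self) -> FieldState:
        return self.at_phase(0.75)

    def periodicity_error(self, cycle_a: int = -2, cycle_b: int = -1) -> float:
        """Relative L2 difference of sectional peak-velocity curves."""
        a = self.cycle_peak_velocity[cycle_a]
        b = self.cycle_peak_velocity[cycle_b]
        return float(np.linalg.norm(a - b) / max(np.linalg.norm(b), 1e-300))


def _d_upwind(fp: np.ndarray, w: np.ndarray, d: float, axis: int) -> np.ndarray:
    """2nd-order upwind derivative; ``fp`` is padded by 2 cells on ``axis``."""

    def sl(k0, k1):
        idx = [slice(None)] * fp.ndim
        idx[axis] = slice(k0, k1 if k1 != 0 else None)
        return fp[tuple(idx)]

    f0 = sl(2, -2)
    fm1, fm2 = sl(1, -3), sl(0, -4)
    fp1, fp2 = sl(3, -1), sl(4, 0)
    pos = (3.0 * f0 - 4.0 * fm1 + fm2) / (2.0 * d)
    neg = (-3.0 * f0 + 4.0 * fp1 - fp2) / (2.0 * d)
    return np.where(w >= 0.0, pos, neg)


def _d_central(fp: np.ndarray, d: float, axis: int) -> np.ndarray:
    """Central first derivative; ``fp`` padded by 1 on ``axis``."""
    idx_p = [slice(None)] * fp.ndim
    idx_m = [slice(None)] * fp.ndim
    idx_p[axis] = slice(2, None)
    idx_m[axis] = slice(0, -2)
    return (fp[tuple(idx_p)] - fp[tuple(idx_m)]) / (2.0 * d)


def _d2_central(fp: np.ndarray, d: float, axis: int) -> np.ndarray:
    """Central second derivative; ``fp`` padded by 1 on ``axis``."""
    idx_p = [slice(None)] * fp.ndim
    idx_0 = [slice(None)] * fp.ndim
    idx_m = [slice(None)] * fp.ndim
    idx_p[axis] = slice(2, None)
    idx_0[axis] = slice(1, -1)
    idx_m[axis] = slice(0, -2)
    return (fp[tuple(idx_p)] - 2.0 * fp[tuple(idx_0)] + fp[tuple(idx_m)]) / d**2


class ProjectionSolver:
    """Incremental pressure-correction solver on one boundary-fitted mesh."""

    def __init__(
        self,
        mesh: Mesh,
        fluid: FluidProperties,
        cond: FlowConditions,
        settings: SolverSettings | None = None,
    ) -> None:
        self.mesh = mesh
        self.fluid = fluid
        self.cond = cond
        self.settings = settings or SolverSettings()
        self._build_metrics()
        self._build_projection_operators()
        self._dt_factorized: float | None = None
        self._rng = np.random.default_rng(self.settings.seed)

    # ------------------------------------------------------------------ setup

    def _build_metrics(self) -> None:
        m = self.mesh
        nz, ny = m.nz, m.ny
        eta_c, eta_v = m.eta_c, m.eta_v
        # y_xi and a = y_xi/h at u-points (xi-faces x eta-centers)
        self.yxi_u = m.dylo_u[:, None] + eta_c[None, :] * m.dh_u[:, None]
        self.a_u = self.yxi_u / m.h_u[:, None]
        # at v-points (xi-centers x eta-faces)
        self.yxi_v = m.dylo_c[:, None] + eta_v[None, :] * m.dh_c[:, None]
        self.a_v = self.yxi_v / m.h_c[:, None]
        # metric derivative terms for the explicit Laplacian remainder
        d2h_u = m.d2yup_u - m.d2ylo_u
        d2h_c = m.d2yup_c - m.d2ylo_c
        yxixi_u = m.d2ylo_u[:, None] + eta_c[None, :] * d2h_u[:, None]
        yxixi_v = m.d2ylo_c[:, None] + eta_v[None, :] * d2h_c[:, None]
        # a_xi = y_xixi/h - y_xi*h'/h^2 ; a_eta = h'/h
        self.axi_u = yxixi_u / m.h_u[:, None] - self.yxi_u * m.dh_u[:, None] / m.h_u[:, None] ** 2
        self.aeta_u = np.broadcast_to((m.dh_u / m.h_u)[:, None], self.a_u.shape)
        self.axi_v = yxixi_v / m.h_c[:, None] - self.yxi_v * m.dh_c[:, None] / m.h_c[:, None] ** 2
        self.aeta_v = np.broadcast_to((m.dh_c / m.h_c)[:, None], self.a_v.shape)
        # implicit eta-eta diffusion coefficients
        self.cu = self.a_u**2 + 1.0 / m.h_u[:, None] ** 2        # (nz+1, ny)
        self.cv = self.a_v**2 + 1.0 / m.h_c[:, None] ** 2        # (nz, ny+1)
        self.nu_flat = (nz + 1) * ny
        self.nv_flat = nz * (ny + 1)
        self.ncell = nz * ny

    def _iu(self, i, j):
        return i * self.mesh.ny + j

    def _iv(self, i, j):
        return self.nu_flat + i * (self.mesh.ny + 1) + j

    def _ip(self, i, j):
        return i * self.mesh.ny + j

    def _build_projection_operators(self) -> None:
        """Assemble sparse divergence D, gradient G and Poisson A = D@G."""
        m = self.mesh
        nz, ny, dxi, deta = m.nz, m.ny, m.dxi, m.deta
        rows, cols, vals = [], [], []

        def add(r, c, v):
            rows.append(np.asarray(r).ravel())
            cols.append(np.asarray(c).ravel())
            vals.append(np.asarray(v).ravel())

        ii, jj = np.meshgrid(np.arange(nz), np.arange(ny), indexing="ij")
        cell = self._ip(ii, jj)
        # axial face fluxes h_u * u
        add(cell, self._iu(ii + 1, jj), np.broadcast_to((m.h_u[1:] / dxi)[:, None], ii.shape))
        add(cell, self._iu(ii, jj), np.broadcast_to((-m.h_u[:-1] / dxi)[:, None], ii.shape))
        # eta face fluxes G = v - y_xi * u_avg at interior eta-faces
        for jf_off, sgn in ((1, +1.0), (0, -1.0)):
            jf = jj + jf_off
            interior = (jf > 0) & (jf < ny)
            ci, cj, cf = ii[interior], jj[interior], jf[interior]
            c_id = self._ip(ci, cj)
            add(c_id, self._iv(ci, cf), np.full(ci.shape, sgn / deta))
            w = sgn * (-m.dylo_c[ci] - m.eta_v[cf] * m.dh_c[ci]) / deta * 0.25
            for di, djf in ((0, -1), (1, -1), (0, 0), (1, 0)):
                add(c_id, self._iu(ci + di, cf + djf), w)
        D = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ncell, self.nu_flat + self.nv_flat),
        ).tocsr()

        rows, cols, vals = [], [], []
        # gradient rows for u faces i = 1..nz-1 (interior)
        ii, jj = np.meshgrid(np.arange(1, nz), np.arange(ny), indexing="ij")
        urow = self._iu(ii, jj)
        add(urow, self._ip(ii, jj), np.full(ii.shape, 1.0 / dxi))
        add(urow, self._ip(ii - 1, jj), np.full(ii.shape, -1.0 / dxi))
        # cross term  -a_u * p_eta (4-point average, one-sided at walls)
        c = -self.a_u[1:nz, :]
        for (imask, jp, jmn, wgt) in (
            ((jj > 0) & (jj < ny - 1), 1, -1, 0.25),   # interior: (p[j+1]-p[j-1])/(4 deta) avg i
            (jj == 0, 1, 0, 0.5),                       # lower wall: one-sided
            (jj == ny - 1, 0, -1, 0.5),                 # upper wall: one-sided
        ):
            ci, cj = ii[imask], jj[imask]
            cc = c[imask] * wgt / deta
            for di in (0, -1):
                add(self._iu(ci, cj), self._ip(ci + di, cj + jp), cc)
                add(self._iu(ci, cj), self._ip(ci + di, cj + jmn), -cc)
        # outlet u faces i = nz: Dirichlet p = 0 at the face (ghost = -p[nz-1])
        jj = np.arange(ny)
        urow = self._iu(nz, jj)
        add(urow, self._ip(nz - 1, jj), np.full(ny, -2.0 / dxi))
        c_out = -self.a_u[nz, :]
        j_int = jj[(jj > 0) & (jj < ny - 1)]
        add(self._iu(nz, j_int), self._ip(nz - 1, j_int + 1), c_out[j_int] * 0.5 / deta)
        add(self._iu(nz, j_int), self._ip(nz - 1, j_int - 1), -c_out[j_int] * 0.5 / deta)
        # v faces j = 1..ny-1
        ii, jj = np.meshgrid(np.arange(nz), np.arange(1, ny), indexing="ij")
        vrow = self._iv(ii, jj)
        hc = np.broadcast_to(m.h_c[:, None], ii.shape)
        add(vrow, self._ip(ii, jj), 1.0 / (hc * deta))
        add(vrow, self._ip(ii, jj - 1), -1.0 / (hc * deta))
        G = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.nu_flat + self.nv_flat, self.ncell),
        ).tocsr()

        self.D = D
        self.G = G
        A = (D @ G).tocsc()
        self._poisson = splu(A)

    def _factorize_diffusion(self, dt: float) -> None:
        """Implicit (I - dt*nu*c*d2/deta2) operators for u and v interiors."""
        m = self.mesh
        nz, ny, deta = m.nz, m.ny, m.deta
        nu = self.fluid.nu
        # u interior: i = 1..nz-1, all j; ghost u(-1) = -u(0) at walls
        k = dt * nu * self.cu[1:nz, :] / deta**2
        n = (nz - 1) * ny
        main = 1.0 + 2.0 * k
        main[:, 0] = 1.0 + 3.0 * k[:, 0]
        main[:, -1] = 1.0 + 3.0 * k[:, -1]
        off = -k
        lower = off.copy().ravel()[1:]
        upper = off.copy().ravel()[:-1]
        # mask couplings across xi-blocks
        mask = np.arange(1, n) % ny == 0
        lower[mask] = 0.0
        upper[mask] = 0.0
        Mu = sp.diags([lower, main.ravel(), upper], [-1, 0, 1], format="csc")
        self._Mu = splu(Mu)
        # v interior: i = 0..nz-1, j = 1..ny-1; Dirichlet v = 0 at walls
        k = dt * nu * self.cv[:, 1:ny] / deta**2
        n = nz * (ny - 1)
        main = (1.0 + 2.0 * k).ravel()
        off = (-k).ravel()
        lower = off[1:].copy()
        upper = off[:-1].copy()
        mask = np.arange(1, n) % (ny - 1) == 0
        lower[mask] = 0.0
        upper[mask] = 0.0
        Mv = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
        self._Mv = splu(Mv)
        self._dt_factorized = dt

    # ------------------------------------------------------------ state setup

    def initial_state(self, kind: str = "rest") -> FieldState:
        """Initial fields: 'rest' (zero) or 'stream' (flux-conserving guess).

        The 'stream' guess scales the inlet parabola by D/h(z) at every
        station (constant flux) with a quasi-1D lubrication pressure; it
        is the default starting point for steady pseudo-time marching.
        """
        m = self.mesh
        u = np.zeros((m.nz + 1, m.ny))
        v = np.zeros((m.nz, m.ny + 1))
        p = np.zeros((m.nz, m.ny))
        if kind == "stream":
            ub = self.cond.u_mean(self.fluid, self.mesh.vessel)
            prof = 1.5 * (1.0 - (2.0 * m.eta_c - 1.0) ** 2)
            u[:] = ub * (m.vessel.D / m.h_u)[:, None] * prof[None, :]
            # quasi-1D pressure: dp/dz = -12 mu Ubar D / h(z)^3, gauge 0 at outlet
            gz = 12.0 * self.fluid.mu * ub * m.vessel.D / m.h_c**3
            cum = np.cumsum(gz[::-1])[::-1] * m.dxi
            p[:] = (cum - 0.5 * gz * m.dxi)[:, None]
        elif kind != "rest":
            raise ValueError(f"unknown initial state kind {kind!r}")
        return FieldState(u=u, v=v, p=p, t=0.0)

    def _inlet(self, t: float, ramp: bool) -> np.ndarray:
        prof = inlet_profile(t, self.cond, self.mesh.vessel, self.fluid, self.mesh.eta_c)
        if ramp and self.settings.ramp_time > 0 and t < self.settings.ramp_time:
            x = t / self.settings.ramp_time
            prof = prof * (x * x * (3.0 - 2.0 * x))
        return prof

    # ---------------------------------------------------------------- advance

    def _explicit_rhs(self, u: np.ndarray, v: np.ndarray, gp_u: np.ndarray, gp_v: np.ndarray):
        """Advection + explicit diffusion + pressure gradient for both momenta."""
        m = self.mesh
        nz, ny, dxi, deta = m.nz, m.ny, m.dxi, m.deta
        nu = self.fluid.nu

        # ---- u-momentum on interior faces i = 1..nz-1
        ui = u[1:nz, :]
        v4 = 0.25 * (v[0 : nz - 1, :-1] + v[0 : nz - 1, 1:] + v[1:nz, :-1] + v[1:nz, 1:])
        W = (v4 - ui * self.yxi_u[1:nz, :]) / m.h_u[1:nz, None]
        # xi padding: linear extrapolation at both ends
        up_xi = np.empty((nz + 5, ny))
        up_xi[2:-2] = u
        up_xi[1] = 2.0 * u[0] - u[1]
        up_xi[0] = 3.0 * u[0] - 2.0 * u[1]
        up_xi[-2] = 2.0 * u[-1] - u[-2]
        up_xi[-1] = 3.0 * u[-1] - 2.0 * u[-2]
        du_dxi = _d_upwind(up_xi[1 : nz + 4], ui, dxi, 0)
        # eta padding: no-slip reflection u(-eta) = -u(eta)
        up_eta = np.empty((nz + 1, ny + 4))
        up_eta[:, 2:-2] = u
        up_eta[:, 1] = -u[:, 0]
        up_eta[:, 0] = -u[:, 1]
        up_eta[:, -2] = -u[:, -1]
        up_eta[:, -1] = -u[:, -2]
        du_deta = _d_upwind(up_eta[1:nz, :], W, deta, 1)
        adv_u = ui * du_dxi + W * du_deta

        u_xi1 = up_xi[1:-1]   # padded by 1 in xi
        u_eta1 = up_eta[:, 1:-1]
        u_xixi = _d2_central(u_xi1, dxi, 0)[1:nz, :]
        u_eta_c = _d_central(u_eta1, deta, 1)[1:nz, :]
        # mixed xi-eta: central on both, needs both pads
        up_b = np.empty((nz + 3, ny + 2))
        up_b[1:-1, 1:-1] = u
        up_b[0, 1:-1] = up_xi[1]
        up_b[-1, 1:-1] = up_xi[-2]
        up_b[:, 0] = -up_b[:, 1]
        up_b[:, -1] = -up_b[:, -2]
        u_xieta = (
            up_b[2:, 2:] - up_b[2:, :-2] - up_b[:-2, 2:] + up_b[:-2, :-2]
        )[1:nz, :] / (4.0 * dxi * deta)
        a = self.a_u[1:nz, :]
        g = a * self.aeta_u[1:nz, :] - self.axi_u[1:nz, :]
        diff_expl_u = nu * (u_xixi - 2.0 * a * u_xieta + g * u_eta_c)
        rhs_u = -adv_u + diff_expl_u - gp_u[1:nz, :] / self.fluid.rho

        # ---- v-momentum on interior faces j = 1..ny-1, all i
        vi = v[:, 1:ny]
        u4 = 0.25 * (u[:-1, 0 : ny - 1] + u[:-1, 1:ny] + u[1:, 0 : ny - 1] + u[1:, 1:ny])
        Wv = (vi - u4 * self.yxi_v[:, 1:ny]) / m.h_c[:, None]
        vp_xi = np.empty((nz + 4, ny + 1))
        vp_xi[2:-2] = v
        vp_xi[1] = -v[0]        # v = 0 at the inlet plane (fully developed)
        vp_xi[0] = -v[1]
        vp_xi[-2] = 2.0 * v[-1] - v[-2]
        vp_xi[-1] = 3.0 * v[-1] - 2.0 * v[-2]
        dv_dxi = _d_upwind(vp_xi[:, 1:ny], u4, dxi, 0)
        vp_eta = np.empty((nz, ny + 5))
        vp_eta[:, 2:-2] = v
        vp_eta[:, 1] = -v[:, 1]     # antisymmetric about the wall (v_wall = 0)
        vp_eta[:, 0] = -v[:, 2]
        vp_eta[:, -2] = -v[:, -2]
        vp_eta[:, -1] = -v[:, -3]
        dv_deta = _d_upwind(vp_eta[:, 1 : ny + 4], Wv, deta, 1)
        adv_v = u4 * dv_dxi + Wv * dv_deta

        v_xixi = _d2_central(vp_xi[1:-1], dxi, 0)[:, 1:ny]
        v_eta1 = vp_eta[:, 1:-1]
        v_eta_c = _d_central(v_eta1, deta, 1)[:, 1:ny]
        vp_b = np.empty((nz + 2, ny + 3))
        vp_b[1:-1, 1:-1] = v
        vp_b[0, 1:-1] = vp_xi[1]
        vp_b[-1, 1:-1] = vp_xi[-2]
        vp_b[:, 0] = np.concatenate(([0.0], -v[:, 1], [0.0]))  # pad rows incl corners
        vp_b[:, -1] = np.concatenate(([0.0], -v[:, -2], [0.0]))
        v_xieta = (
            vp_b[2:, 2:] - vp_b[2:, :-2] - vp_b[:-2, 2:] + vp_b[:-2, :-2]
        )[:, 1:ny] / (4.0 * dxi * deta)
        av = self.a_v[:, 1:ny]
        gv = av * self.aeta_v[:, 1:ny] - self.axi_v[:, 1:ny]
        diff_expl_v = nu * (v_xixi - 2.0 * av * v_xieta + gv * v_eta_c)
        rhs_v = -adv_v + diff_expl_v - gp_v[:, 1:ny] / self.fluid.rho
        return rhs_u, rhs_v

    def advance(self, state: FieldState, dt: float | None = None, ramp: bool = False) -> FieldState:
        """One incremental pressure-correction step; restores the divergence
        invariant to direct-solver round-off."""
        m = self.mesh
        nz, ny = m.nz, m.ny
        dt = float(dt if dt is not None else self.settings.dt)
        dt = self._enforce_cfl(state, dt)
        if self._dt_factorized != dt:
            self._factorize_diffusion(dt)
        u, v, p = state.u, state.v, state.p
        t_new = state.t + dt

        gp = self.G @ p.ravel()
        gp_u = gp[: self.nu_flat].reshape(nz + 1, ny)
        gp_v = gp[self.nu_flat :].reshape(nz, ny + 1)
        rhs_u, rhs_v = self._explicit_rhs(u, v, gp_u, gp_v)

        u_star = np.empty_like(u)
        u_star[1:nz, :] = self._Mu.solve((u[1:nz, :] + dt * rhs_u).ravel()).reshape(nz - 1, ny)
        u_star[0, :] = self._inlet(t_new, ramp)
        # outlet: zero-gradient copy rescaled to the instantaneous inlet flux
        u_star[nz, :] = u_star[nz - 1, :]
        q_in = m.h_u[0] * u_star[0, :].mean()
        q_out = m.h_u[nz] * u_star[nz, :].mean()
        if abs(q_out) > 1e-300:
            u_star[nz, :] *= q_in / q_out

        v_star = np.zeros_like(v)
        v_star[:, 1:ny] = self._Mv.solve((v[:, 1:ny] + dt * rhs_v).ravel()).reshape(nz, ny - 1)

        vel = np.concatenate([u_star.ravel(), v_star.ravel()])
        div = self.D @ vel
        phi = self._poisson.solve(self.fluid.rho / dt * div)
        if not np.all(np.isfinite(phi)):
            raise LinearSolverError("pressure Poisson solve returned non-finite values")
        corr = (dt / self.fluid.rho) * (self.G @ phi)
        vel -= corr
        u_new = vel[: self.nu_flat].reshape(nz + 1, ny)
        v_new = vel[self.nu_flat :].reshape(nz, ny + 1)
        p_new = p + phi.reshape(nz, ny)
        if not (np.all(np.isfinite(u_new)) and np.all(np.isfinite(v_new))):
            raise SolverInstabilityError(f"non-finite velocity at t = {t_new:.6g} s")
        return FieldState(u=u_new, v=v_new, p=p_new, t=t_new)

    def _enforce_cfl(self, state: FieldState, dt: float) -> float:
        """Cap dt by the advective CFL in mapped coordinates.

        Axial speed is u; the transverse advection speed (per unit eta)
        is W = (v - y_xi*u)/h, which includes the metric sweep along the
        stenosis slopes.  A lower bound on the expected jet speed keeps
        the a-priori estimate honest before the jet has formed.
        """
        m = self.mesh
        ub = self.cond.u_mean(self.fluid, m.vessel)
        amp = self.cond.amplitude if self.cond.waveform == "sinusoidal" else 0.0
        u_jet = 1.5 * ub * (1.0 + amp) * m.vessel.D / m.h_u.min()
        umax = max(float(np.abs(state.u).max()), u_jet, 1e-12)
        v4 = 0.25 * (
            state.v[:-1, :-1] + state.v[:-1, 1:] + state.v[1:, :-1] + state.v[1:, 1:]
        )
        W = (v4 - state.u[1:-1, :] * self.yxi_u[1:-1, :]) / m.h_u[1:-1, None]
        wmax = max(
            float(np.abs(W).max()),
            u_jet * float(np.abs(self.yxi_u / m.h_u[:, None]).max()),
            1e-12,
        )
        lim = self.settings.cfl * min(m.dxi / umax, m.deta / wmax)
        while dt > lim:
            dt *= 0.5
        return dt

    def divergence(self, state: FieldState) -> float:
        """Max |discrete divergence| scaled by the bulk inlet velocity."""
        vel = np.concatenate([state.u.ravel(), state.v.ravel()])
        ub = self.cond.u_mean(self.fluid, self.mesh.vessel)
        return float(np.abs(self.D @ vel).max() / ub)

    # ------------------------------------------------------------- high level

    def solve_steady(self) -> Tuple[FieldState, SteadyReport]:
        """Pseudo-time march to steady state (or a flagged time average).

        Convergence: relative L2 change of velocity per unit time below
        ``steady_tol``.  If the flow has not settled by
        ``max_steady_time`` (expected physical behavior at high Re and
        severe stenosis) the fields averaged over the last
        ``steady_window`` seconds are returned with ``unsteady=True``.
        """
        s = self.settings
        state = self.initial_state("stream")
        dt = self._enforce_cfl(state, 1e9)
        t_avg_start = s.max_steady_time - s.steady_window
        acc = None
        n_acc = 0
        res = np.inf
        n = 0
        while state.t < s.max_steady_time:
            new = self.advance(state, dt)
            dt_taken = new.t - state.t   # adopt any CFL-driven reduction
            dvel = np.linalg.norm(new.u - state.u) ** 2 + np.linalg.norm(new.v - state.v) ** 2
            nvel = np.linalg.norm(state.u) ** 2 + np.linalg.norm(state.v) ** 2
            res = np.sqrt(dvel / max(nvel, 1e-300)) / dt_taken
            dt = dt_taken
            state = new
            n += 1
            if res < s.steady_tol:
                rep = SteadyReport(True, False, float(res), state.t, n, dt, self.divergence(state))
                return state, rep
            if state.t >= t_avg_start:
                if acc is None:
                    acc = FieldState(state.u.copy(), state.v.copy(), state.p.copy(), state.t)
                else:
                    acc.u += state.u
                    acc.v += state.v
                    acc.p += state.p
                n_acc += 1
        acc.u /= n_acc
        acc.v /= n_acc
        acc.p /= n_acc
        acc.t = state.t
        rep = SteadyReport(False, True, float(res), state.t, n, dt, self.divergence(state))
        return acc, rep

    def solve_pulsatile(self) -> PulsatileResult:
        """Integrate ``n_cycles`` cardiac cycles from rest with a ramped
        inlet; returns final-cycle snapshots at the configured phases
        (0.25 = systole, 0.75 = diastole included for phases % 4 == 0)."""
        if self.cond.waveform != "sinusoidal":
            raise ValueError("solve_pulsatile requires the sinusoidal waveform")
        s = self.settings
        m = self.mesh
        period = 1.0 / self.cond.f
        # a-priori CFL bound with margin; then integer steps per cycle
        dt = 0.75 * self._enforce_cfl(self.initial_state("rest"), s.dt)
        nph = max(s.snapshot_phases, 4)
        for _attempt in range(6):
            steps = int(np.ceil(period / dt - 1e-9))
            steps = ((steps + nph - 1) // nph) * nph  # snapshots land exactly on phases
            dt = period / steps
            try:
                return self._run_cycles(dt, steps)
            except _TimestepReduced:
                dt *= 0.5
        raise SolverInstabilityError("could not find a stable pulsatile time step")

    def _run_cycles(self, dt: float, steps: int) -> "PulsatileResult":
        s = self.settings
        m = self.mesh
        state = self.initial_state("rest")
        nph = s.snapshot_phases
        phases = np.arange(nph) / nph
        snap_steps = np.round(phases * steps).astype(int) % steps
        peak = np.zeros((s.n_cycles, nph, m.nz))
        snapshots: List[Optional[FieldState]] = [None] * nph
        n_total = 0
        for cyc in range(s.n_cycles):
            for k in range(steps):
                t_prev = state.t
                state = self.advance(state, dt, ramp=True)
                if abs((state.t - t_prev) - dt) > 1e-12:
                    raise _TimestepReduced  # CFL kicked in: retry whole run
                n_total += 1
                hits = np.nonzero(snap_steps == (k + 1) % steps)[0]
                for ph in hits:
                    uc = 0.5 * (state.u[:-1, :] + state.u[1:, :])
                    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
                    peak[cyc, ph, :] = np.sqrt(uc**2 + vc**2).max(axis=1)
                    if cyc == s.n_cycles - 1:
                        snapshots[ph] = state.copy()
        return PulsatileResult(
            snapshots=list(snapshots),
            phases=phases,
            cycle_peak_velocity=peak,
            dt=dt,
            n_steps=n_total,
        )


def solve_steady(scenario, nz: int | None = None, ny: int | None = None):
    """Steady flow for a complete scenario (duck-typed: needs .stenosis,
    .vessel, .fluid, .conditions, .settings, .nz, .ny attributes)."""
    from .geometry import build_mesh

    mesh = build_mesh(scenario.stenosis, scenario.vessel, nz or scenario.nz, ny or scenario.ny)
    cond = replace(scenario.conditions, waveform="steady")
    solver = ProjectionSolver(mesh, scenario.fluid, cond, scenario.settings)
    state, report = solver.solve_steady()
    return mesh, state, report


def solve_pulsatile(scenario, nz: int | None = None, ny: int | None = None):
    """Pulsatile flow for a complete scenario; returns (mesh, PulsatileResult)."""
    from .geometry import build_mesh

    mesh = build_mesh(scenario.stenosis, scenario.vessel, nz or scenario.nz, ny or scenario.ny)
    cond = replace(scenario.conditions, waveform="sinusoidal")
    solver = ProjectionSolver(mesh, scenario.fluid, cond, scenario.settings)
    return mesh, solver.solve_pulsatile()
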