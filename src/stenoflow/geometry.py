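"""Lumen geometry of an idealized stenosed vessel segment.

The vessel is a planar 2D channel of height ``D`` (the "diameter") and
length ``L``.  A stenosis is carved into one or both walls as a cosine
indentation of total axial width ``z0``; three shape models are supported:

* model 1 — symmetric: both walls indented by half the total depth,
* model 2 — one-sided: the full depth on the upper wall,
* model 3 — double/asymmetric: two serial cosine stenoses on opposite
  walls (upper first, lower second), each with the full depth.

For a stenosis ratio ``s`` (percent lumen reduction at the throat) the
normalized depth is ``delta = s/100`` and the minimal lumen height is
``D*(1 - s/100)`` for every model, so models are compared at equal throat.

The module also names the axial probe stations used throughout the
analysis (P1, Ps1..Ps3, P2, and Ps4/Ps5 for model 3) and builds the
boundary-fitted structured mesh the flow solver operates on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np


class FullOcclusionError(ValueError):
    """Raised when the requested stenosis ratio closes the lumen (s >= 100)."""


class ResolutionError(ValueError):
    """Raised when the mesh cannot resolve the throat."""


@dataclass(frozen=True)
class VesselSpec:
    """Straight-segment dimensions, SI units (m)."""

    D: float = 0.015
    L: float = 0.110
    h_wall: float = 0.002

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"vessel height D must be positive, got {self.D}")
        if self.L <= self.D:
            raise ValueError(f"segment length L={self.L} must exceed D={self.D}")
        if self.h_wall <= 0:
            raise ValueError("wall thickness must be positive")


def depth_from_ratio(s: float) -> float:
    """Normalized stenosis depth ``delta`` from the percent ratio ``s``.

    ``delta = s/100``; the throat lumen height is ``D*(1 - s/100)``.
    """
    if s < 0:
        raise ValueError(f"stenosis ratio must be non-negative, got {s}")
    if s >= 100:
        raise FullOcclusionError(f"stenosis ratio {s}% occludes the lumen")
    return s / 100.0


@dataclass(frozen=True)
class StenosisSpec:
    """Shape model, severity and axial placement of the stenosis.

    ``zc`` is the throat coordinate for models 1-2 and the junction of the
    two serial stenoses for model 3 (first on [zc-z0, zc], second on
    [zc, zc+z0]).  ``zc=None`` defaults to the segment midpoint.
    """

    model: int = 1
    s: float = 50.0
    z0: float = 0.015
    zc: float | None = None

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3):
            raise ValueError(f"stenosis model must be 1, 2 or 3, got {self.model}")
        depth_from_ratio(self.s)  # validates range
        if self.z0 <= 0:
            raise ValueError("stenosis length z0 must be positive")

    @property
    def delta(self) -> float:
        return depth_from_ratio(self.s)

    def center(self, vessel: VesselSpec) -> float:
        zc = vessel.L / 2.0 if self.zc is None else self.zc
        if not (0 < self.z0 < vessel.L):
            raise ValueError(f"z0={self.z0} must lie in (0, L={vessel.L})")
        half = self.z0 if self.model == 3 else self.z0 / 2.0
        if not (half <= zc <= vessel.L - half):
            raise ValueError(
                f"stenosis center zc={zc} places the stenosis outside [0, L]"
            )
        return zc


def _bump(zeta: np.ndarray, z0: float) -> np.ndarray:
    """Cosine indentation shape: 1 at the throat, 0 at |zeta| = z0/2, C1."""
    zeta = np.asarray(zeta, dtype=float)
    inside = np.abs(zeta) <= z0 / 2.0
    out = np.zeros_like(zeta)
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * zeta[inside] / z0))
    return out


def _dbump(zeta: np.ndarray, z0: float) -> np.ndarray:
    zeta = np.asarray(zeta, dtype=float)
    inside = np.abs(zeta) <= z0 / 2.0
    out = np.zeros_like(zeta)
    out[inside] = -(np.pi / z0) * np.sin(2.0 * np.pi * zeta[inside] / z0)
    return out


def _d2bump(zeta: np.ndarray, z0: float) -> np.ndarray:
    zeta = np.asarray(zeta, dtype=float)
    inside = np.abs(zeta) <= z0 / 2.0
    out = np.zeros_like(zeta)
    out[inside] = -(2.0 * np.pi**2 / z0**2) * np.cos(2.0 * np.pi * zeta[inside] / z0)
    return out


def _wall_terms(
    spec: StenosisSpec, vessel: VesselSpec
) -> Tuple[Tuple[float, float, float], ...]:
    """Indentations as (amplitude on lower wall, amplitude on upper wall, center)."""
    zc = spec.center(vessel)
    dD = spec.delta * vessel.D
    if spec.model == 1:
        return ((dD / 2.0, dD / 2.0, zc),)
    if spec.model == 2:
        return ((0.0, dD, zc),)
    # model 3: upper-wall stenosis centered zc - z0/2, lower-wall centered zc + z0/2
    return ((0.0, dD, zc - spec.z0 / 2.0), (dD, 0.0, zc + spec.z0 / 2.0))


def lumen_profile(
    z: np.ndarray | float, spec: StenosisSpec, vessel: VesselSpec
) -> Tuple[np.ndarray, np.ndarray]:
    """Lower and upper wall ordinates ``(y_lo, y_up)`` at axial position(s) z."""
    z = np.asarray(z, dtype=float)
    if np.any(z < -1e-12) or np.any(z > vessel.L + 1e-12):
        raise ValueError("axial coordinate outside [0, L]")
    y_lo = np.zeros_like(z)
    y_up = np.full_like(z, vessel.D)
    for amp_lo, amp_up, c in _wall_terms(spec, vessel):
        b = _bump(z - c, spec.z0)
        y_lo = y_lo + amp_lo * b
        y_up = y_up - amp_up * b
    return y_lo, y_up


def lumen_slopes(
    z: np.ndarray | float, spec: StenosisSpec, vessel: VesselSpec
) -> Tuple[np.ndarray, np.ndarray]:
    """First derivatives ``(dy_lo/dz, dy_up/dz)``."""
    z = np.asarray(z, dtype=float)
    d_lo = np.zeros_like(z)
    d_up = np.zeros_like(z)
    for amp_lo, amp_up, c in _wall_terms(spec, vessel):
        db = _dbump(z - c, spec.z0)
        d_lo = d_lo + amp_lo * db
        d_up = d_up - amp_up * db
    return d_lo, d_up


def lumen_curvatures(
    z: np.ndarray | float, spec: StenosisSpec, vessel: VesselSpec
) -> Tuple[np.ndarray, np.ndarray]:
    """Second derivatives ``(d2y_lo/dz2, d2y_up/dz2)``."""
    z = np.asarray(z, dtype=float)
    d_lo = np.zeros_like(z)
    d_up = np.zeros_like(z)
    for amp_lo, amp_up, c in _wall_terms(spec, vessel):
        d2b = _d2bump(z - c, spec.z0)
        d_lo = d_lo + amp_lo * d2b
        d_up = d_up - amp_up * d2b
    return d_lo, d_up


@dataclass(frozen=True)
class ProbeSet:
    """Named axial probe stations, strictly increasing in z.

    Models 1-2: P1 (pre-stenosis midpoint), Ps1 (stenosis start), Ps2
    (throat), Ps3 (stenosis end), P2 (post-stenosis midpoint).  Model 3
    replaces P2 with Ps4 (second throat) and Ps5 (second stenosis end).
    """

    names: Tuple[str, ...]
    coords: Dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        zs = [self.coords[n] for n in self.names]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError(f"probe coordinates not strictly increasing: {self.coords}")

    def __getitem__(self, name: str) -> float:
        return self.coords[name]

    def items(self):
        return ((n, self.coords[n]) for n in self.names)


def probe_locations(spec: StenosisSpec, vessel: VesselSpec) -> ProbeSet:
    """Locate the named probe stations for the given geometry."""
    zc = spec.center(vessel)
    z0 = spec.z0
    if spec.model in (1, 2):
        ps1, ps2, ps3 = zc - z0 / 2.0, zc, zc + z0 / 2.0
        coords = {
            "P1": ps1 / 2.0,
            "Ps1": ps1,
            "Ps2": ps2,
            "Ps3": ps3,
            "P2": (ps3 + vessel.L) / 2.0,
        }
        names = ("P1", "Ps1", "Ps2", "Ps3", "P2")
    else:
        coords = {
            "P1": (zc - z0) / 2.0,
            "Ps1": zc - z0,
            "Ps2": zc - z0 / 2.0,
            "Ps3": zc,
            "Ps4": zc + z0 / 2.0,
            "Ps5": zc + z0,
        }
        names = ("P1", "Ps1", "Ps2", "Ps3", "Ps4", "Ps5")
    return ProbeSet(names=names, coords=coords)


@dataclass(frozen=True)
class Mesh:
    """Boundary-fitted structured grid over the lumen.

    The computational domain is the unit square (xi, eta) in
    [0, L] x [0, 1]; the physical map is y = y_lo(xi) + eta * h(xi) with
    h = y_up - y_lo, so eta-lines stretch linearly between the walls and
    wall nodes lie exactly on the analytic profile.  Staggered layout for
    the solver: u at xi-faces (nz+1, ny), v at eta-faces (nz, ny+1),
    scalars at cell centers (nz, ny); 0-based, half-open cells.
    """

    vessel: VesselSpec
    stenosis: StenosisSpec
    nz: int
    ny: int
    dxi: float
    deta: float
    z_u: np.ndarray        # (nz+1,) axial face coordinates
    z_c: np.ndarray        # (nz,)   axial cell centers
    eta_c: np.ndarray      # (ny,)   transverse cell centers
    eta_v: np.ndarray      # (ny+1,) transverse face coordinates
    y_lo_c: np.ndarray
    y_up_c: np.ndarray
    h_c: np.ndarray        # lumen height at cell centers
    h_u: np.ndarray        # lumen height at xi-faces
    dylo_u: np.ndarray
    dyup_u: np.ndarray
    dylo_c: np.ndarray
    dyup_c: np.ndarray
    d2ylo_u: np.ndarray
    d2yup_u: np.ndarray
    d2ylo_c: np.ndarray
    d2yup_c: np.ndarray

    @property
    def dh_u(self) -> np.ndarray:
        return self.dyup_u - self.dylo_u

    @property
    def dh_c(self) -> np.ndarray:
        return self.dyup_c - self.dylo_c

    @property
    def throat_height(self) -> float:
        return float(self.h_u.min())

    def y_at(self, z: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """Physical y of computational points (broadcasting z x eta)."""
        y_lo, y_up = lumen_profile(z, self.stenosis, self.vessel)
        return y_lo[:, None] + np.asarray(eta)[None, :] * (y_up - y_lo)[:, None]

    def node_coordinates(self) -> Tuple[np.ndarray, np.ndarray]:
        """(Z, Y) arrays of shape (nz+1, ny+1) for export / plotting."""
        Z = np.repeat(self.z_u[:, None], self.ny + 1, axis=1)
        Y = self.y_at(self.z_u, self.eta_v)
        return Z, Y

    def cell_areas(self) -> np.ndarray:
        """Physical cell areas (nz, ny); positive everywhere."""
        return self.dxi * self.deta * np.repeat(self.h_c[:, None], self.ny, axis=1)


def build_mesh(
    spec: StenosisSpec, vessel: VesselSpec, nz: int = 256, ny: int = 64
) -> Mesh:
    """Build the boundary-fitted mesh; validates resolution and positivity."""
    if nz < 64:
        raise ResolutionError(f"nz={nz} below the minimum of 64 axial stations")
    if ny < 16:
        raise ResolutionError(f"ny={ny} below the minimum of 16 transverse stations")
    # boundary-fitted: every one of the ny transverse cells spans the throat
    if ny * 1 < 8:  # pragma: no cover - implied by ny >= 16
        raise ResolutionError("fewer than 8 transverse cells across the throat")
    dxi = vessel.L / nz
    deta = 1.0 / ny
    z_u = np.linspace(0.0, vessel.L, nz + 1)
    z_c = z_u[:-1] + dxi / 2.0
    eta_v = np.linspace(0.0, 1.0, ny + 1)
    eta_c = eta_v[:-1] + deta / 2.0

    y_lo_c, y_up_c = lumen_profile(z_c, spec, vessel)
    y_lo_u, y_up_u = lumen_profile(z_u, spec, vessel)
    h_c = y_up_c - y_lo_c
    h_u = y_up_u - y_lo_u
    if h_c.min() <= 0 or h_u.min() <= 0:
        raise FullOcclusionError("lumen height non-positive somewhere")
    dylo_u, dyup_u = lumen_slopes(z_u, spec, vessel)
    dylo_c, dyup_c = lumen_slopes(z_c, spec, vessel)
    d2ylo_u, d2yup_u = lumen_curvatures(z_u, spec, vessel)
    d2ylo_c, d2yup_c = lumen_curvatures(z_c, spec, vessel)
    return Mesh(
        vessel=vessel,
        stenosis=spec,
        nz=nz,
        ny=ny,
        dxi=dxi,
        deta=deta,
        z_u=z_u,
        z_c=z_c,
        eta_c=eta_c,
        eta_v=eta_v,
        y_lo_c=y_lo_c,
        y_up_c=y_up_c,
        h_c=h_c,
        h_u=h_u,
        dylo_u=dylo_u,
        dyup_u=dyup_u,
        dylo_c=dylo_c,
        dyup_c=dyup_c,
        d2ylo_u=d2ylo_u,
        d2yup_u=d2yup_u,
        d2ylo_c=d2ylo_c,
        d2yup_c=d2yup_c,
    )
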