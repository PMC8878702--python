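"""One-way thin-walled vessel response to the computed wall pressure.

The lumen is treated as rigid for the flow solve; afterwards the wall
pressure profile is fed through thin-wall (Laplace-law) estimates of
circumferential (hoop) stress and radial displacement.  The per-scenario
report of max(dr)/D makes the validity of the rigid-lumen approximation
visible: where it exceeds a few percent, wall compliance would start to
feed back on the flow.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VesselSpec


@dataclass(frozen=True)
class WallProperties:
    """Elastic constants of the vessel wall."""

    E: float = 0.7e6       # Young's modulus, Pa
    nu: float = 0.49       # Poisson ratio
    rho_w: float = 2000.0  # wall density, kg/m^3 (reporting only)
    h_wall: float = 0.002  # thickness, m

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.h_wall <= 0:
            raise ValueError("wall thickness must be positive")


def hoop_stress(
    p_wall: np.ndarray, r_local: np.ndarray, vessel: VesselSpec
) -> np.ndarray:
    """Laplace-law hoop stress sigma_theta = p * R_local / h_wall (Pa).

    ``r_local`` is the local lumen half-height; at the throat the smaller
    radius lowers the hoop stress at equal pressure.
    """
    return np.asarray(p_wall) * np.asarray(r_local) / vessel.h_wall


def radial_displacement(
    p_wall: np.ndarray,
    r_local: np.ndarray,
    vessel: VesselSpec,
    wall: WallProperties,
) -> np.ndarray:
    """Thin-shell radial displacement dr = p R^2 (1 - nu^2) / (E h) (m)."""
    p = np.asarray(p_wall)
    r = np.asarray(r_local)
    return p * r**2 * (1.0 - wall.nu**2) / (wall.E * wall.h_wall)


def compliance_report(
    p_wall: np.ndarray,
    r_local: np.ndarray,
    vessel: VesselSpec,
    wall: WallProperties,
    threshold: float = 0.05,
) -> dict:
    """Summary of the rigid-lumen approximation quality.

    Returns max |dr|/D and whether it exceeds ``threshold`` (default 5%),
    the level at which one-way coupling becomes questionable.
    """
    dr = radial_displacement(p_wall, r_local, vessel, wall)
    ratio = float(np.abs(dr).max() / vessel.D)
    return {
        "max_displacement_m": float(np.abs(dr).max()),
        "max_displacement_over_D": ratio,
        "exceeds_threshold": ratio > threshold,
        "threshold": threshold,
    }
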