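"""Scenario enumeration: the full factorial study grid and randomized
geometries/conditions for property-based tests.

All study inputs are analytic (geometry parameters, fluid constants,
Reynolds numbers, waveform), so this module fully specifies a run; no
external data is involved.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Tuple

import numpy as np

from .flow import FlowConditions, FluidProperties, SolverSettings
from .geometry import StenosisSpec, VesselSpec
from .wall_mechanics import WallProperties

#: stenosis-ratio grid of the results section; the methods-section
#: variant {20, 50, 70} is available by passing ratios=(20, 50, 70)
DEFAULT_RATIOS: Tuple[float, ...] = (30.0, 50.0, 70.0)
DEFAULT_REYNOLDS: Tuple[float, ...] = (500.0, 800.0, 1200.0)
DEFAULT_MODELS: Tuple[int, ...] = (1, 2, 3)
DEFAULT_WAVEFORMS: Tuple[str, ...] = ("steady", "sinusoidal")


@dataclass(frozen=True)
class StenosisScenario:
    """Complete specification of one simulation case."""

    vessel: VesselSpec = field(default_factory=VesselSpec)
    stenosis: StenosisSpec = field(default_factory=StenosisSpec)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    conditions: FlowConditions = field(default_factory=FlowConditions)
    wall: WallProperties = field(default_factory=WallProperties)
    settings: SolverSettings = field(default_factory=SolverSettings)
    nz: int = 256
    ny: int = 64
    label: str = ""

    def with_label(self) -> "StenosisScenario":
        if self.label:
            return self
        wf = "steady" if self.conditions.waveform == "steady" else "pulsatile"
        lab = f"m{self.stenosis.model}_s{self.stenosis.s:g}_re{self.conditions.Re:g}_{wf}"
        return replace(self, label=lab)


def paper_grid(
    ratios: Iterable[float] = DEFAULT_RATIOS,
    reynolds: Iterable[float] = DEFAULT_REYNOLDS,
    models: Iterable[int] = DEFAULT_MODELS,
    waveforms: Iterable[str] = DEFAULT_WAVEFORMS,
    nz: int = 256,
    ny: int = 64,
    settings: SolverSettings | None = None,
) -> List[StenosisScenario]:
    """The full factorial study grid, order-stable (model, s, Re, waveform)."""
    settings = settings or SolverSettings()
    out: List[StenosisScenario] = []
    for model in sorted(models):
        for s in sorted(ratios):
            for re_ in sorted(reynolds):
                for wf in waveforms:
                    out.append(
                        StenosisScenario(
                            stenosis=StenosisSpec(model=model, s=float(s)),
                            conditions=FlowConditions(Re=float(re_), waveform=wf),
                            settings=settings,
                            nz=nz,
                            ny=ny,
                        ).with_label()
                    )
    return out


def scenario(label: str, **overrides) -> StenosisScenario:
    """Look up a grid scenario by its label, e.g. 'm1_s70_re1200_steady'."""
    for sc in paper_grid(**overrides):
        if sc.label == label:
            return sc
    raise KeyError(f"no scenario labelled {label!r} in the grid")


def random_scenario(seed: int) -> StenosisScenario:
    """Randomized-but-valid scenario for property tests; deterministic in seed.

    s ~ U[10, 80] %, Re ~ U[100, 1200], model ~ U{1, 2, 3}, stenosis
    center jittered +/-10% of L around the midpoint.
    """
    rng = np.random.default_rng(seed)
    vessel = VesselSpec()
    model = int(rng.integers(1, 4))
    s = float(rng.uniform(10.0, 80.0))
    re_ = float(rng.uniform(100.0, 1200.0))
    zc = vessel.L / 2.0 + float(rng.uniform(-0.1, 0.1)) * vessel.L
    sten = StenosisSpec(model=model, s=s, zc=zc)
    sten.center(vessel)  # validates placement
    return StenosisScenario(
        vessel=vessel,
        stenosis=sten,
        conditions=FlowConditions(Re=re_),
        settings=SolverSettings(seed=seed),
        label=f"rand_seed{seed}_m{model}",
    )
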