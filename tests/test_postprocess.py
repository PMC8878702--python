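"""Post-processing against analytic oracle fields and solver runs."""
import numpy as np
import pytest

from stenoflow.flow import FieldState, FlowConditions, FluidProperties
from stenoflow.geometry import StenosisSpec, VesselSpec, build_mesh, probe_locations
from stenoflow.oracles import poiseuille, poiseuille_wss
from stenoflow.postprocess import (
    WallProfile,
    detect_recirculation,
    detect_separation,
    pressure_drop,
    sectional_series,
    total_recirculation_area,
    wall_fields,
)

VESSEL = VesselSpec()
FLUID = FluidProperties()
COND = FlowConditions(Re=500)


@pytest.fixture(scope="module")
def oracle_setup():
    mesh = build_mesh(StenosisSpec(model=1, s=0.0), VESSEL, 128, 32)
    orc = poiseuille(mesh, FLUID, COND)
    return mesh, orc


class TestOracleEquivalence:
    """Injected analytic Poiseuille fields reproduce closed forms to 1e-10."""

    def test_sectional_means_and_flux(self, oracle_setup):
        mesh, orc = oracle_setup
        series = sectional_series(orc.state, mesh)
        ub = COND.u_mean(FLUID, VESSEL)
        # midpoint sampling of the parabola has the exact discrete mean
        # ub * (1 + deta^2/2); the flux is exactly constant
        discrete_mean = ub * (1 + mesh.deta**2 / 2)
        np.testing.assert_allclose(series.mean_u, discrete_mean, rtol=1e-12)
        np.testing.assert_allclose(series.flux, series.flux[0], rtol=1e-12)
        np.testing.assert_allclose(series.max_vmag, 1.5 * ub, rtol=2e-3)

    def test_pressure_drop_linear_profile(self, oracle_setup):
        mesh, orc = oracle_setup
        series = sectional_series(orc.state, mesh)
        dp, per_probe = pressure_drop(series, probe_locations(mesh.stenosis, VESSEL))
        gz = -orc.params["dpdz"]
        assert dp == pytest.approx(gz * (mesh.z_c[-1] - mesh.z_c[0]), rel=1e-10)
        assert per_probe["Ps2"] == pytest.approx(
            gz * (probe_locations(mesh.stenosis, VESSEL)["Ps2"] - mesh.z_c[0]), rel=1e-10
        )

    def test_wss_exact_on_both_walls(self, oracle_setup):
        mesh, orc = oracle_setup
        wall = wall_fields(orc.state, mesh, FLUID.mu)
        tau = poiseuille_wss(FLUID, COND, VESSEL)
        np.testing.assert_allclose(wall.wss["lower"], tau, rtol=1e-10)
        np.testing.assert_allclose(wall.wss["upper"], tau, rtol=1e-10)
        assert tau == pytest.approx(0.154, rel=0.01)

    def test_traction_closed_form(self, oracle_setup):
        mesh, orc = oracle_setup
        wall = wall_fields(orc.state, mesh, FLUID.mu)
        tau = poiseuille_wss(FLUID, COND, VESSEL)
        for side in ("lower", "upper"):
            expect = np.hypot(wall.p_wall[side], tau)
            np.testing.assert_allclose(wall.traction[side], expect, rtol=1e-10)

    def test_hydrostatic_rest_state_traction_is_pressure(self):
        mesh = build_mesh(StenosisSpec(model=1, s=30), VESSEL, 64, 16)
        p0 = 1234.5
        state = FieldState(
            u=np.zeros((mesh.nz + 1, mesh.ny)),
            v=np.zeros((mesh.nz, mesh.ny + 1)),
            p=np.full((mesh.nz, mesh.ny), p0),
        )
        wall = wall_fields(state, mesh, FLUID.mu)
        for side in ("lower", "upper"):
            np.testing.assert_allclose(wall.traction[side], abs(p0), rtol=1e-12)
            np.testing.assert_allclose(wall.wss[side], 0.0, atol=1e-15)

    def test_zero_flow_pressure_drop_and_wss(self):
        mesh = build_mesh(StenosisSpec(model=1, s=0), VESSEL, 64, 16)
        state = FieldState(
            u=np.zeros((mesh.nz + 1, mesh.ny)),
            v=np.zeros((mesh.nz, mesh.ny + 1)),
            p=np.zeros((mesh.nz, mesh.ny)),
        )
        dp, _ = pressure_drop(sectional_series(state, mesh))
        assert dp == 0.0
        wall = wall_fields(state, mesh, FLUID.mu)
        assert np.all(wall.wss["lower"] == 0.0)


class TestSeparationDetection:
    def test_poiseuille_has_no_events(self, oracle_setup):
        mesh, orc = oracle_setup
        wall = wall_fields(orc.state, mesh, FLUID.mu)
        assert detect_separation(wall).events == []

    def test_synthetic_sine_wss_crossings(self):
        z = np.linspace(0, VESSEL.L, 513)[:-1] + VESSEL.L / 1024
        tau = np.sin(2 * np.pi * z / VESSEL.L)
        wall = WallProfile(
            z=z,
            wss={"lower": tau, "upper": np.abs(tau) + 0.1},
            traction={"lower": tau, "upper": tau},
            p_wall={"lower": tau, "upper": tau},
        )
        rep = detect_separation(wall)
        lower = [e for e in rep.events if e.side == "lower"]
        assert len(lower) == 1
        assert lower[0].z_separation == pytest.approx(VESSEL.L / 2, rel=1e-3)
        assert lower[0].truncated
        assert lower[0].z_reattachment == pytest.approx(VESSEL.L, rel=1e-2)
        assert [e for e in rep.events if e.side == "upper"] == []

    def test_short_events_discarded(self):
        z = np.linspace(0.001, 0.109, 109)
        tau = np.ones_like(z)
        tau[50] = -0.5  # single-cell blip
        wall = WallProfile(
            z=z, wss={"lower": tau, "upper": tau},
            traction={"lower": tau, "upper": tau}, p_wall={"lower": tau, "upper": tau},
        )
        assert detect_separation(wall).events == []


class TestRecirculationDetection:
    def test_poiseuille_no_zones(self, oracle_setup):
        mesh, orc = oracle_setup
        rep = detect_recirculation(orc.state, mesh)
        assert rep.zones == []

    def test_synthetic_wall_blob_area_and_side(self):
        mesh = build_mesh(StenosisSpec(model=1, s=0), VESSEL, 64, 16)
        u = np.full((mesh.nz + 1, mesh.ny), 0.1)
        u[30:41, :3] = -0.05  # reversed patch on the lower wall
        state = FieldState(u=u, v=np.zeros((mesh.nz, mesh.ny + 1)), p=np.zeros((mesh.nz, mesh.ny)))
        rep = detect_recirculation(state, mesh, u_ref=0.1)
        assert len(rep.zones) == 1
        zone = rep.zones[0]
        assert zone.side == "lower"
        # 10 cell columns x 3 rows of uniform cells
        expect_area = 10 * 3 * mesh.dxi * (VESSEL.D / mesh.ny)
        assert zone.area == pytest.approx(expect_area, rel=1e-12)

    def test_interior_blob_ignored(self):
        mesh = build_mesh(StenosisSpec(model=1, s=0), VESSEL, 64, 16)
        u = np.full((mesh.nz + 1, mesh.ny), 0.1)
        u[30:35, 7:9] = -0.05  # reversed patch away from both walls
        state = FieldState(u=u, v=np.zeros((mesh.nz, mesh.ny + 1)), p=np.zeros((mesh.nz, mesh.ny)))
        assert detect_recirculation(state, mesh, u_ref=0.1).zones == []


class TestSolverRunConsistency:
    """Cross-checks between WSS, separation and recirculation on a
    separated stenotic flow (model 2, s=50, Re=1200)."""

    def test_wss_sign_matches_near_wall_velocity(self, steady_run):
        run = steady_run(2, 50, 1200)
        uc = 0.5 * (run.state.u[:-1, :] + run.state.u[1:, :])
        vc = 0.5 * (run.state.v[:, :-1] + run.state.v[:, 1:])
        for side, col, slope in (
            ("lower", 0, run.mesh.dylo_c),
            ("upper", -1, run.mesh.dyup_c),
        ):
            ut = uc[:, col] + vc[:, col] * slope
            tau = run.wall.wss[side]
            # compare away from the zero crossings of either field
            big = (np.abs(tau) > 0.01 * np.abs(tau).max()) & (
                np.abs(ut) > 0.01 * np.abs(ut).max()
            )
            assert np.all(np.sign(tau[big]) == np.sign(ut[big]))

    def test_zones_overlap_separation_intervals(self, steady_run):
        run = steady_run(2, 50, 1200)
        assert run.recirculation.zones, "expected post-stenotic recirculation"
        events = run.separation.events
        for zone in run.recirculation.zones:
            sides = ("lower", "upper") if zone.side == "both" else (zone.side,)
            overlapping = [
                e
                for e in events
                if e.side in sides
                and e.z_separation <= zone.z_max
                and e.z_reattachment >= zone.z_min
            ]
            assert overlapping, f"zone {zone} has no matching separation event"

    def test_throat_pressure_far_below_prestenotic(self, steady_run):
        run = steady_run(2, 50, 1200)
        pv = run.series.probe_values(run.probes, "mean_p")
        assert pv["Ps2"] < pv["Ps1"] < pv["P1"]
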