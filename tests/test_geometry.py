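"""Geometry: stenosis profiles, probe stations, boundary-fitted mesh."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stenoflow.geometry import (
    FullOcclusionError,
    ResolutionError,
    StenosisSpec,
    VesselSpec,
    build_mesh,
    depth_from_ratio,
    lumen_profile,
    probe_locations,
)

VESSEL = VesselSpec()
MM = 1e-3


class TestDepthFromRatio:
    @pytest.mark.parametrize("s,delta", [(0.0, 0.0), (70.0, 0.70), (50.0, 0.50)])
    def test_depth_and_throat_height(self, s, delta):
        assert depth_from_ratio(s) == pytest.approx(delta, abs=0)
        mesh = build_mesh(StenosisSpec(model=1, s=s), VESSEL, 64, 16)
        assert mesh.throat_height == pytest.approx(VESSEL.D * (1 - s / 100), rel=1e-14)

    def test_domain_errors(self):
        with pytest.raises(FullOcclusionError):
            depth_from_ratio(100.0)
        with pytest.raises(ValueError):
            depth_from_ratio(-1.0)


class TestLumenProfile:
    @pytest.mark.parametrize("model", [1, 2, 3])
    def test_profile_joins_straight_wall_at_window_edges(self, model):
        spec = StenosisSpec(model=model, s=50)
        zc = spec.center(VESSEL)
        edges = [zc - spec.z0 / 2, zc + spec.z0 / 2]
        if model == 3:
            edges = [zc - spec.z0, zc + spec.z0]
        for z in edges:
            y_lo, y_up = lumen_profile(z, spec, VESSEL)
            assert y_up - y_lo == pytest.approx(VESSEL.D, rel=1e-14)

    def test_model1_quarter_window_height(self):
        spec = StenosisSpec(model=1, s=50)
        zc = spec.center(VESSEL)
        y_lo, y_up = lumen_profile(zc + spec.z0 / 4, spec, VESSEL)
        assert y_up - y_lo == pytest.approx(0.75 * VESSEL.D, rel=1e-14)

    def test_model2_all_narrowing_on_upper_wall(self):
        spec = StenosisSpec(model=2, s=70)
        zc = spec.center(VESSEL)
        y_lo, y_up = lumen_profile(zc, spec, VESSEL)
        assert y_lo == pytest.approx(0.0, abs=1e-16)
        assert y_up == pytest.approx(0.30 * VESSEL.D, rel=1e-14)
        z = np.linspace(0, VESSEL.L, 4001)
        y_lo, y_up = lumen_profile(z, spec, VESSEL)
        assert (y_up - y_lo).min() == pytest.approx(0.30 * VESSEL.D, rel=1e-6)

    def test_out_of_domain_raises(self):
        with pytest.raises(ValueError):
            lumen_profile(VESSEL.L * 1.01, StenosisSpec(), VESSEL)

    @given(s=st.floats(5, 90), model=st.sampled_from([1, 2, 3]))
    @settings(max_examples=30, deadline=None)
    def test_equal_throat_across_models_and_c1_continuity(self, s, model):
        spec = StenosisSpec(model=model, s=s)
        z = np.linspace(0, VESSEL.L, 8001)
        y_lo, y_up = lumen_profile(z, spec, VESSEL)
        h = y_up - y_lo
        # finite sampling misses the exact throat by O(dz^2) in height
        assert h.min() == pytest.approx(VESSEL.D * (1 - s / 100), rel=1e-5, abs=1e-7)
        # C1: the numerical slope of each wall has no jump anywhere; a
        # genuine kink would give a step ~O(0.1-1) regardless of dz,
        # while the cosine blend's curvature is bounded by ~1.2e3 1/m
        dz = z[1] - z[0]
        for y in (y_lo, y_up):
            slope = np.diff(y) / dz
            assert np.abs(np.diff(slope)).max() < 3000.0 * dz

    @given(s=st.floats(0, 90))
    @settings(max_examples=20, deadline=None)
    def test_model1_midline_symmetry(self, s):
        spec = StenosisSpec(model=1, s=s)
        z = np.linspace(0, VESSEL.L, 501)
        y_lo, y_up = lumen_profile(z, spec, VESSEL)
        np.testing.assert_allclose(y_lo + y_up, VESSEL.D, rtol=1e-13)


class TestProbeLocations:
    def test_model1_default_centering(self):
        probes = probe_locations(StenosisSpec(model=1, s=50), VESSEL)
        expect = {"P1": 23.75, "Ps1": 47.5, "Ps2": 55.0, "Ps3": 62.5, "P2": 86.25}
        for name, val in expect.items():
            assert probes[name] == pytest.approx(val * MM, rel=1e-12)

    def test_model3_second_stenosis_probes(self):
        probes = probe_locations(StenosisSpec(model=3, s=50), VESSEL)
        assert probes["Ps4"] == pytest.approx(62.5 * MM, rel=1e-12)
        assert probes["Ps5"] == pytest.approx(70.0 * MM, rel=1e-12)
        assert "P2" not in probes.coords

    @given(
        model=st.sampled_from([1, 2, 3]),
        s=st.floats(0, 90),
        zc_frac=st.floats(0.35, 0.65),
    )
    @settings(max_examples=40, deadline=None)
    def test_probe_ordering_strictly_increasing(self, model, s, zc_frac):
        spec = StenosisSpec(model=model, s=s, zc=zc_frac * VESSEL.L)
        probes = probe_locations(spec, VESSEL)
        zs = [z for _, z in probes.items()]
        assert all(b > a for a, b in zip(zs, zs[1:]))
        assert all(0 <= z <= VESSEL.L for z in zs)

    def test_degenerate_unobstructed_probes_well_ordered(self):
        probes = probe_locations(StenosisSpec(model=1, s=0.0), VESSEL)
        zs = [z for _, z in probes.items()]
        assert all(b > a for a, b in zip(zs, zs[1:]))


class TestBuildMesh:
    def test_unobstructed_mesh_is_uniform(self):
        mesh = build_mesh(StenosisSpec(model=1, s=0), VESSEL, 64, 16)
        areas = mesh.cell_areas()
        np.testing.assert_allclose(areas, areas[0, 0], rtol=1e-13)

    def test_throat_transverse_resolution(self):
        # boundary-fitted: all ny cells span the throat (64 * 0.30 -> >= 19)
        mesh = build_mesh(StenosisSpec(model=1, s=70), VESSEL, 64, 64)
        assert mesh.ny >= 19
        assert mesh.throat_height / mesh.ny > 0

    @pytest.mark.parametrize("nz,ny", [(32, 32), (64, 8)])
    def test_resolution_errors(self, nz, ny):
        with pytest.raises(ResolutionError):
            build_mesh(StenosisSpec(model=1, s=50), VESSEL, nz, ny)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_cell_positivity_random_geometry(self, seed):
        from stenoflow.scenarios import random_scenario

        sc = random_scenario(seed)
        mesh = build_mesh(sc.stenosis, sc.vessel, 64, 16)
        assert mesh.cell_areas().min() > 0
        assert mesh.h_c.min() > 0 and mesh.h_u.min() > 0
        # wall nodes lie exactly on the analytic profile
        y_lo, y_up = lumen_profile(mesh.z_u, sc.stenosis, sc.vessel)
        Z, Y = mesh.node_coordinates()
        np.testing.assert_allclose(Y[:, 0], y_lo, atol=1e-15)
        np.testing.assert_allclose(Y[:, -1], y_up, atol=1e-15)
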