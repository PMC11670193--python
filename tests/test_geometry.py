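import numpy as np
import pytest

from veinflow.geometry import (
    VesselGeometry,
    absolute_length,
    actual_length,
    area_ratio,
    cross_section,
    divide_segments,
    mesh_is_watertight,
    mesh_volume,
    planar_cap_area,
    station_weights,
    tortuosity_index,
)
from veinflow.synthetic import (
    VesselParams,
    generate_vessel,
    semicircle_geometry,
    with_tortuosity,
)


class TestTortuosityIndex:
    def test_straight_vessel(self):
        assert tortuosity_index(50.0, 50.0) == 1.0

    def test_semicircle_closed_form(self):
        # arc length pi*r over chord 2*r
        assert tortuosity_index(np.pi * 20.0, 40.0) == pytest.approx(np.pi / 2)

    def test_semicircle_preset(self):
        g = semicircle_geometry(arc_radius=20.0)
        ti = tortuosity_index(actual_length(g), absolute_length(g))
        assert ti == pytest.approx(np.pi / 2, rel=1e-4)

    def test_nonpositive_absolute_rejected(self):
        with pytest.raises(ValueError):
            tortuosity_index(50.0, 0.0)
        with pytest.raises(ValueError):
            tortuosity_index(50.0, -1.0)

    def test_actual_below_absolute_rejected(self):
        with pytest.raises(ValueError):
            tortuosity_index(30.0, 50.0)

    def test_amplitude_rescaling_hits_target(self):
        base = VesselParams(inlet_radius=2.0, target_actual_length=60.0, seed=11)
        g = generate_vessel(with_tortuosity(base, 2.0))
        ti = tortuosity_index(actual_length(g), absolute_length(g))
        assert 1.98 <= ti <= 2.02


class TestAreaRatio:
    def test_equal_areas(self):
        assert area_ratio(20.0, 20.0) == 1.0

    def test_quarter(self):
        assert area_ratio(10.0, 40.0) == 0.25

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            area_ratio(0.0, 10.0)
        with pytest.raises(ValueError):
            area_ratio(10.0, -1.0)

    def test_mesh_slice_cross_check(self, tapered_geometry):
        """Sliced cross-sections near the ends match (r_out/r_in)^2 within 2%."""
        g = tapered_geometry
        tangent = np.gradient(g.centerline, axis=0)
        i0, i1 = 6, g.n_stations - 7
        _, r0 = cross_section(g.vertices, g.faces, g.centerline[i0], tangent[i0], g.radius[i0])
        _, r1 = cross_section(g.vertices, g.faces, g.centerline[i1], tangent[i1], g.radius[i1])
        analytic = (g.radius[i1] / g.radius[i0]) ** 2
        assert (r1 / r0) ** 2 == pytest.approx(analytic, rel=0.02)


class TestLengths:
    def test_straight_tube(self):
        g = generate_vessel(VesselParams(inlet_radius=2.0, target_actual_length=40.0))
        assert absolute_length(g) == pytest.approx(40.0, rel=1e-9)
        assert actual_length(g) == pytest.approx(40.0, rel=1e-9)

    def test_semicircle(self):
        g = semicircle_geometry(arc_radius=20.0)
        assert absolute_length(g) == pytest.approx(40.0, rel=1e-9)
        assert actual_length(g) == pytest.approx(62.832, rel=1e-3)

    def test_degenerate_endpoints_rejected(self):
        phi = np.linspace(0.0, 2 * np.pi, 101)
        pts = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)]) * 10
        s = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        g = VesselGeometry(
            vertices=np.zeros((3, 3)),
            faces=np.empty((0, 3), dtype=int),
            centerline=pts,
            radius=np.ones(101),
            arclength=s,
        )
        with pytest.raises(ValueError, match="degenerate"):
            absolute_length(g)

    @pytest.mark.parametrize("seed", range(100))
    def test_actual_never_below_absolute(self, seed):
        rng = np.random.default_rng(seed)
        params = with_tortuosity(
            VesselParams(
                inlet_radius=2.0,
                target_actual_length=float(rng.uniform(36, 80)),
                tortuosity_wavelengths=int(rng.integers(1, 4)),
                n_stations=61,
                n_circumference=8,
                seed=seed,
            ),
            float(rng.uniform(1.0, 3.0)),
        )
        g = generate_vessel(params)
        act, absl = actual_length(g), absolute_length(g)
        assert act >= absl * (1 - 1e-9)
        assert tortuosity_index(act, absl) >= 1.0

    def test_refinement_stability(self, straight_params, tapered_params):
        import dataclasses

        for base in (straight_params, tapered_params):
            tort = with_tortuosity(dataclasses.replace(base, seed=5), 1.8)
            coarse = generate_vessel(tort)
            fine = generate_vessel(dataclasses.replace(tort, n_stations=2 * tort.n_stations - 1))
            assert actual_length(fine) == pytest.approx(actual_length(coarse), rel=5e-3)


class TestDivideSegments:
    def test_boundaries_equally_spaced(self):
        g = generate_vessel(VesselParams(inlet_radius=2.0, target_actual_length=150.0))
        scheme = divide_segments(g, K=15)
        np.testing.assert_allclose(scheme.boundaries, np.arange(16) * 10.0, rtol=1e-9)
        seglens = np.diff(scheme.boundaries)
        np.testing.assert_allclose(seglens, seglens[0], rtol=1e-9)

    def test_group_c_is_11_to_15(self, straight_geometry):
        scheme = divide_segments(straight_geometry, K=15)
        assert scheme.groups == {
            "A": tuple(range(1, 6)),
            "B": tuple(range(6, 11)),
            "C": tuple(range(11, 16)),
        }

    def test_partition(self, straight_geometry, tapered_geometry):
        for g in (straight_geometry, tapered_geometry):
            scheme = divide_segments(g, K=15)
            total = sum(scheme.stations_in_segment(k).size for k in range(1, 16))
            assert total == g.n_stations
            assert scheme.segment_of_station.min() == 1
            assert scheme.segment_of_station.max() == 15

    def test_boundary_station_goes_downstream(self):
        # 301 stations over 60 mm: stations land exactly on the K=15 boundaries
        g = generate_vessel(VesselParams(inlet_radius=2.0, target_actual_length=60.0))
        scheme = divide_segments(g, K=15)
        # station at s=4 mm (index 20) sits on the segment-1/2 boundary
        assert g.arclength[20] == pytest.approx(4.0, abs=1e-9)
        assert scheme.segment_of_station[20] == 2

    def test_too_few_stations_rejected(self):
        g = generate_vessel(VesselParams(inlet_radius=2.0, n_stations=31))
        with pytest.raises(ValueError):
            divide_segments(g, K=40)

    def test_k_below_one_rejected(self, straight_geometry):
        with pytest.raises(ValueError):
            divide_segments(straight_geometry, K=0)


class TestStationWeights:
    def test_weights_sum_to_total_length(self, tapered_geometry):
        w = station_weights(tapered_geometry.arclength)
        assert w.sum() == pytest.approx(tapered_geometry.total_length, rel=1e-12)


class TestMeshChecks:
    def test_presets_watertight(self, straight_geometry, tapered_geometry):
        for g in (straight_geometry, tapered_geometry, semicircle_geometry()):
            assert mesh_is_watertight(g.faces)

    def test_open_mesh_detected(self, straight_geometry):
        assert not mesh_is_watertight(straight_geometry.faces[:-1])

    def test_volume_close_to_analytic(self, straight_geometry):
        vol = mesh_volume(straight_geometry.vertices, straight_geometry.faces)
        assert vol == pytest.approx(np.pi * 2.5**2 * 60.0, rel=0.02)

    def test_slice_radius_matches_analytic(self, tapered_geometry):
        g = tapered_geometry
        tangent = np.gradient(g.centerline, axis=0)
        for i in (30, 150, 270):
            _, reff = cross_section(
                g.vertices, g.faces, g.centerline[i], tangent[i], g.radius[i]
            )
            assert reff == pytest.approx(g.radius[i], rel=0.02)

    def test_cap_areas(self, tapered_geometry):
        g = tapered_geometry
        tangent = np.gradient(g.centerline, axis=0)
        a_in = planar_cap_area(g.vertices, g.faces, g.centerline[0], tangent[0], tol=1e-6)
        a_out = planar_cap_area(g.vertices, g.faces, g.centerline[-1], tangent[-1], tol=1e-6)
        assert a_in == pytest.approx(g.inlet_area, rel=0.02)
        assert a_out == pytest.approx(g.exit_area, rel=0.02)

    def test_centerline_endpoints_on_caps(self, tapered_geometry):
        g = tapered_geometry
        # cap centroid vertices are the appended centerline endpoints
        assert np.allclose(g.vertices[-2], g.centerline[0])
        assert np.allclose(g.vertices[-1], g.centerline[-1])


class TestVesselGeometryValidation:
    def test_nonincreasing_arclength_rejected(self):
        with pytest.raises(ValueError):
            VesselGeometry(
                vertices=np.zeros((3, 3)),
                faces=np.empty((0, 3), dtype=int),
                centerline=np.zeros((3, 3)),
                radius=np.ones(3),
                arclength=np.array([0.0, 2.0, 1.0]),
            )

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            VesselGeometry(
                vertices=np.zeros((3, 3)),
                faces=np.empty((0, 3), dtype=int),
                centerline=np.column_stack([np.zeros(3), np.zeros(3), np.arange(3.0)]),
                radius=np.array([1.0, 0.0, 1.0]),
                arclength=np.arange(3.0),
            )
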