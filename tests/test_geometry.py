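"""Parametric AAA geometry: calibration closure, shape properties, export."""

import numpy as np
import pytest

from aaafsi import geometry as geo
from aaafsi.errors import ConfigurationError, DomainError, GeometryError


class TestBoundaryCurves:
    def test_zero_amplitude_reduces_to_baseline(self, table1):
        spec = table1["lateral-middle"]
        flat = geo.CurveSpec(spec.name, spec.c0, 0.0, spec.c2, spec.c3, spec.p1, spec.p2)
        x = np.linspace(0, 190, 41)
        assert np.allclose(geo.eval_boundary_curve(flat, x), spec.c0)

    def test_outside_domain_rejected(self, table1):
        with pytest.raises(DomainError):
            geo.eval_boundary_curve(table1["posterior"], -1.0)
        with pytest.raises(DomainError):
            geo.eval_boundary_curve(table1["posterior"], 190.5)

    def test_curve_is_smooth(self, table1):
        """Central second differences stay bounded (continuously differentiable)."""
        x = np.linspace(0, 190, 2001)
        y = geo.eval_boundary_curve(table1["anterior-middle"], x)
        d2 = np.diff(y, 2) / (x[1] - x[0]) ** 2
        assert np.abs(d2).max() < 1.0  # mm^-1, gentle curvature everywhere

    def test_far_from_bulge_tends_to_baseline(self, table1):
        spec = table1["lateral-middle"]
        assert geo.eval_boundary_curve(spec, 0.0) == pytest.approx(spec.c0, abs=0.05)


class TestCalibrationClosure:
    """The calibrated parse reproduces the published overall dimensions."""

    def test_printed_dimensions(self, default_geometry):
        rep = geo.measure_diameters(default_geometry)
        assert rep.max_lateral == pytest.approx(64.8, rel=0.005)
        assert rep.max_anterior_posterior == pytest.approx(54.6, rel=0.005)
        assert rep.proximal_neck == pytest.approx(21.6, rel=0.005)
        assert rep.distal_neck == pytest.approx(21.6, rel=0.005)
        assert default_geometry.length == pytest.approx(190.0, rel=1e-12)

    def test_neck_halfwidth_at_end_stations(self, table1):
        """Direct closed-form evaluation of the calibrated edges at x = 0, 190."""
        parse = geo.calibrate_parse()
        for x in (0.0, 190.0):
            lat = geo._blended_edge(table1["lateral-near-end"],
                                    table1["lateral-middle"], x, parse)
            assert float(lat) == pytest.approx(21.6 / 2, abs=0.01)

    def test_lateral_halfwidth_at_apex(self, table1):
        parse = geo.calibrate_parse()
        lat = geo._blended_edge(table1["lateral-near-end"],
                                table1["lateral-middle"], 95.0, parse)
        assert float(lat) == pytest.approx(32.4, abs=0.05)


class TestBuildAndMeasure:
    def test_straight_tube(self, straight_tube_curves):
        g = geo.build_geometry(straight_tube_curves, n_stations=50)
        rep = geo.measure_diameters(g)
        for v in (rep.max_lateral, rep.max_anterior_posterior,
                  rep.proximal_neck, rep.distal_neck):
            assert v == pytest.approx(20.0, rel=1e-9)

    def test_missing_curve_rejected(self, table1):
        curves = dict(table1)
        curves.pop("posterior")
        with pytest.raises(ConfigurationError):
            geo.build_geometry(curves)

    def test_resolution_bounds_enforced(self):
        with pytest.raises(ConfigurationError):
            geo.build_geometry(n_stations=10)

    @pytest.mark.parametrize("k", [1.3, 2.0])
    def test_amplitude_scaling_monotonicity(self, table1, k):
        base = geo.measure_diameters(geo.build_geometry(table1))
        scaled = {n: geo.CurveSpec(n, s.c0, s.c1 * k, s.c2, s.c3, s.p1, s.p2)
                  for n, s in table1.items()}
        rep = geo.measure_diameters(geo.build_geometry(scaled))
        assert rep.max_lateral > base.max_lateral
        assert rep.max_anterior_posterior > base.max_anterior_posterior
        g = geo.build_geometry(scaled)
        assert g.length == pytest.approx(190.0)

    def test_argmax_location_matches_dense_search(self, table1):
        """Station-grid argmax within one spacing of a dense brute-force argmax."""
        g = geo.build_geometry(table1, n_stations=101)
        rep = geo.measure_diameters(g)
        parse = geo.calibrate_parse()
        xd = np.linspace(0, 190, 20001)
        lat = geo._blended_edge(table1["lateral-near-end"], table1["lateral-middle"],
                                xd, parse)
        x_true = xd[np.argmax(lat)]
        assert abs(rep.axial_location_of_max - x_true) <= 190 / 100

    def test_degenerate_geometry_rejected(self, default_geometry):
        import dataclasses
        bad = dataclasses.replace(default_geometry,
                                  lateral=np.zeros_like(default_geometry.lateral))
        with pytest.raises(GeometryError):
            geo.measure_diameters(bad)

    def test_resolution_convergence(self, table1):
        r200 = geo.measure_diameters(geo.build_geometry(table1, n_stations=200))
        r400 = geo.measure_diameters(geo.build_geometry(table1, n_stations=400))
        for a, b in [(r200.max_lateral, r400.max_lateral),
                     (r200.max_anterior_posterior, r400.max_anterior_posterior)]:
            assert abs(a - b) / b < 1e-3

    def test_sagittal_symmetry_of_lateral_profile(self, default_geometry):
        """Reflection y -> -y maps the surface point cloud onto itself."""
        pts = default_geometry.surface_points()
        refl = pts.copy()
        refl[..., 1] *= -1
        a = set(map(tuple, np.round(pts.reshape(-1, 3), 9)))
        b = set(map(tuple, np.round(refl.reshape(-1, 3), 9)))
        assert a == b


class TestSagittalProfile:
    def test_straight_tube_parallel_lines(self, straight_tube_curves):
        g = geo.build_geometry(straight_tube_curves, n_stations=40)
        ant, post = geo.sagittal_profile(g)
        gap = ant[:, 1] - post[:, 1]
        assert np.allclose(gap, 20.0)

    def test_max_gap_is_ap_diameter(self, default_geometry):
        ant, post = geo.sagittal_profile(default_geometry)
        assert np.max(ant[:, 1] - post[:, 1]) == pytest.approx(54.6, rel=0.005)

    def test_asymmetry_preserved(self, default_geometry):
        ant, post = geo.sagittal_profile(default_geometry)
        assert not np.allclose(ant[:, 1], -post[:, 1])

    def test_enclosed_area_matches_quadrature(self, default_geometry):
        """Area between the polylines equals the trapezoid integral of the gap."""
        ant, post = geo.sagittal_profile(default_geometry)
        x = ant[:, 0]
        gap = ant[:, 1] - post[:, 1]
        expected = np.trapezoid(gap, x)
        # shoelace on the closed polygon (anterior forward, posterior back)
        poly = np.vstack([ant, post[::-1]])
        xs, zs = poly[:, 0], poly[:, 1]
        area = 0.5 * abs(np.dot(xs, np.roll(zs, -1)) - np.dot(zs, np.roll(xs, -1)))
        assert area == pytest.approx(expected, rel=1e-9)


class TestExport:
    def test_vertex_count_and_watertight(self, straight_tube_curves, tmp_path):
        import trimesh
        g = geo.build_geometry(straight_tube_curves, n_stations=24,
                               n_circumferential=16)
        path = tmp_path / "tube.stl"
        geo.export_surface(g, path, "stl")
        mesh = trimesh.load(str(path))
        assert len(mesh.vertices) == 24 * 16 + 2  # stations x circ + 2 cap centres
        assert mesh.is_watertight

    def test_ascii_binary_equivalence(self, straight_tube_curves, tmp_path):
        import trimesh
        g = geo.build_geometry(straight_tube_curves, n_stations=22,
                               n_circumferential=16)
        pa, pb = tmp_path / "a.stl", tmp_path / "b.stl"
        geo.export_surface(g, pa, "stl-ascii")
        geo.export_surface(g, pb, "stl")
        va = np.unique(np.round(trimesh.load(str(pa)).vertices, 5), axis=0)
        vb = np.unique(np.round(trimesh.load(str(pb)).vertices, 5), axis=0)
        assert np.allclose(va, vb)

    def test_stl_roundtrip_preserves_diameters(self, default_geometry, tmp_path):
        import trimesh
        path = tmp_path / "aaa.stl"
        geo.export_surface(default_geometry, path, "stl")
        mesh = trimesh.load(str(path))
        v = mesh.vertices
        lat = 2 * np.max(np.abs(v[:, 1]))
        assert lat == pytest.approx(64.8, rel=0.01)

    def test_vtk_polydata_structure(self, straight_tube_curves, tmp_path):
        g = geo.build_geometry(straight_tube_curves, n_stations=21,
                               n_circumferential=16)
        path = tmp_path / "tube.vtk"
        geo.export_surface(g, path, "vtk")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# vtk DataFile")
        npoints = int([l for l in lines if l.startswith("POINTS")][0].split()[1])
        assert npoints == 21 * 16 + 2

    def test_profile_csv(self, default_geometry, tmp_path):
        import pandas as pd
        path = tmp_path / "profile.csv"
        geo.export_profile_csv(default_geometry, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["x_mm", "lateral_halfwidth_mm",
                                    "z_anterior_mm", "z_posterior_mm"]
        assert len(df) == default_geometry.n_stations


class TestStretch:
    def test_axial_stretch_scales_length_only(self, default_geometry):
        g2 = geo.axially_stretched(default_geometry, 1.25)
        assert g2.length == pytest.approx(190 * 1.25)
        r = geo.measure_diameters(g2)
        assert r.max_lateral == pytest.approx(64.8, rel=0.005)
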