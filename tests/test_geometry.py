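"""Surface geometry: sampling uniformity, geodesic stepping, confinement,
projection, and chart round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from confinedspt.geometry import (
    CellGeometry,
    Region,
    SurfacePoint,
    chart_to_camera,
    chart_to_surface,
    geodesic_confinement_test,
    project_to_camera,
    reflect_into_disc,
    sample_uniform_point,
    step_on_surface,
)


class TestCellGeometry:
    def test_default_length_is_diameter(self):
        g = CellGeometry(radius=0.5)
        assert g.cylinder_length == pytest.approx(1.0)
        assert g.total_length == pytest.approx(2.0)

    @pytest.mark.parametrize("kwargs", [{"radius": 0.0}, {"radius": -1.0},
                                        {"radius": 1.0, "cylinder_length": -0.1}])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CellGeometry(**kwargs)


class TestUniformSampling:
    def test_cap_area_fraction(self, geometry, rng):
        # cap area 4πr² equals cylinder area 2πrL when L = 2r
        pts = [sample_uniform_point(geometry, rng) for _ in range(100_000)]
        frac = np.mean([p.region is not Region.CYLINDER for p in pts])
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_cylinder_only_mode(self, geometry, rng):
        for _ in range(200):
            p = sample_uniform_point(geometry, rng, "cylinder_only")
            assert p.region is Region.CYLINDER

    def test_axial_coordinate_uniform(self, geometry, rng):
        axial = []
        while len(axial) < 100_000:
            p = sample_uniform_point(geometry, rng)
            if p.region is Region.CYLINDER:
                axial.append(p.axial)
        stat = stats.kstest(axial, "uniform",
                            args=(0, geometry.cylinder_length)).statistic
        critical_1pct = 1.63 / math.sqrt(len(axial))
        assert stat < critical_1pct


class TestStepping:
    def test_axial_translation(self, geometry):
        p = SurfacePoint(Region.CYLINDER, axial=0.5, azimuth=0.0)
        q = step_on_surface(p, [0.01, 0.0], geometry)
        assert q.axial == pytest.approx(0.51)
        assert q.azimuth == pytest.approx(0.0)

    def test_circumferential_arc(self, geometry):
        p = SurfacePoint(Region.CYLINDER, axial=0.5, azimuth=0.0)
        q = step_on_surface(p, [0.0, 0.01], geometry)
        assert q.azimuth == pytest.approx(0.02)  # arc = r·Δazimuth, r = 0.5
        assert q.axial == pytest.approx(0.5)

    def test_specular_reflection_at_cylinder_end(self, geometry):
        p = SurfacePoint(Region.CYLINDER, axial=0.005, azimuth=0.0)
        q = step_on_surface(p, [-0.01, 0.0], geometry, "cylinder_only")
        assert q.axial == pytest.approx(0.005)

    def test_oversized_step_rejected(self, geometry):
        p = SurfacePoint(Region.CYLINDER, axial=0.5, azimuth=0.0)
        with pytest.raises(ValueError, match="radius/2"):
            step_on_surface(p, [0.3, 0.0], geometry)

    def test_step_length_preserved_across_junction(self, geometry, rng):
        # intrinsic (≈ chord, at these sizes) distance equals the chart norm
        # to first order even when the geodesic crosses onto a cap
        for _ in range(500):
            p = sample_uniform_point(geometry, rng)
            d = rng.normal(size=2)
            d *= 1e-4 / np.linalg.norm(d)
            q = step_on_surface(p, d, geometry)
            chord = np.linalg.norm(q.to_xyz(geometry) - p.to_xyz(geometry))
            assert chord == pytest.approx(1e-4, rel=1e-6)

    def test_walker_stays_on_surface(self, geometry, rng):
        p = sample_uniform_point(geometry, rng)
        r, L = geometry.radius, geometry.cylinder_length
        for _ in range(2000):
            p = step_on_surface(p, rng.normal(0.0, 0.02, 2), geometry)
            x, y, z = p.to_xyz(geometry)
            if 0 <= x <= L:
                assert math.hypot(y, z) == pytest.approx(r, abs=1e-9)
            else:
                cx = 0.0 if x < 0 else L
                assert math.dist((x, y, z), (cx, 0, 0)) == pytest.approx(r, abs=1e-9)


class TestChartRoundTrip:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=200, deadline=None)
    def test_chart_to_xyz_round_trip(self, seed):
        g = CellGeometry()
        rng = np.random.default_rng(seed)
        p = sample_uniform_point(g, rng)
        xyz = p.to_xyz(g)
        q = SurfacePoint.from_xyz(xyz, g)
        assert np.allclose(q.to_xyz(g), xyz, atol=1e-9)

    def test_scalar_and_vectorized_chart_mapping_agree(self, geometry, rng):
        for mode in ("whole_surface", "cylinder_only"):
            for _ in range(500):
                origin = sample_uniform_point(geometry, rng, mode)
                uv = rng.uniform(-0.25, 0.25, 2)
                sp = chart_to_surface(origin, uv, geometry, mode)
                cam = chart_to_camera(origin, uv[None, :], geometry, mode)[0]
                assert np.allclose(sp.to_xyz(geometry)[:2], cam, atol=1e-9)


class TestConfinement:
    def test_inside_unchanged(self):
        inside, d = geodesic_confinement_test(None, [0.1, 0.0], 0.2)
        assert inside and np.allclose(d, [0.1, 0.0])

    def test_one_dimensional_mirror(self):
        inside, d = geodesic_confinement_test(None, [0.25, 0.0], 0.2)
        assert not inside
        assert np.allclose(d, [0.15, 0.0])  # 0.2 − (0.25 − 0.2)

    def test_repeated_reflection_lands_inside(self, rng):
        for _ in range(1000):
            d = reflect_into_disc(rng.normal(0, 0.5, 2), 0.15)
            assert np.hypot(*d) <= 0.15 + 1e-12

    def test_stationary_density_uniform_over_disc(self, rng):
        # reflected Brownian motion in a disc equilibrates to the uniform
        # (area) measure; chi-squared on a radial histogram at the 1% level
        R = 0.15
        n, burn, steps = 3000, 400, 1200
        p = np.zeros((n, 2))
        sig = 0.01  # step ≪ R so the reflected chain is a faithful discretization
        for i in range(steps):
            p += rng.normal(0.0, sig, (n, 2))
            rho = np.hypot(p[:, 0], p[:, 1])
            m = rho > R
            if m.any():
                u = np.mod(rho[m] + R, 4 * R)
                p[m] *= ((R - np.abs(u - 2 * R)) / rho[m])[:, None]
        rho = np.hypot(p[:, 0], p[:, 1])
        edges = np.linspace(0.0, R, 11)
        counts, _ = np.histogram(rho, edges)
        expected = n * np.diff(edges**2) / R**2  # area-weighted
        chi2 = float(np.sum((counts - expected) ** 2 / expected))
        assert chi2 < stats.chi2.ppf(0.99, df=len(counts) - 1)


class TestProjection:
    def test_top_of_cell_projects_to_axis(self, geometry):
        p = SurfacePoint(Region.CYLINDER, axial=0.3, azimuth=0.0)
        cam = project_to_camera(p, geometry)
        assert cam.x == pytest.approx(0.3)
        assert cam.y == pytest.approx(0.0)

    def test_cell_edge(self, geometry):
        p = SurfacePoint(Region.CYLINDER, axial=0.3, azimuth=math.pi / 2)
        assert project_to_camera(p, geometry).y == pytest.approx(0.5)

    def test_foreshortening_at_edge(self, geometry):
        # a circumferential arc δ produces |Δy| ≈ δ at the top but ≈ 0 at the edge
        delta = 1e-3
        top0 = SurfacePoint(Region.CYLINDER, axial=0.5, azimuth=0.0)
        top1 = step_on_surface(top0, [0.0, delta], geometry)
        dy_top = abs(project_to_camera(top1, geometry).y
                     - project_to_camera(top0, geometry).y)
        edge0 = SurfacePoint(Region.CYLINDER, axial=0.5, azimuth=math.pi / 2)
        edge1 = step_on_surface(edge0, [0.0, delta], geometry)
        dy_edge = abs(project_to_camera(edge1, geometry).y
                      - project_to_camera(edge0, geometry).y)
        assert dy_top == pytest.approx(delta, rel=1e-5)
        assert dy_edge < 0.01 * delta

    def test_projection_never_increases_msd(self, geometry, rng):
        # orthographic projection can only shrink displacements
        from confinedspt.simulate import _chart_paths, _chart_to_camera_batch, _sample_origins
        from confinedspt.geometry import Mode

        n, T = 400, 200
        origins = _sample_origins(geometry, Mode.WHOLE_SURFACE, n, rng)
        chart = _chart_paths(n, T, 5e-4, 2.0, 0.2, rng)
        cam = _chart_to_camera_batch(origins, chart, geometry, Mode.WHOLE_SURFACE)
        for lag in (1, 5, 20, 100):
            d_chart = chart[:, lag:, :] - chart[:, :-lag, :]
            d_cam = cam[:, lag:, :] - cam[:, :-lag, :]
            msd_chart = np.mean(np.sum(d_chart**2, axis=2))
            msd_cam = np.mean(np.sum(d_cam**2, axis=2))
            assert msd_cam <= msd_chart * (1 + 1e-9)
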