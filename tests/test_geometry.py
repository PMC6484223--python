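import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budmorph import geometry as G
from budmorph.errors import GeometryError, InputError


def _circle(r=50.0, n=200, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return center + r * np.column_stack([np.cos(th), np.sin(th)])


def _ellipse(a, b, n=400):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(th), b * np.sin(th)])


class TestBoundaryCurve:
    def test_orientation_forced_ccw(self):
        pts = _circle(10, 50)[::-1]
        curve = G.BoundaryCurve(pts)
        # outward normal at the rightmost point must point +x
        i = np.argmax(curve.points[:, 0])
        assert curve.outward_normals()[i, 0] > 0.9

    def test_rejects_self_intersection(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2.0]])
        with pytest.raises(GeometryError):
            G.BoundaryCurve(bowtie)

    def test_rejects_duplicate_points(self):
        pts = np.array([[0, 0], [1, 0], [1, 0], [1, 1], [0, 1.0]])
        with pytest.raises(InputError):
            G.BoundaryCurve(pts)

    def test_area_and_length_of_circle(self):
        c = G.BoundaryCurve(_circle(10, 500))
        assert c.area == pytest.approx(np.pi * 100, rel=1e-3)
        assert c.total_length == pytest.approx(2 * np.pi * 10, rel=1e-3)

    def test_resample_preserves_shape(self):
        c = G.BoundaryCurve(_circle(10, 100))
        r = c.resample(57)
        assert r.n_points == 57
        assert np.allclose(np.linalg.norm(r.points, axis=1), 10, atol=0.05)

    def test_csv_roundtrip(self, tmp_path):
        c = G.BoundaryCurve(_circle(5, 40))
        path = tmp_path / "curve.csv"
        c.to_csv(path)
        c2 = G.BoundaryCurve.from_csv(path)
        assert np.allclose(c.points, c2.points)


class TestFitBoundarySpline:
    def test_circle_reproduced(self):
        curve = G.fit_boundary_spline(_circle(50, 200), n_control=50)
        r = np.linalg.norm(curve.spline_points(2000), axis=1)
        assert np.abs(r - 50).max() < 1e-3

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            G.fit_boundary_spline(np.array([[0, 0], [1, 0], [0, 1.0]]), degree=3)

    def test_self_intersecting_input_rejected(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2], [0, 1],
                           [-1, 1.0]])
        with pytest.raises(GeometryError):
            G.fit_boundary_spline(bowtie)

    def test_noisy_ellipse_rms_below_noise(self):
        # oracle: dense point-to-curve distances against the fitted spline
        rng = np.random.default_rng(42)
        th = np.linspace(0, 2 * np.pi, 300, endpoint=False)
        clean = np.column_stack([40 * np.cos(th), 25 * np.sin(th)])
        nrm = np.column_stack([25 * np.cos(th), 40 * np.sin(th)])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        noisy = clean + 0.5 * rng.normal(size=(300, 1)) * nrm
        curve = G.fit_boundary_spline(noisy, n_control=24)
        dense = curve.spline_points(4000)
        d = np.abs(np.linalg.norm(dense / np.array([40, 25.0]), axis=1) - 1.0)
        rms_resid = np.sqrt(np.mean((d * 25) ** 2))  # lower bound on distance
        assert rms_resid < 0.5

    def test_periodic_continuity(self):
        curve = G.fit_boundary_spline(_circle(10, 60), n_control=20)
        a = curve.eval_spline(np.array([0.0]))
        b = curve.eval_spline(np.array([1.0 - 1e-12]))
        assert np.allclose(a, b, atol=1e-6)


class TestMesenchymeEllipse:
    def test_filled_ellipse_closed_form(self):
        # second moments of a uniform ellipse are (a^2/4, b^2/4) so the
        # derived semi-axes are alpha*(a, b)
        bc = G.BoundaryCurve(_ellipse(10, 5))
        ell = G.mesenchyme_ellipse(bc, alpha=3.0)
        assert ell.semi_axes[0] == pytest.approx(30.0, rel=1e-3)
        assert ell.semi_axes[1] == pytest.approx(15.0, rel=1e-3)
        assert np.allclose(ell.center, 0.0, atol=1e-6)

    def test_disc_gives_circle(self):
        bc = G.BoundaryCurve(_circle(7, 300))
        ell = G.mesenchyme_ellipse(bc, alpha=2.0)
        assert ell.semi_axes[0] == pytest.approx(14.0, rel=1e-3)
        assert ell.semi_axes[1] == pytest.approx(14.0, rel=1e-3)

    def test_alpha_linearity(self):
        bc = G.BoundaryCurve(_ellipse(12, 7))
        e1 = G.mesenchyme_ellipse(bc, alpha=1.5)
        e2 = G.mesenchyme_ellipse(bc, alpha=3.0)
        assert np.allclose(2 * np.asarray(e1.semi_axes),
                           np.asarray(e2.semi_axes), rtol=1e-9)
        assert np.allclose(e1.center, e2.center)

    def test_rigid_motion_equivariance(self):
        bc = G.BoundaryCurve(_ellipse(12, 7))
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = np.array([13.0, -4.0])
        moved = G.BoundaryCurve(bc.points @ R.T + shift)
        e0 = G.mesenchyme_ellipse(bc, alpha=3.0)
        e1 = G.mesenchyme_ellipse(moved, alpha=3.0)
        assert np.allclose(e1.center, R @ e0.center + shift, atol=1e-6)
        assert np.allclose(e1.semi_axes, e0.semi_axes, rtol=1e-6)
        # orientation equivariant up to sign
        assert abs(np.dot(e1.orientation, R @ e0.orientation)) > 1 - 1e-6

    def test_boundary_mode_available(self):
        bc = G.BoundaryCurve(_ellipse(10, 5))
        ell = G.mesenchyme_ellipse(bc, alpha=3.0, mode="boundary")
        # boundary-point second moments of an ellipse differ from the
        # filled ones but axes ratio orientation is preserved
        assert ell.semi_axes[0] > ell.semi_axes[1]

    def test_sampling_density_invariance(self):
        m_coarse = G.polygon_moments(_ellipse(10, 5, 200))[2]
        m_fine = G.polygon_moments(_ellipse(10, 5, 2000))[2]
        assert np.allclose(m_coarse, m_fine, rtol=5e-3)
        assert np.all(np.linalg.eigvalsh(m_fine) >= 0)

    def test_invalid_alpha(self):
        bc = G.BoundaryCurve(_ellipse(10, 5))
        with pytest.raises(InputError):
            G.mesenchyme_ellipse(bc, alpha=0.0)


class TestRemoveStalk:
    def test_no_interval_is_identity(self):
        c = G.BoundaryCurve(_circle(10, 100))
        assert G.remove_stalk(c) is c

    def test_circle_segment_area(self):
        r, n = 50.0, 2000
        total = 2 * np.pi * r
        frac = 0.10
        c = G.BoundaryCurve(_circle(r, n), stalk_interval=(0.0, frac * total))
        cut = G.remove_stalk(c)
        theta = frac * 2 * np.pi
        segment = 0.5 * r * r * (theta - np.sin(theta))
        assert cut.area == pytest.approx(np.pi * r * r - segment, rel=1e-3)
        assert cut.area <= c.area

    def test_full_interval_rejected(self):
        c = G.BoundaryCurve(_circle(10, 100))
        c = G.BoundaryCurve(c.points, stalk_interval=(0.0, c.total_length))
        with pytest.raises(InputError):
            G.remove_stalk(c)

    def test_wrapping_interval(self):
        total = 2 * np.pi * 10
        c = G.BoundaryCurve(_circle(10, 400),
                            stalk_interval=(0.9 * total, 0.1 * total))
        cut = G.remove_stalk(c)
        assert cut.area < c.area
        assert cut.stalk_interval is None


class TestBuildMesh:
    def test_structure(self, small_disc_domain, small_disc_mesh):
        mesh = small_disc_mesh
        assert set(np.unique(mesh.subdomain_labels)) == {G.EPITHELIUM,
                                                         G.MESENCHYME}
        # interface loop is closed: consecutive loop nodes are mesh edges
        loop = mesh.interface_loops[0]
        edges = {tuple(sorted(e)) for e in
                 mesh.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)}
        for i in range(len(loop)):
            a, b = loop[i], loop[(i + 1) % len(loop)]
            assert (min(a, b), max(a, b)) in edges

    def test_median_edge_near_target(self, small_disc_mesh):
        assert abs(small_disc_mesh.median_edge_length() - 1.5) / 1.5 < 0.25

    def test_subdomain_areas(self, small_disc_domain):
        mesh = G.build_mesh(small_disc_domain, target_h=1.0)
        epi = mesh.subdomain_area(G.EPITHELIUM)
        mes = mesh.subdomain_area(G.MESENCHYME)
        assert abs(epi - np.pi * 15 ** 2) / (np.pi * 15 ** 2) < 0.01
        total = np.pi * 45.0 * 45.0001
        assert abs(epi + mes - total) / total < 0.01

    def test_refinement_scaling(self, small_disc_domain):
        m1 = G.build_mesh(small_disc_domain, target_h=2.0)
        m2 = G.build_mesh(small_disc_domain, target_h=1.0)
        ratio = m2.n_triangles / m1.n_triangles
        assert 2.8 < ratio < 5.2  # ~4x with +-30%

    def test_min_angle_floor(self, small_disc_mesh):
        assert small_disc_mesh.min_angles().min() >= 10.0

    def test_epithelium_outside_rejected(self):
        epi = G.BoundaryCurve(_circle(30, 100))
        ell = G.Ellipse2D(np.zeros(2), (20.0001, 20.0), np.array([1.0, 0.0]))
        with pytest.raises(GeometryError):
            G.TwoLayerDomain((epi,), ell)

    def test_msh_export(self, small_disc_mesh, tmp_path):
        path = tmp_path / "mesh.msh"
        small_disc_mesh.save_msh(path)
        text = path.read_text()
        assert "$MeshFormat" in text and "$Elements" in text


class TestRectangleMesh:
    def test_area_and_labels(self):
        mesh = G.rectangle_mesh(10, 4, 0.5)
        assert mesh.triangle_areas().sum() == pytest.approx(40.0)
        assert np.all(mesh.subdomain_labels == G.EPITHELIUM)


@settings(max_examples=20, deadline=None)
@given(a=st.floats(5, 30), b=st.floats(2, 20), alpha=st.floats(0.5, 5))
def test_moment_ellipse_property(a, b, alpha):
    """Closed-form second moments for any uniform ellipse."""
    lo, hi = min(a, b), max(a, b)
    bc = G.BoundaryCurve(_ellipse(hi, lo))
    ell = G.mesenchyme_ellipse(bc, alpha=alpha)
    assert ell.semi_axes[0] == pytest.approx(alpha * hi, rel=2e-3)
    assert ell.semi_axes[1] == pytest.approx(alpha * lo, rel=2e-3)
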