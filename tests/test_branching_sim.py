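import numpy as np
import pytest

from budmorph.branching_sim import (GrowthLaw, add_ligand_source,
                                    classify_elongation, detect_tips,
                                    grow_step, lambda_fraction,
                                    simulate_branching)
from budmorph.errors import InputError
from budmorph.fem_solver import SignalProfile, solve_steady
from budmorph.geometry import (BoundaryCurve, Ellipse2D, TwoLayerDomain,
                               build_mesh)
from budmorph.rd_models import ModelSpec
from budmorph.synthetic_data import fixture_parameters


def _circle_curve(r, n=200):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return BoundaryCurve(r * np.column_stack([np.cos(th), np.sin(th)]))


def _profile(values, total):
    n = len(values)
    return SignalProfile(arc_positions=np.linspace(0, total, n,
                                                   endpoint=False),
                         values=np.asarray(values, dtype=float),
                         total_length=total, closed=True)


class TestGrowthLaw:
    def test_defaults(self):
        law = GrowthLaw()
        assert law.v_g == 0.04
        assert law.outer_speed == 0.04

    def test_f_properties(self):
        law = GrowthLaw(K_g=2.0, h_g=2.0)
        s = np.linspace(0, 100, 500)
        f = law.f(s)
        assert f[0] == 0.0
        assert np.all(np.diff(f) >= 0)
        assert np.all(f <= 1.0)
        assert law.f(2.0) == pytest.approx(0.5)

    def test_invalid(self):
        with pytest.raises(InputError):
            GrowthLaw(K_g=0.0)


class TestGrowStep:
    def test_zero_signal_interface_frozen_outer_expands(self):
        epi = _circle_curve(10.0)
        ell = Ellipse2D(np.zeros(2), (40.0001, 40.0), np.array([1.0, 0.0]))
        dom = TwoLayerDomain((epi,), ell)
        law = GrowthLaw(v_g=0.05, K_g=1.0)
        prof = _profile(np.zeros(100), epi.total_length)
        new = grow_step(None, dom, law, dt=10.0, profiles=[prof])
        assert np.allclose(new.epithelium.points, epi.points)
        assert new.mesenchyme.semi_axes[0] == pytest.approx(40.5001)

    def test_constant_signal_concentric_growth(self):
        epi = _circle_curve(10.0, 300)
        ell = Ellipse2D(np.zeros(2), (40.0001, 40.0), np.array([1.0, 0.0]))
        dom = TwoLayerDomain((epi,), ell)
        law = GrowthLaw(v_g=0.05, K_g=1.0, h_g=2.0)
        s0 = 3.0
        prof = _profile(np.full(150, s0), epi.total_length)
        dt = 10.0
        new = grow_step(None, dom, law, dt, profiles=[prof])
        r_new = np.linalg.norm(new.epithelium.points, axis=1)
        expected = 10.0 + law.v_g * law.f(s0) * dt
        assert np.allclose(r_new, expected, atol=5e-3)

    def test_area_nondecreasing_outward(self):
        epi = _circle_curve(10.0)
        ell = Ellipse2D(np.zeros(2), (40.0001, 40.0), np.array([1.0, 0.0]))
        dom = TwoLayerDomain((epi,), ell)
        law = GrowthLaw(v_g=0.05, K_g=0.5)
        rng = np.random.default_rng(0)
        prof = _profile(rng.uniform(0.5, 3.0, 100), epi.total_length)
        new = grow_step(None, dom, law, 5.0, profiles=[prof])
        assert new.epithelium.area >= dom.epithelium.area

    def test_peak_signal_displaces_tip(self):
        epi = _circle_curve(10.0, 360)
        ell = Ellipse2D(np.zeros(2), (40.0001, 40.0), np.array([1.0, 0.0]))
        dom = TwoLayerDomain((epi,), ell)
        law = GrowthLaw(v_g=0.05, K_g=1.0)
        total = epi.total_length
        s = np.linspace(0, total, 360, endpoint=False)
        peak_arc = 0.25 * total  # top of the circle
        vals = 5.0 * np.exp(-0.5 * ((s - peak_arc) / (0.03 * total)) ** 2)
        prof = _profile(vals, total)
        dt = 20.0
        new = grow_step(None, dom, law, dt, profiles=[prof])
        # analytic per-point advection oracle
        disp = np.linalg.norm(new.epithelium.points, axis=1) - 10.0
        i_max = np.argmax(disp)
        arc_of_max = new.epithelium.arc_positions[i_max]
        assert abs(arc_of_max - peak_arc) < 3 * total / 360 + 1e-9
        assert disp.max() == pytest.approx(law.v_g * law.f(vals.max()) * dt,
                                           rel=0.05)


class TestDetectTips:
    def test_circle_no_tips(self):
        pos, _ = detect_tips(_circle_curve(20.0), curvature_threshold=0.01)
        assert len(pos) == 0

    def test_three_lobed_flower(self):
        # r(t) = R + a cos(3t): curvature maxima exactly at the 3 apices
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        r = 20.0 + 5.0 * np.cos(3 * th)
        curve = BoundaryCurve(np.column_stack([r * np.cos(th),
                                               r * np.sin(th)]))
        pos, _ = detect_tips(curve, curvature_threshold=0.06,
                             min_separation=15.0)
        assert len(pos) == 3
        angles = np.sort(np.mod(np.arctan2(pos[:, 1], pos[:, 0]), 2 * np.pi))
        assert np.allclose(angles, [0, 2 * np.pi / 3, 4 * np.pi / 3],
                           atol=0.1)

    def test_huge_threshold_empty(self):
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        r = 20.0 + 5.0 * np.cos(3 * th)
        curve = BoundaryCurve(np.column_stack([r * np.cos(th),
                                               r * np.sin(th)]))
        pos, _ = detect_tips(curve, curvature_threshold=1e6)
        assert len(pos) == 0


class TestClassifyElongation:
    def _single_peak(self, ratio, centre_frac=0.5, total=100.0, n=200):
        s = np.linspace(0, total, n, endpoint=False)
        base = 1.0
        peak = (ratio - 1.0) * np.exp(
            -0.5 * ((s - centre_frac * total) / (0.05 * total)) ** 2)
        return _profile(base + peak, total)

    def test_flat_profile_fails_amplitude(self):
        prof = _profile(np.ones(100), 100.0)
        res = classify_elongation([prof, prof], [50.0, 50.0])
        assert not res.elongation
        assert not res.criterion_flags["amplitude"]

    def test_single_centred_peak_passes(self):
        p1 = self._single_peak(20.0)
        res = classify_elongation([p1, p1], [50.0, 50.0])
        assert res.elongation
        assert res.criterion_flags == {"amplitude": True, "single_peak": True,
                                       "centred": True}

    def test_two_peaks_fail(self):
        s = np.linspace(0, 100, 200, endpoint=False)
        vals = (1.0 + 20 * np.exp(-0.5 * ((s - 30) / 4) ** 2)
                + 20 * np.exp(-0.5 * ((s - 70) / 4) ** 2))
        p2 = _profile(vals, 100.0)
        good = self._single_peak(20.0)
        res = classify_elongation([good, p2], [50.0, 50.0])
        assert not res.elongation
        assert not res.criterion_flags["single_peak"]

    def test_off_centre_peak_fails(self):
        p = self._single_peak(20.0, centre_frac=0.2)
        res = classify_elongation([p, p], [50.0, 50.0])
        assert not res.elongation
        assert not res.criterion_flags["centred"]

    def test_empty_profile_rejected(self):
        with pytest.raises(InputError):
            classify_elongation([_profile(np.zeros(10), 10.0)], [5.0])


class TestLambdaFraction:
    def test_none(self):
        assert lambda_fraction([False, False]) == 0.0

    def test_all(self):
        assert lambda_fraction([True] * 7 ) == 1.0

    def test_three_of_eight(self):
        assert lambda_fraction([True] * 3 + [False] * 5) == 0.375

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            lambda_fraction([])


class TestAddLigandSource:
    def test_zero_rate_unchanged(self):
        m = ModelSpec("T1", fixture_parameters()["T1_fine"])
        assert add_ligand_source(m, "uniform", rate=0.0) is m

    def test_bead_outside_rejected(self):
        m = ModelSpec("T1", fixture_parameters()["T1_fine"])
        epi = _circle_curve(10.0)
        ell = Ellipse2D(np.zeros(2), (30.0001, 30.0), np.array([1.0, 0.0]))
        dom = TwoLayerDomain((epi,), ell)
        with pytest.raises(InputError):
            add_ligand_source(m, "bead", location=(100.0, 0.0), rate=1.0,
                              radius=3.0, domain=dom)
        with pytest.raises(InputError):  # inside the epithelium
            add_ligand_source(m, "bead", location=(0.0, 0.0), rate=1.0,
                              radius=3.0, domain=dom)

    def test_bead_raises_local_ligand(self, small_disc_domain):
        mesh = build_mesh(small_disc_domain, target_h=2.0)
        m = ModelSpec("T3", fixture_parameters()["T1_fine"])
        bead_pos = np.array([0.0, 30.0])
        m_bead = add_ligand_source(m, "bead", location=bead_pos, rate=5.0,
                                   radius=4.0, domain=small_disc_domain)
        st0 = solve_steady(m, mesh, tol=1e-6)
        st1 = solve_steady(m_bead, mesh, tol=1e-6)
        near = np.linalg.norm(mesh.nodes - bead_pos, axis=1) < 6.0
        far = np.linalg.norm(mesh.nodes - (-bead_pos), axis=1) < 6.0
        gain_near = st1.L[near].mean() - st0.L[near].mean()
        gain_far = st1.L[far].mean() - st0.L[far].mean()
        assert gain_near > 0
        assert gain_near > 2 * gain_far

    def test_uniform_raises_ligand_everywhere(self, small_disc_domain):
        mesh = build_mesh(small_disc_domain, target_h=2.0)
        m = ModelSpec("T3", fixture_parameters()["T1_fine"])
        m_up = add_ligand_source(m, "uniform", rate=1.0)
        st0 = solve_steady(m, mesh, tol=1e-6)
        st1 = solve_steady(m_up, mesh, tol=1e-6)
        assert st1.L.mean() > st0.L.mean()


class TestSimulateBranchingSmoke:
    def test_short_run_structure(self):
        from budmorph.scenarios import SINGLE_BUD_SIM_KWARGS, single_bud_scenario
        domain, law, model = single_bud_scenario("T1")
        shapes, log, tips = simulate_branching(model, domain, law, t_end=40.0,
                                               remesh_every=5, seed=0,
                                               **SINGLE_BUD_SIM_KWARGS)
        assert len(shapes) >= 2
        assert tips[0][1] == 1  # single-bud init
        # area grows (outward velocities only)
        assert shapes[-1][1].epithelium.area >= shapes[0][1].epithelium.area
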