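import numpy as np
import pytest

from budmorph.errors import GeometryError, InputError
from budmorph.geometry import BoundaryCurve
from budmorph.image_pipeline import (border_to_curve, displacement_field,
                                     extract_border, growth_field,
                                     interbud_min_distance, segment_epithelium)
from budmorph.synthetic_data import (GrowthSpec, ShapeSpec, make_bud_shape,
                                     make_timelapse, mask_to_world, rasterize)


def _circle_curve(r, n=300, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return BoundaryCurve(np.asarray(center)
                         + r * np.column_stack([np.cos(th), np.sin(th)]))


class TestSegmentEpithelium:
    def test_largest_object_selected(self):
        img = np.zeros((60, 60))
        img[5:30, 5:25] = 1.0  # area 500
        img[40:50, 40:45] = 1.0  # area 50
        mask = segment_epithelium(img, threshold=0.5)
        assert mask[10, 10] and not mask[45, 42]
        assert mask.sum() == 500

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            segment_epithelium(np.zeros((10, 10)))

    def test_noisy_synthetic_recovery(self):
        shape = make_bud_shape(ShapeSpec(base=(25.0, 16.0),
                                         buds=((0.8, 8.0, 0.4),)))
        img, meta = rasterize(shape, resolution=2.0, noise_sigma=0.05, seed=0)
        mask = segment_epithelium(img, threshold=0.5)
        border = extract_border(mask)
        world = mask_to_world(border, meta)
        # Hausdorff distance to ground truth <= 2 px (= 1 length unit here)
        from scipy.spatial import cKDTree
        d1 = cKDTree(shape.points).query(world)[0].max()
        d2 = cKDTree(world).query(shape.points)[0].max()
        assert max(d1, d2) <= 2.0 / meta["resolution"] + 0.5


class TestExtractBorder:
    def test_square_perimeter(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True  # 20x20 square
        border = extract_border(mask)
        closed = np.vstack([border, border[:1]])
        perim = np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))
        assert perim == pytest.approx(80.0, rel=0.05)

    def test_single_pixel_degenerate(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(GeometryError):
            extract_border(mask)

    def test_disc_area(self):
        yy, xx = np.ogrid[:80, :80]
        mask = (yy - 40) ** 2 + (xx - 40) ** 2 < 30 ** 2
        border = extract_border(mask)
        x, y = border[:, 1], border[:, 0]
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert area == pytest.approx(np.pi * 900, rel=0.02)

    def test_multiple_components_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:15, 10:15] = True
        with pytest.raises(InputError):
            extract_border(mask)


class TestDisplacementField:
    def test_concentric_circle_dilation(self):
        c1 = _circle_curve(10.0)
        c2 = _circle_curve(11.0)
        base, vecs, mags, arcs = displacement_field(c1, c2, n_points=200)
        assert np.all(mags > 0)
        assert np.allclose(mags, 1.0, atol=1e-3)

    def test_identical_curves_zero(self):
        c = _circle_curve(10.0)
        _, vecs, mags, _ = displacement_field(c, c, n_points=100)
        assert np.allclose(np.abs(mags), 0.0, atol=1e-6)

    def test_scaled_ellipse_matches_bruteforce_oracle(self):
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        e1 = BoundaryCurve(np.column_stack([20 * np.cos(th),
                                            10 * np.sin(th)]))
        e2 = BoundaryCurve(np.column_stack([22 * np.cos(th),
                                            11 * np.sin(th)]))
        base, vecs, mags, _ = displacement_field(e1, e2, n_points=100)

        # brute force: for each base point walk its normal ray in tiny
        # steps until crossing the dense target polygon
        from matplotlib.path import Path
        target = Path(e2.points)
        normals = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        for i in range(0, 100, 7):
            t_grid = np.linspace(1e-6, 6.0, 12000)
            pts = base[i] + t_grid[:, None] * normals[i]
            inside = target.contains_points(pts)
            first_out = np.argmin(inside)  # leaves the target polygon
            t_cross = t_grid[first_out]
            assert mags[i] == pytest.approx(t_cross, rel=0.01)

    def test_shrinkage_negative(self):
        c1 = _circle_curve(10.0)
        c2 = _circle_curve(9.0)
        _, _, mags, _ = displacement_field(c1, c2, n_points=64)
        assert np.all(mags < 0)
        assert np.allclose(mags, -1.0, atol=1e-3)

    def test_missing_flagged(self):
        c1 = _circle_curve(10.0)
        c2 = _circle_curve(10.0, center=(100.0, 0))
        _, _, mags, _ = displacement_field(c1, c2, n_points=32, max_ray=5.0)
        assert np.isnan(mags).any()


class TestGrowthField:
    def test_inward_zeroing_rule(self):
        c1 = _circle_curve(10.0)
        base = c1.points[:3]
        vecs = np.array([[1.0, 0], [-0.5, 0], [2.0, 0]])
        mags = np.array([1.0, -0.5, 2.0])
        gf = growth_field((base, vecs, mags, np.arange(3.0)))
        assert np.allclose(gf.magnitudes, [1.0, 0.0, 2.0])
        assert np.allclose(gf.vectors[1], 0.0)

    def test_all_inward_zero(self):
        gf = growth_field((np.zeros((4, 2)), -np.ones((4, 2)),
                           -np.ones(4), np.arange(4.0)))
        assert np.allclose(gf.magnitudes, 0.0)

    def test_all_outward_unchanged(self):
        vecs = np.ones((4, 2))
        mags = np.full(4, np.sqrt(2))
        gf = growth_field((np.zeros((4, 2)), vecs, mags, np.arange(4.0)))
        assert np.allclose(gf.magnitudes, mags)
        assert np.allclose(gf.vectors, vecs)

    def test_missing_treated_as_zero(self):
        mags = np.array([1.0, np.nan, 2.0])
        gf = growth_field((np.zeros((3, 2)), np.ones((3, 2)), mags,
                           np.arange(3.0)))
        assert np.allclose(gf.magnitudes, [1.0, 0.0, 2.0])

    def test_rigid_motion_invariance(self):
        shape = make_bud_shape(ShapeSpec(base=(20.0, 14.0)))
        tl = make_timelapse(shape, GrowthSpec((15.0,), (1.5,), (8.0,),
                                              n_frames=2))
        f0, f1 = tl.frames
        gf = growth_field(displacement_field(f0, f1, n_points=128))
        ang = 1.1
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = np.array([7.0, -2.0])
        f0r = BoundaryCurve(f0.points @ R.T + shift)
        f1r = BoundaryCurve(f1.points @ R.T + shift)
        gfr = growth_field(displacement_field(f0r, f1r, n_points=128))
        assert np.allclose(gfr.magnitudes, gf.magnitudes, atol=1e-6)


class TestInterbudMinDistance:
    def test_two_circles_analytic_gap(self):
        b1 = _circle_curve(5.0, center=(0.0, 0.0))
        b2 = _circle_curve(5.0, center=(20.0, 0.0))
        res = interbud_min_distance([b1, b2], ((-60, -60), (80, 60)))
        assert res["overall_min"] == pytest.approx(10.0, rel=1e-3)

    def test_edge_discard_rule(self):
        b1 = _circle_curve(5.0, center=(0.0, 0.0))
        b2 = _circle_curve(5.0, center=(20.0, 0.0))
        # image edge 3 px left of bud 1: its leftmost points are nearer
        # the edge than the other bud and must be discarded
        res = interbud_min_distance([b1, b2], ((-8, -60), (80, 60)))
        assert res["per_bud"][0]["n_discarded"] > 0
        far = interbud_min_distance([b1, b2], ((-60, -60), (80, 60)))
        assert res["per_bud"][0]["n_discarded"] > far["per_bud"][0]["n_discarded"]

    def test_three_buds_bruteforce(self):
        b1 = _circle_curve(3.0, center=(0.0, 0.0))
        b2 = _circle_curve(3.0, center=(10.0, 0.0))  # gap 4
        b3 = _circle_curve(3.0, center=(0.0, 13.0))  # gap 7 to b1
        res = interbud_min_distance([b1, b2, b3], ((-50, -50), (60, 60)))
        # brute-force all-pairs point distances
        curves = [b1, b2, b3]
        brute = np.inf
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                d = np.min(np.linalg.norm(
                    curves[i].points[:, None] - curves[j].points[None], axis=2))
                brute = min(brute, d)
        assert res["overall_min"] == pytest.approx(brute, rel=0.02)
        assert res["overall_min"] == pytest.approx(4.0, rel=0.02)

    def test_single_bud_rejected(self):
        with pytest.raises(InputError):
            interbud_min_distance([_circle_curve(5.0)], ((-10, -10), (10, 10)))


class TestEndToEnd:
    def test_displacements_reproduce_next_frame(self):
        shape = make_bud_shape(ShapeSpec(base=(25.0, 16.0)))
        tl = make_timelapse(shape, GrowthSpec((20.0, 70.0), (1.2, 0.8),
                                              (9.0, 9.0), n_frames=2))
        f0, f1 = tl.frames
        base, vecs, mags, _ = displacement_field(f0, f1, n_points=300)
        moved = base + np.nan_to_num(vecs)
        from scipy.spatial import cKDTree
        d = cKDTree(f1.points).query(moved)[0].max()
        bbox = np.ptp(f1.points, axis=0)
        assert d <= 0.02 * np.hypot(*bbox)

    def test_growth_profile_recovery_pearson(self):
        # full pipeline: shape -> raster -> segment -> border -> spline ->
        # displacement -> growth field vs known ground truth
        shape = make_bud_shape(ShapeSpec(base=(30.0, 20.0),
                                         buds=((0.6, 8.0, 0.45),)))
        growth = GrowthSpec((25.0, 95.0), (1.5, 1.0), (10.0, 8.0),
                            n_frames=3)
        tl = make_timelapse(shape, growth)
        recovered_frames = []
        for frame in tl.frames:
            img, meta = rasterize(frame, resolution=2.0, noise_sigma=0.03,
                                  seed=1)
            mask = segment_epithelium(img, threshold=0.5)
            border = extract_border(mask)
            recovered_frames.append(border_to_curve(border, meta,
                                                    n_control=80))
        r_values = []
        for i in range(2):
            f0 = recovered_frames[i]
            f1 = recovered_frames[i + 1]
            base, vecs, mags, arcs = displacement_field(f0, f1, n_points=300)
            gf = growth_field((base, vecs, mags, arcs))
            truth = tl.ground_truth[i]
            # sample ground truth at the recovered base points (nearest)
            from scipy.spatial import cKDTree
            _, idx = cKDTree(truth["base_points"]).query(base)
            r = np.corrcoef(gf.magnitudes, truth["magnitudes"][idx])[0, 1]
            r_values.append(r)
        assert min(r_values) >= 0.95
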