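import numpy as np
import pytest

import microves as mv
from microves.skeleton import Branch, smooth_branch
from conftest import analyze_mask, voxelized_curve_branch


@pytest.fixture(scope="module")
def tube_table(straight_tube):
    _, _, mask, _ = straight_tube
    graph = analyze_mask(mask)
    return graph, mask, mv.compute_morphometry(graph, mask)


@pytest.fixture(scope="module")
def elliptical_tube():
    spec = mv.PhantomSpec(
        box_size=(160, 100, 80), spacing=1.0,
        tubes=[mv.TubeSpec(mv.Line((15, 50, 40), (145, 50, 40)), a=20.0, b=10.0)],
    )
    _, mask, truth = mv.render(spec)
    graph = analyze_mask(mask)
    return mask, truth, mv.compute_morphometry(graph, mask)


class TestLength:
    def test_two_points(self):
        b = smooth_branch(Branch(1, 2, np.array([[0, 0, 0], [10, 0, 0.0]])))
        assert mv.branch_length(b) == pytest.approx(10.0, rel=1e-6)

    def test_quarter_circle_analytic(self):
        th = np.linspace(0, np.pi / 2, 300)
        pts = np.c_[20 * np.cos(th), 20 * np.sin(th), np.zeros_like(th)]
        b = voxelized_curve_branch(pts)
        assert mv.branch_length(b) == pytest.approx(10 * np.pi, abs=0.6)

    def test_network_total_against_truth(self, straight_tube):
        _, _, mask, truth = straight_tube
        graph = analyze_mask(mask)
        truth_total = sum(b.metrics["length_true"] for b in truth.branches)
        assert graph.total_length() == pytest.approx(truth_total, rel=0.03)


class TestTortuosity:
    def test_straight_branch_is_one(self, tube_table):
        _, _, table = tube_table
        assert table["tortuosity"].iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_semicircle_is_half_pi(self):
        th = np.linspace(0, np.pi, 400)
        pts = np.c_[60 + 40 * np.cos(th), 20 + 40 * np.sin(th), np.zeros_like(th)]
        b = voxelized_curve_branch(pts)
        assert mv.branch_tortuosity(b) == pytest.approx(np.pi / 2, rel=0.01)

    def test_sine_wave_matches_quadrature_oracle(self):
        curve = mv.SineWave((0, 30, 30), run=120, amplitude=10, periods=2)
        pts = curve.point(np.linspace(0, 1, 600))
        b = voxelized_curve_branch(pts)
        oracle = curve.length() / curve.chord()
        assert mv.branch_tortuosity(b) == pytest.approx(oracle, rel=0.01)

    def test_rotation_invariance(self):
        # same arc drawn in two orientations of its plane
        t_vals = []
        for u, v in [((1, 0, 0), (0, 1, 0)), ((0.6, 0.8, 0), (0, 0, 1))]:
            curve = mv.Arc((60, 60, 40), 30, 0, 2.0, u=u, v=v)
            pts = curve.point(np.linspace(0, 1, 400))
            t_vals.append(mv.branch_tortuosity(voxelized_curve_branch(pts)))
        assert t_vals[0] == pytest.approx(t_vals[1], rel=0.01)

    def test_closed_loop_reports_nan(self):
        th = np.linspace(0, 2 * np.pi, 100)
        pts = np.c_[np.cos(th), np.sin(th), np.zeros_like(th)] * 10
        pts[-1] = pts[0]
        b = Branch(1, 1, pts)
        assert np.isnan(mv.branch_tortuosity(b))


class TestRadius:
    @pytest.mark.parametrize("r", [4, 8, 15, 30])
    def test_circular_tube_recovery(self, r):
        box = (4 * r + 80, 2 * r + 16, 2 * r + 16)
        spec = mv.PhantomSpec(
            box_size=box, spacing=1.0,
            tubes=[mv.TubeSpec(mv.Line((10, box[1] / 2, box[2] / 2),
                                       (box[0] - 10, box[1] / 2, box[2] / 2)), a=float(r))],
        )
        _, mask, _ = mv.render(spec)
        table = mv.compute_morphometry(analyze_mask(mask), mask)
        assert abs(table["radius_um"].iloc[0] - r) <= max(1.0, 0.05 * r)

    def test_elliptical_tube_equivalent_radius(self, elliptical_tube):
        _, _, table = elliptical_tube
        assert table["radius_um"].iloc[0] == pytest.approx(np.sqrt(20 * 10), abs=0.7)

    def test_nr1_vs_nr3_differ_on_tapered_vessel(self):
        # piecewise taper: thin half then thick half along one axis
        spec = mv.PhantomSpec(
            box_size=(140, 60, 60), spacing=1.0,
            tubes=[
                mv.TubeSpec(mv.Line((10, 30, 30), (70, 30, 30)), a=6.0),
                mv.TubeSpec(mv.Line((70, 30, 30), (130, 30, 30)), a=12.0),
            ],
        )
        _, mask, _ = mv.render(spec)
        graph = analyze_mask(mask)
        t1 = mv.compute_morphometry(graph, mask, n_r=1)
        t3 = mv.compute_morphometry(graph, mask, n_r=3)
        assert not np.allclose(t1["radius_um"].mean(), t3["radius_um"].mean(), rtol=0.02)

    def test_branch_outside_mask_fails(self, straight_tube):
        _, _, mask, _ = straight_tube
        far = smooth_branch(Branch(1, 2, np.array([[5.0, 5, 5], [20.0, 5, 5]])))
        with pytest.raises(ValueError, match="empty"):
            mv.branch_radius(far, mask)


class TestEccentricity:
    def test_circle_scores_one(self, tube_table):
        _, _, table = tube_table
        assert table["eccentricity"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_axis_ratio_convention_on_half_ellipse(self, elliptical_tube):
        _, _, table = elliptical_tube
        assert table["eccentricity"].iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_classical_convention(self, elliptical_tube):
        mask, _, _ = elliptical_tube
        graph = analyze_mask(mask)
        ecc = mv.branch_eccentricity(graph.branches[0], mask, convention="classical")
        assert ecc == pytest.approx(np.sqrt(1 - 0.5**2), abs=0.06)

    def test_ensemble_near_in_vitro_axis_ratio(self):
        q = 0.83
        tubes = [
            mv.TubeSpec(mv.Line((15, 25 + 30 * i, 30), (145, 25 + 30 * i, 30)),
                        a=10 / np.sqrt(q), b=10 * np.sqrt(q))
            for i in range(4)
        ]
        spec = mv.PhantomSpec(box_size=(160, 140, 60), spacing=1.0, tubes=tubes)
        _, mask, _ = mv.render(spec)
        table = mv.compute_morphometry(analyze_mask(mask), mask)
        assert abs(table["eccentricity"].mean() - q) < 0.05


class TestLateralArea:
    def test_cylinder_closed_form(self, tube_table):
        _, _, table = tube_table
        L = table["length_um"].iloc[0]
        assert table["lateral_area_um2"].iloc[0] == pytest.approx(2 * np.pi * 8 * L, rel=0.05)

    def test_frustum_formula_for_linear_taper(self):
        b = smooth_branch(Branch(1, 2, np.array([[0, 0, 0], [50, 0, 0], [100.0, 0, 0]])))
        # stations at L/6, L/2, 5L/6 of a 10→20 μm linear taper
        radii = np.array([10 + 10 / 6, 15.0, 20 - 10 / 6])
        assert mv.branch_lateral_area(b, radii) == pytest.approx(np.pi * (10 + 20) * 100, rel=0.05)

    def test_zero_length_branch_is_zero(self):
        b = Branch(1, 1, np.array([[3.0, 3, 3], [3.0, 3, 3]]))
        assert mv.branch_lateral_area(b, np.array([5.0])) == 0.0


class TestSurfaceOverVolume:
    def test_cylinder_in_box_closed_form(self):
        r, L = 10.0, 460.0
        spec = mv.PhantomSpec(
            box_size=(500, 100, 100), spacing=1.0,
            tubes=[mv.TubeSpec(mv.Line((20, 50, 50), (480, 50, 50)), a=r)],
        )
        _, mask, _ = mv.render(spec)
        table = mv.compute_morphometry(analyze_mask(mask), mask)
        sv = mv.surface_over_volume(table, mask)
        closed = (2 * np.pi * r * L * 1e-6) / ((500 * 100 * 100 - np.pi * r**2 * L) * 1e-9)
        assert sv == pytest.approx(closed, rel=0.05)

    def test_box_doubling_scales_exactly(self, tube_table):
        _, mask, table = tube_table
        v_box = float(np.prod(mask.data.shape)) * mask.voxel_volume()
        lumen = float(mask.data.sum()) * mask.voxel_volume()
        sv1 = mv.surface_over_volume(table, mask)
        sv2 = mv.surface_over_volume(table, mask, box_volume_um3=2 * v_box)
        assert sv2 == pytest.approx(sv1 * (v_box - lumen) / (2 * v_box - lumen), rel=1e-12)

    def test_box_smaller_than_lumen_rejected(self, tube_table):
        _, mask, table = tube_table
        with pytest.raises(ValueError):
            mv.surface_over_volume(table, mask, box_volume_um3=1.0)


class TestProjection:
    def test_flat_ellipse_projected_radius_exceeds_3d(self, elliptical_tube):
        mask, _, table3d = elliptical_tube
        table2d = mv.analyze_projection(mask)
        assert table2d["radius_um"].mean() > table3d["radius_um"].mean()
        # 2D sees the horizontal semi-major axis
        assert table2d["radius_um"].mean() == pytest.approx(20.0, rel=0.10)

    def test_circular_tube_2d_3d_agree(self, tube_table):
        _, mask, table3d = tube_table
        table2d = mv.analyze_projection(mask)
        assert table2d["radius_um"].mean() == pytest.approx(table3d["radius_um"].mean(), rel=0.10)

    def test_undulating_tube_projection_shortens(self):
        spec = mv.PhantomSpec(
            box_size=(140, 60, 80), spacing=1.0,
            tubes=[mv.TubeSpec(mv.SineWave((10, 30, 40), run=120, amplitude=12, periods=2), a=5.0)],
        )
        _, mask, _ = mv.render(spec)
        table3d = mv.compute_morphometry(analyze_mask(mask), mask)
        table2d = mv.analyze_projection(mask)
        assert table2d["length_um"].sum() < table3d["length_um"].sum()
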