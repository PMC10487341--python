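import numpy as np
import pytest
from scipy import stats

import microves as mv
from microves.hemodynamics import read_3d1d_inputs
from conftest import dense_flow_oracle, random_network_graph


def single_tube_graph(L=100.0, D=30.0):
    nodes = {
        1: mv.Node(1, np.array([0.0, 0, 0]), "endpoint"),
        2: mv.Node(2, np.array([L, 0, 0]), "endpoint"),
    }
    b = mv.Branch(1, 2, np.array([nodes[1].position, nodes[2].position]),
                  metrics={"length": L, "diameter": D})
    return mv.VesselGraph(nodes, [b])


class TestHydraulicResistance:
    def test_reference_value(self):
        # 128·μ·L/(π·D⁴) with L=100 μm, D=30 μm, μ=1 mPa·s
        expected = 128 * 1e-3 * 100e-6 / (np.pi * (30e-6) ** 4)
        assert mv.hydraulic_resistance(100, 30) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.03e12, rel=0.01)

    def test_quartic_diameter_and_linear_length_scaling(self):
        R = mv.hydraulic_resistance(100, 30)
        assert mv.hydraulic_resistance(100, 60) == pytest.approx(R / 16, rel=1e-12)
        assert mv.hydraulic_resistance(200, 30) == pytest.approx(2 * R, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            mv.hydraulic_resistance(-1, 30)
        with pytest.raises(ValueError):
            mv.hydraulic_resistance(100, 0)


class TestSolveFlow:
    def test_single_tube_poiseuille_closed_form(self):
        sol = mv.solve_flow(mv.FlowProblem(single_tube_graph(), {1: 100.0, 2: 0.0}))
        Q_expected = np.pi * 100 * (30e-6) ** 4 / (128 * 1e-3 * 100e-6)
        assert sol.Q[0] == pytest.approx(Q_expected, rel=1e-12)
        assert sol.v[0] == pytest.approx(2.8125e4, rel=1e-12)  # μm/s

    def test_symmetric_y_splits_flow_equally(self):
        nodes = {
            1: mv.Node(1, np.array([0.0, 0, 0]), "endpoint"),
            2: mv.Node(2, np.array([100.0, 0, 0]), "junction"),
            3: mv.Node(3, np.array([200.0, 50, 0]), "endpoint"),
            4: mv.Node(4, np.array([200.0, -50, 0]), "endpoint"),
        }
        mk = lambda a, b, L, D: mv.Branch(a, b, np.array([nodes[a].position, nodes[b].position]),
                                          metrics={"length": L, "diameter": D})
        g = mv.VesselGraph(nodes, [mk(1, 2, 100, 30), mk(2, 3, 120, 20), mk(2, 4, 120, 20)])
        sol = mv.solve_flow(mv.FlowProblem(g, {1: 100.0, 3: 0.0, 4: 0.0}))
        assert sol.Q[1] == pytest.approx(sol.Q[2], rel=1e-12)
        assert sol.Q[0] == pytest.approx(sol.Q[1] + sol.Q[2], rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dense_oracle_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        g = random_network_graph(rng, n_nodes=rng.integers(5, 9), extra_edges=rng.integers(1, 4))
        bc = {0: 100.0, max(g.nodes): 0.0}
        sol = mv.solve_flow(mv.FlowProblem(g, bc))
        Q_oracle, p_oracle = dense_flow_oracle(g, bc)
        assert np.max(np.abs(sol.Q - Q_oracle)) <= 1e-10 * np.max(np.abs(Q_oracle))
        for nid, p in p_oracle.items():
            assert sol.pressures[nid] == pytest.approx(p, abs=1e-8)

    def test_interior_mass_balance(self):
        rng = np.random.default_rng(11)
        g = random_network_graph(rng, n_nodes=10, extra_edges=4)
        bc = {0: 250.0, 9: 0.0}
        sol = mv.solve_flow(mv.FlowProblem(g, bc))
        max_q = np.max(np.abs(sol.Q))
        for nid in g.nodes:
            if nid in bc:
                continue
            net = sum(
                (q if b.node_b == nid else 0) - (q if b.node_a == nid else 0)
                for q, b in zip(sol.Q, g.branches)
            )
            assert abs(net) <= 1e-9 * max_q

    def test_global_conservation(self):
        rng = np.random.default_rng(4)
        g = random_network_graph(rng, n_nodes=8, extra_edges=3)
        bc = {0: 100.0, 7: 0.0}
        sol = mv.solve_flow(mv.FlowProblem(g, bc))
        inflow = sum(
            (q if b.node_a == 0 else 0) - (q if b.node_b == 0 else 0)
            for q, b in zip(sol.Q, g.branches)
        )
        outflow = sum(
            (q if b.node_b == 7 else 0) - (q if b.node_a == 7 else 0)
            for q, b in zip(sol.Q, g.branches)
        )
        assert inflow == pytest.approx(outflow, rel=1e-9)

    def test_pressure_scaling_is_exact(self):
        rng = np.random.default_rng(5)
        g = random_network_graph(rng, n_nodes=8, extra_edges=3)
        s1 = mv.solve_flow(mv.FlowProblem(g, {0: 100.0, 7: 0.0}))
        s2 = mv.solve_flow(mv.FlowProblem(g, {0: 200.0, 7: 0.0}))
        assert np.array_equal(2 * s1.Q, s2.Q)
        assert np.array_equal(2 * s1.v, s2.v)
        assert np.array_equal(2 * s1.tau, s2.tau)

    def test_dead_end_branch_carries_no_flow(self):
        nodes = {
            1: mv.Node(1, np.array([0.0, 0, 0]), "endpoint"),
            2: mv.Node(2, np.array([100.0, 0, 0]), "junction"),
            3: mv.Node(3, np.array([200.0, 0, 0]), "endpoint"),
            4: mv.Node(4, np.array([100.0, 80, 0]), "endpoint"),  # dead end
        }
        mk = lambda a, b: mv.Branch(a, b, np.array([nodes[a].position, nodes[b].position]),
                                    metrics={"length": 100.0, "diameter": 20.0})
        g = mv.VesselGraph(nodes, [mk(1, 2), mk(2, 3), mk(2, 4)])
        sol = mv.solve_flow(mv.FlowProblem(g, {1: 100.0, 3: 0.0}))
        assert abs(sol.Q[2]) <= 1e-12 * np.max(np.abs(sol.Q))
        assert sol.tau[2] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_boundary_conditions_rejected(self):
        g = single_tube_graph()
        with pytest.raises(ValueError):
            mv.FlowProblem(g, {1: 100.0})
        with pytest.raises(ValueError):
            mv.FlowProblem(g, {1: 100.0, 2: 100.0})


class TestWallShearStress:
    def test_reference_value(self):
        # τ = 4 μ v / r: 500 μm/s in a 15 μm vessel at 1 mPa·s → 133 mPa
        tau = 4 * 1e-3 * 500e-6 / 15e-6
        assert tau == pytest.approx(0.1333, rel=1e-3)
        g = single_tube_graph(L=100, D=30)
        dp = 8 * 1e-3 * 100e-6 * 500e-6 / (15e-6) ** 2
        sol = mv.solve_flow(mv.FlowProblem(g, {1: dp, 2: 0.0}))
        assert sol.v[0] == pytest.approx(500.0, rel=1e-9)
        assert sol.tau[0] == pytest.approx(0.1333, rel=1e-3)
        assert mv.wall_shear_stress(sol)[0] == sol.tau[0]


class TestUncertaintyAnalytic:
    def test_velocity_uncertainty_reference(self):
        dv, _ = mv.uncertainty_analytic(v=500.0, tau=0.1333, r=15.0, dr=1.6)
        assert dv == pytest.approx(106.7, abs=0.5)  # ≈ 107 μm/s

    def test_wss_uncertainty_reference(self):
        _, dwss = mv.uncertainty_analytic(v=500.0, tau=0.1333, r=15.0, dr=1.6)
        assert dwss * 1e3 == pytest.approx(14.2, abs=0.3)  # ≈ 14 mPa

    def test_zero_dr_gives_zero(self):
        assert mv.uncertainty_analytic(500.0, 0.1333, 15.0, 0.0) == (0.0, 0.0)


class TestUncertaintyMonteCarlo:
    def test_single_vessel_linear_statistics(self):
        # WSS = Δp·r/(2l) is linear in r, so mean/SD converge to the
        # closed forms Δp·r̄/(2l) and Δp·σ_r/(2l)
        mc = mv.uncertainty_monte_carlo(15.0, 1.6, n_draws=200_000, seed=7)
        dp = mc["dp_Pa"]
        assert mc["summary"]["tau_Pa"]["mean"] == pytest.approx(dp * 15e-6 / (2 * 100e-6), rel=5e-3)
        assert mc["summary"]["tau_Pa"]["sd"] == pytest.approx(dp * 1.6e-6 / (2 * 100e-6), rel=2e-2)

    def test_distribution_shapes(self):
        mc = mv.uncertainty_monte_carlo(15.0, 1.6, n_draws=100_000, seed=2)
        assert stats.normaltest(mc["tau"]).pvalue > 1e-3
        assert stats.normaltest(mc["v"]).pvalue < 1e-6
        assert stats.normaltest(np.sqrt(mc["v"])).pvalue > 1e-3

    def test_seed_reproducibility(self):
        a = mv.uncertainty_monte_carlo(15.0, 1.6, n_draws=1000, seed=5)
        b = mv.uncertainty_monte_carlo(15.0, 1.6, n_draws=1000, seed=5)
        np.testing.assert_array_equal(a["tau"], b["tau"])

    def test_eight_vessel_network_spreads_comparable_to_single(self):
        # ladder of eight vessels, nominal radii a permutation of {13..17} μm
        radii = np.array([13, 14, 14, 15, 15, 16, 16, 17.0])
        nodes = {i: mv.Node(i, np.array([100.0 * i, 0, 0]), "junction") for i in range(5)}
        nodes.update({i + 5: mv.Node(i + 5, np.array([100.0 * i, 80, 0]), "junction") for i in range(4)})
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 5), (5, 6), (6, 7), (7, 4)]
        branches = [
            mv.Branch(a, b, np.array([nodes[a].position, nodes[b].position]),
                      metrics={"length": 100.0, "diameter": 2 * radii[k]})
            for k, (a, b) in enumerate(edges)
        ]
        g = mv.VesselGraph(nodes, branches)
        dp = 8 * 1e-3 * 100e-6 * 500e-6 / (15e-6) ** 2
        problem = mv.FlowProblem(g, {0: dp, 4: 0.0})
        net = mv.uncertainty_monte_carlo(radii, 1.6, n_draws=150, seed=3, problem=problem, dp=dp)
        single = mv.uncertainty_monte_carlo(15.0, 1.6, n_draws=150, seed=3, dp=dp)
        ratio = net["summary"]["tau_Pa"]["sd"] / single["summary"]["tau_Pa"]["sd"]
        assert 0.2 < ratio < 5.0

    def test_nonpositive_radii_redrawn(self):
        mc = mv.uncertainty_monte_carlo(1.0, 2.0, n_draws=5000, seed=0)
        assert mc["redraws"] > 0
        assert (mc["r"] > 0).all()


class TestExport3d1d:
    def test_single_tube_tables(self, tmp_path):
        g = single_tube_graph()
        npath, spath = mv.export_3d1d_inputs(g, tmp_path / "net", boundary_pressures={1: 100.0})
        nodes, segments = read_3d1d_inputs(tmp_path / "net")
        assert len(nodes) == 2 and len(segments) == 1
        assert nodes[1]["pressure"] == 100.0 and nodes[2]["pressure"] is None
        assert segments[0] == (1, 2, 15.0, 100.0)

    def test_roundtrip_restores_geometry_exactly(self, tmp_path, y_mask):
        g = mv.build_graph(mv.skeletonize(y_mask))
        for b in g.branches:
            b.metrics.update(length=b.polyline_length(), radius_mean=5.0)
        mv.export_3d1d_inputs(g, tmp_path / "y")
        nodes, segments = read_3d1d_inputs(tmp_path / "y")
        assert len(nodes) == len(g.nodes)
        assert len(segments) == len(g.branches)
        assert {(s[0], s[1]) for s in segments} == {(b.node_a, b.node_b) for b in g.branches}
        for s, b in zip(segments, g.branches):
            assert s[3] == b.metrics["length"]
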