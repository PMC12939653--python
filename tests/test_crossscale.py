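import numpy as np
import pytest

from vascsense.graphs import VascularGraph
from vascsense.crossscale import (MesoParams, MicroParams, define_risk_region,
                                  edge_conductance, graph_to_velocity_field,
                                  perfusion_endpoints, propagate_uncertainty,
                                  select_boundary_nodes, simulate_transport,
                                  simulate_viability, solve_graph_flow,
                                  run_cascade, TABLE_DEFAULTS)


def line_graph(points, diameters=None, ids=None):
    g = VascularGraph()
    ids = ids or list(range(len(points)))
    for i, p in zip(ids, points):
        g.add_node(i, p)
    for a, b in zip(ids[:-1], ids[1:]):
        pa = np.asarray(g.g.nodes[a]["pos_mm"])
        pb = np.asarray(g.g.nodes[b]["pos_mm"])
        dia = diameters[ids.index(a)] if diameters else 1.0
        g.add_edge(a, b, np.vstack([pa, pb]), dia)
    g.refresh_kinds()
    return g


class TestConductance:
    def test_direct_value(self):
        assert np.isclose(edge_conductance(1.0, 1.0), 1.0 / (1.0 + 1e-6))

    def test_quartic_diameter_scaling(self):
        assert np.isclose(edge_conductance(2.0, 1.0)
                          / edge_conductance(1.0, 1.0), 16.0)

    def test_decreasing_in_length(self):
        assert edge_conductance(1.0, 2.0) < edge_conductance(1.0, 1.0)

    def test_negative_inputs_fail(self):
        with pytest.raises(ValueError):
            edge_conductance(-1.0, 1.0)


class TestGraphFlow:
    def test_single_edge_ohm(self):
        g = line_graph([(0.0, 0.0), (10.0, 0.0)])
        sol = solve_graph_flow(g, [0], [1])
        ge = edge_conductance(1.0, 10.0)
        assert np.isclose(list(sol.flows.values())[0], ge)

    def test_parallel_edges_split_by_conductance(self):
        g = VascularGraph()
        g.add_node(0, (0.0, 0.0))
        g.add_node(1, (10.0, 0.0))
        g.add_edge(0, 1, [(0, 0), (10, 0)], 1.0)       # g1
        g.add_edge(0, 1, [(0, 0), (5, 3), (10, 0)], 1.5)  # thicker: g2
        sol = solve_graph_flow(g, [0], [1])
        flows = {k: v for k, v in sol.flows.items()}
        (k1, f1), (k2, f2) = sorted(flows.items())
        d1 = g.g.get_edge_data(0, 1, k1[2])
        d2 = g.g.get_edge_data(0, 1, k2[2])
        g1 = edge_conductance(d1["diameter_mm"], d1["length_mm"])
        g2 = edge_conductance(d2["diameter_mm"], d2["length_mm"])
        assert np.isclose(f1 / f2, g1 / g2)
        # direct 2x2 parallel-circuit solve: total flow = (g1+g2) * dp
        assert np.isclose(f1 + f2, g1 + g2)

    def test_kirchhoff_conservation(self, small_phantom):
        _, truth = small_phantom
        inlets, outlets = select_boundary_nodes(truth)
        sol = solve_graph_flow(truth, inlets, outlets)
        assert sol.node_imbalance(truth) < 1e-8 * sol.total_inflow()

    def test_boundary_selection_without_terminals(self):
        # a pure ring has no degree-1 nodes; the lowest-degree fallback
        # still yields a usable inlet/outlet pair
        pos = {0: (0.0, 0.0), 1: (10.0, 0.0), 2: (5.0, 8.0)}
        g = VascularGraph()
        for i, p in pos.items():
            g.add_node(i, p)
        g.add_edge(0, 1, [pos[0], pos[1]], 1.0)
        g.add_edge(1, 2, [pos[1], pos[2]], 1.0)
        g.add_edge(2, 0, [pos[2], pos[0]], 1.0)
        g.refresh_kinds()
        inlets, outlets = select_boundary_nodes(g)
        assert inlets and outlets
        sol = solve_graph_flow(g, inlets, outlets)
        assert sol.total_inflow() > 0

    def test_disconnected_inlet_outlet_fails(self):
        g = VascularGraph()
        for i, p in enumerate([(0, 0), (10, 0), (20, 0), (30, 0)]):
            g.add_node(i, p)
        g.add_edge(0, 1, [(0, 0), (10, 0)], 1.0)
        g.add_edge(2, 3, [(20, 0), (30, 0)], 1.0)
        with pytest.raises(ValueError, match="components"):
            solve_graph_flow(g, [0], [3])


class TestVelocityField:
    def test_zero_flow_zero_field(self):
        g = line_graph([(0.0, 0.0), (10.0, 0.0)])
        sol = solve_graph_flow(g, [0], [1])
        zeroed = {k: 0.0 for k in sol.flows}
        sol.flows = zeroed
        u = graph_to_velocity_field(sol, g, (32, 32), 0.5)
        assert np.all(u == 0)

    def test_straight_edge_axial_velocity(self):
        # horizontal edge: velocity along axis 1, no transverse component
        g = line_graph([(2.0, 1.0), (2.0, 14.0)])
        sol = solve_graph_flow(g, [0], [1])
        u = graph_to_velocity_field(sol, g, (32, 32), 0.5,
                                    smoothing_sigma_mm=0.0)
        centerline = u[:, 4, 4:26]
        axial = np.abs(centerline[1]).max()
        transverse = np.abs(centerline[0]).max()
        assert axial > 0
        assert transverse < 1e-6 * axial

    def test_linear_in_flows(self):
        g = line_graph([(2.0, 1.0), (6.0, 10.0)])
        sol = solve_graph_flow(g, [0], [1])
        u1 = graph_to_velocity_field(sol, g, (32, 32), 0.5)
        sol.flows = {k: 3.0 * v for k, v in sol.flows.items()}
        u3 = graph_to_velocity_field(sol, g, (32, 32), 0.5)
        assert np.allclose(u3, 3.0 * u1, atol=1e-12)


class TestTransport:
    def test_no_dynamics_constant(self):
        p = MesoParams(diffusivity=0.0, decay_rate=0.0, dt=0.1, horizon=5.0,
                       spacing_mm=1.0)
        c0 = np.random.default_rng(0).random((16, 16))
        _, series = simulate_transport(np.zeros((2, 16, 16)), p, c0=c0)
        assert np.array_equal(series[-1], c0)

    def test_decay_matches_closed_form(self):
        """With only clearance active, total mass decays as exp(-lambda T)
        (fixed defaults lambda=0.012/s, T=60 s)."""
        p = MesoParams(diffusivity=0.0, dt=TABLE_DEFAULTS["dt_s"],
                       decay_rate=TABLE_DEFAULTS["decay_per_s"],
                       horizon=TABLE_DEFAULTS["horizon_s"], spacing_mm=1.0)
        c0 = np.random.default_rng(1).random((16, 16))
        _, series = simulate_transport(np.zeros((2, 16, 16)), p, c0=c0)
        ratio = series[-1].sum() / series[0].sum()
        assert abs(ratio - np.exp(-0.72)) <= 0.01 * np.exp(-0.72)

    def test_pure_diffusion_conserves_mass(self):
        p = MesoParams(diffusivity=0.80, decay_rate=0.0, dt=0.1,
                       horizon=20.0, spacing_mm=1.0)
        c0 = np.zeros((24, 24))
        c0[12, 12] = 1.0
        _, series = simulate_transport(np.zeros((2, 24, 24)), p, c0=c0)
        assert abs(series[-1].sum() - 1.0) < 1e-10
        peaks = [s.max() for s in series]
        assert np.all(np.diff(peaks) <= 1e-12)

    def test_cfl_violation_names_admissible_step(self):
        p = MesoParams(diffusivity=0.80, dt=0.2, spacing_mm=0.5)
        with pytest.raises(ValueError, match="dt"):
            simulate_transport(np.zeros((2, 8, 8)), p)


class TestPerfusionEndpoints:
    def test_triangular_pulse_time_to_peak(self):
        times = np.arange(0.0, 11.0)
        curve = np.concatenate([np.linspace(0, 1, 6),
                                np.linspace(0.8, 0, 5)])
        series = curve[:, None, None] * np.ones((1, 1))
        peak, ttp, auc = perfusion_endpoints(times, series)
        assert ttp[0, 0] == 5.0

    def test_constant_curve_auc(self):
        times = np.linspace(0, 60, 61)
        series = np.ones((61, 2, 2))
        _, _, auc = perfusion_endpoints(times, series)
        assert np.allclose(auc, 60.0)

    def test_piecewise_linear_trapezoid(self):
        times = np.array([0.0, 2.0, 5.0, 6.0])
        vals = np.array([0.0, 4.0, 4.0, 0.0])
        series = vals[:, None, None] * np.ones((1, 1))
        _, _, auc = perfusion_endpoints(times, series)
        # hand trapezoid: 0.5*2*4 + 3*4 + 0.5*1*4
        assert np.isclose(auc[0, 0], 4 + 12 + 2)

    def test_needs_two_time_points(self):
        with pytest.raises(ValueError):
            perfusion_endpoints(np.array([0.0]), np.ones((1, 2, 2)))


class TestViability:
    def test_fixed_point_matches_closed_form(self):
        p = MicroParams()
        T = 5.0 / p.gamma
        _, e, pmap = simulate_viability(np.ones((3, 3)), p, T=T, dt=0.1,
                                        demand=1.0)
        target = (p.alpha - p.beta) / p.gamma
        assert abs(e[-1][0, 0] - target) <= 0.01 * target
        expect_p = 1.0 / (1.0 + np.exp(-p.logistic_slope
                                       * (e[-1][0, 0] - p.theta)))
        assert np.isclose(pmap[0, 0], expect_p)

    def test_logistic_midpoint(self):
        p = MicroParams()
        # supply chosen so that E stays 0 = theta shift: test sigma directly
        _, e, pmap = simulate_viability(np.full((2, 2), p.theta * p.gamma
                                                / p.alpha),
                                        p, T=500.0, dt=0.1, demand=0.0)
        assert np.allclose(e[-1], p.theta, atol=1e-3)
        assert np.allclose(pmap, 0.5, atol=0.01)

    def test_probability_range(self):
        p = MicroParams()
        rng = np.random.default_rng(2)
        # moderate energies keep the logistic away from float saturation
        _, _, pmap = simulate_viability(rng.uniform(0.5, 1.2, (8, 8)), p,
                                        T=8.0, dt=0.1)
        assert np.all(pmap > 0) and np.all(pmap < 1)

    def test_unstable_step_fails(self):
        with pytest.raises(ValueError):
            simulate_viability(np.ones((2, 2)), MicroParams(), T=10.0,
                               dt=40.0)


class TestRiskRegion:
    def test_identical_endpoints_empty_mask(self):
        auc = np.random.default_rng(3).uniform(0.1, 2.0, (16, 16))
        mask = define_risk_region({"auc": auc}, {"auc": auc}, 0.6)
        assert not mask.any()

    def test_deficit_region_detected_and_monotone(self):
        rng = np.random.default_rng(4)
        healthy = rng.uniform(1.0, 2.0, (16, 16))
        lesioned = healthy.copy()
        lesioned[4:10, 4:10] *= 0.3
        m06 = define_risk_region({"auc": healthy}, {"auc": lesioned}, 0.6)
        m09 = define_risk_region({"auc": healthy}, {"auc": lesioned}, 0.99)
        assert m06[4:10, 4:10].all()
        assert not m06[12:, 12:].any()
        assert (m06 <= m09).all()  # monotone nesting

    def test_occlusion_creates_downstream_risk(self):
        # Y-graph: inlet trunk feeding two branches; severing one branch's
        # edge starves its territory
        g = VascularGraph()
        pts = {0: (8.0, 1.0), 1: (8.0, 8.0), 2: (3.0, 15.0), 3: (13.0, 15.0)}
        for i, p in pts.items():
            g.add_node(i, p)
        g.add_edge(0, 1, [pts[0], pts[1]], 1.5)
        g.add_edge(1, 2, [pts[1], pts[2]], 1.0)
        g.add_edge(1, 3, [pts[1], pts[3]], 1.0)
        g.refresh_kinds()

        def endpoints(graph):
            sol = solve_graph_flow(graph, [0],
                                   [n for n in graph.g.nodes
                                    if graph.g.degree(n) == 1 and n != 0])
            u = graph_to_velocity_field(sol, graph, (16, 16), 1.0)
            u = u * (3.0 / np.abs(u).max())  # advection-dominated regime
            src = np.zeros((16, 16))
            src[8, 1] = 1.0
            p = MesoParams(spacing_mm=1.0, horizon=30.0, diffusivity=0.2)
            times, series = simulate_transport(u, p, source_mask=src)
            return perfusion_endpoints(times, series)[2]

        healthy = endpoints(g)
        lesioned_g = g.copy()
        lesioned_g.g.remove_edge(1, 3)
        lesioned_g.g.remove_node(3)
        lesioned = endpoints(lesioned_g)
        mask = define_risk_region({"auc": healthy}, {"auc": lesioned}, 0.6)
        assert mask.any()
        # the starved territory is around the removed branch's distal end
        assert mask[10:, 10:].any()


class TestUncertaintyPropagation:
    def test_identical_realizations_zero_variance(self, small_phantom,
                                                  topo_cfg):
        img, _ = small_phantom
        report = propagate_uncertainty(
            [img, img], topo_cfg, MesoParams(), MicroParams(),
            risk_mask=np.ones((48, 48), bool))
        assert all(v == 0 for v in report.U_meso.values())
        assert report.U_micro_mean == 0

    def test_micro_mean_recomputed_from_map(self, small_phantom, topo_cfg,
                                            noisy_kspace):
        from vascsense.recon import ReconConfig, stochastic_realizations
        from vascsense.acquisition import poisson_disc_mask
        img, _ = small_phantom
        mask = poisson_disc_mask((96, 96), 0.5, 0.8, 0.08, seed=3)
        ens = stochastic_realizations(noisy_kspace.restrict(mask),
                                      ReconConfig(lambda_reg=5e-3,
                                                  max_iterations=25),
                                      3, 1.0, seed=8)
        risk = np.zeros((48, 48), bool)
        risk[10:30, 10:30] = True
        report = propagate_uncertainty(list(ens), topo_cfg, MesoParams(),
                                       MicroParams(), risk_mask=risk)
        assert np.isclose(report.U_micro_mean,
                          report.U_micro[report.risk_mask].mean())
        assert report.U_micro.min() >= 0
        assert report.K == 3

    def test_requires_two_realizations(self, small_phantom, topo_cfg):
        img, _ = small_phantom
        with pytest.raises(ValueError):
            propagate_uncertainty([img], topo_cfg, MesoParams(),
                                  MicroParams(),
                                  risk_mask=np.ones((48, 48), bool))

    def test_empty_risk_region_fails(self, small_phantom, topo_cfg):
        img, _ = small_phantom
        with pytest.raises(ValueError, match="risk"):
            propagate_uncertainty([img, img], topo_cfg, MesoParams(),
                                  MicroParams(),
                                  risk_mask=np.zeros((48, 48), bool))


class TestVarianceDecomposition:
    def test_uncertainty_grows_with_perturbation_scale(self, small_phantom,
                                                       noisy_kspace,
                                                       topo_cfg):
        """U_meso and the risk-region micro variance are non-decreasing in
        the reconstruction ensemble's perturbation scale."""
        from vascsense.acquisition import poisson_disc_mask
        from vascsense.recon import ReconConfig, stochastic_realizations
        mask = poisson_disc_mask((96, 96), 0.6, 1.0, 0.08, seed=4)
        y = noisy_kspace.restrict(mask)
        cfg = ReconConfig(lambda_reg=5e-3, max_iterations=30)
        risk = np.zeros((48, 48), bool)
        risk[10:38, 10:38] = True
        auc_var, micro = [], []
        for scale in (0.5, 1.0, 2.0):
            ens = stochastic_realizations(y, cfg, 3, scale, seed=9,
                                          jitter_lambda=False)
            rep = propagate_uncertainty(list(ens), topo_cfg, MesoParams(),
                                        MicroParams(), risk_mask=risk)
            auc_var.append(rep.U_meso["auc"])
            micro.append(rep.U_micro_mean)
        assert auc_var[0] <= auc_var[1] <= auc_var[2]
        assert micro[0] <= micro[1] <= micro[2]


class TestCrossScaleCoupling:
    def test_removing_collateral_never_increases_total_auc(self):
        """Dropping a collateral chord removes flow redundancy: the perfusion
        AUC summed over the tissue domain must not increase."""
        from vascsense.phantom import PhantomSpec, generate_vascular_phantom
        for seed in range(4):
            spec = PhantomSpec(grid_shape=(96, 96), n_main_branches=5,
                               n_collateral_loops=2, seed=seed)
            _, truth = generate_vascular_phantom(spec)

            def total_auc(graph):
                inlets, outlets = select_boundary_nodes(graph)
                sol = solve_graph_flow(graph, inlets, outlets)
                u = graph_to_velocity_field(sol, graph, (48, 48), 1.0)
                scale = np.abs(u).max()
                p = MesoParams(horizon=30.0)
                cap = 0.5 * p.spacing_mm / p.dt
                if scale > cap:
                    u = u * cap / scale
                src = np.zeros((48, 48))
                pos = graph.node_positions()
                c = np.clip(np.round(pos[inlets[0]] / 1.0).astype(int), 0, 47)
                src[tuple(c)] = 1.0
                times, series = simulate_transport(u, p, source_mask=src)
                return perfusion_endpoints(times, series)[2].sum()

            base = total_auc(truth)
            # remove one chord edge participating in a cycle
            lesioned = truth.copy()
            import networkx as nx
            cycle = nx.cycle_basis(nx.Graph(lesioned.g))[0]
            u0, v0 = cycle[0], cycle[1]
            key = next(iter(lesioned.g.get_edge_data(u0, v0)))
            lesioned.g.remove_edge(u0, v0, key)
            assert total_auc(lesioned) <= base * (1 + 1e-9)

    def test_larger_topology_error_larger_outcome_error(self, small_phantom,
                                                        noisy_kspace,
                                                        topo_cfg):
        """Error cascade: reconstructions with larger Betti deviation show a
        larger infarct-proxy discrepancy (positive rank correlation)."""
        from scipy.stats import spearmanr
        from vascsense.acquisition import poisson_disc_mask
        from vascsense.recon import ReconConfig, stochastic_realizations
        from vascsense.topology import betti_deviation, diagrams_from_image
        img, truth = small_phantom
        ref = run_cascade(img, topo_cfg, MesoParams(), MicroParams())
        ref_p = ref["p_survival"]
        dbs, errs = [], []
        for sd, accel in enumerate((0.3, 0.5, 0.65, 0.75, 0.8, 0.85)):
            mask = poisson_disc_mask((96, 96), accel, 0.8, 0.08, seed=sd + 1)
            ens = stochastic_realizations(
                noisy_kspace.restrict(mask),
                ReconConfig(lambda_reg=8e-3, max_iterations=60), 3, 1.0,
                seed=11 + sd)
            for member in ens:
                try:
                    res = run_cascade(member, topo_cfg, MesoParams(),
                                      MicroParams())
                except ValueError:
                    continue
                _, graph = diagrams_from_image(member, topo_cfg)
                dbs.append(betti_deviation(graph, truth))
                errs.append(np.abs(res["p_survival"] - ref_p).mean())
        rho, _ = spearmanr(dbs, errs)
        assert rho > 0
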