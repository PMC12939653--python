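import itertools

import numpy as np
import pytest

from conftest import straight_tube_image
from vascsense.core import ImageVolume
from vascsense.graphs import VascularGraph
from vascsense.topology import (ESSENTIAL_DEATH, PersistenceDiagram,
                                TopologyConfig, betti_deviation,
                                branch_completeness, extract_graph,
                                macro_uncertainty, persistence_stability,
                                prune_graph, superlevel_persistence,
                                threshold_sensitivity, topology_uncertainty,
                                vesselness, wasserstein_distance,
                                vesselness_per_scale)


def graph_from_edges(edges, positions=None):
    """Build a VascularGraph from (u, v, confidence[, length]) tuples."""
    g = VascularGraph()
    nodes = sorted({n for e in edges for n in e[:2]})
    for n in nodes:
        pos = positions[n] if positions else (float(n), 0.0)
        g.add_node(n, pos)
    for e in edges:
        u, v, conf = e[:3]
        length = e[3] if len(e) > 3 else 5.0
        pu = np.asarray(positions[u] if positions else (float(u), 0.0))
        pv = np.asarray(positions[v] if positions else (float(v), 0.0))
        if u == v:
            poly = np.vstack([pu, pu + (length / 2, 0), pu + (length / 2, 1),
                              pu])
        else:
            poly = np.vstack([pu, pv])
            if np.allclose(pu, pv):
                poly = np.vstack([pu, pu + (length, 0)])
        g.add_edge(u, v, poly, 1.0, conf)
    g.refresh_kinds()
    return g


# ---------------------------------------------------------------------------
# brute-force persistence oracle: recount components / cycle rank at every
# distinct confidence threshold of the decreasing filtration
# ---------------------------------------------------------------------------

def brute_force_diagrams(g: VascularGraph):
    import networkx as nx

    edges = sorted(((d["confidence"], d["index"], u, v)
                    for u, v, d in g.g.edges(data=True)),
                   key=lambda t: (-t[0], t[1]))
    if not edges:
        return (PersistenceDiagram(0, [], []), PersistenceDiagram(1, [], []))
    thresholds = sorted({c for c, *_ in edges}, reverse=True)
    # dim-1: cycle-rank increments; each increment is an essential class
    d1_births = []
    prev_rank = 0
    sub = nx.MultiGraph()
    for thr in thresholds:
        for c, idx, u, v in edges:
            if c >= thr and not sub.has_edge(u, v, key=(idx,)):
                sub.add_edge(u, v, key=(idx,))
        rank = (sub.number_of_edges() - sub.number_of_nodes()
                + nx.number_connected_components(sub))
        d1_births.extend([thr] * (rank - prev_rank))
        prev_rank = rank
    # dim-0 by explicit component tracking with the elder rule
    comp_birth = {}  # frozenset of nodes -> birth
    pairs = []
    sub = nx.MultiGraph()
    comps = []
    births = []
    for thr in thresholds:
        for c, idx, u, v in edges:
            if c == thr:
                sub.add_edge(u, v, key=(idx,))
        new_comps = [frozenset(cc) for cc in nx.connected_components(sub)]
        survivors = []
        for nc in new_comps:
            merged = [(b, oc) for b, oc in zip(births, comps) if oc <= nc]
            if not merged:
                survivors.append((thr, nc))
            else:
                oldest = max(b for b, _ in merged)
                for b, _ in merged:
                    if b != oldest:
                        pairs.append((b, thr))
                # several components may share the oldest birth; all but one
                # of the ties dies too
                tie = sorted((b for b, _ in merged), reverse=True)
                for b in tie[1:]:
                    if b == oldest:
                        pairs.append((b, thr))
                survivors.append((oldest, nc))
        births = [b for b, _ in survivors]
        comps = [c for _, c in survivors]
    d0_b = [b for b, _ in pairs]
    d0_d = [d for _, d in pairs]
    d0_b += births
    d0_d += [ESSENTIAL_DEATH] * len(births)
    return (PersistenceDiagram(0, d0_b, d0_d),
            PersistenceDiagram(1, d1_births,
                               [ESSENTIAL_DEATH] * len(d1_births)))


def diagrams_equal(a, b):
    return (np.allclose(np.sort(a.births), np.sort(b.births))
            and np.allclose(np.sort(a.deaths), np.sort(b.deaths)))


# ---------------------------------------------------------------------------
# exhaustive Wasserstein oracle for small diagrams
# ---------------------------------------------------------------------------

def wasserstein_bruteforce(d1, d2, q=2.0):
    a, b = d1.finite_pairs, d2.finite_pairs
    n, m = len(a), len(b)

    def diag_cost(p):
        return (p[0] - p[1]) / 2.0

    best = np.inf
    idx_b = list(range(m))
    for k in range(0, min(n, m) + 1):
        for subset_a in itertools.combinations(range(n), k):
            for subset_b in itertools.permutations(idx_b, k):
                cost = 0.0
                for i, j in zip(subset_a, subset_b):
                    cost += np.max(np.abs(a[i] - b[j])) ** q
                for i in range(n):
                    if i not in subset_a:
                        cost += diag_cost(a[i]) ** q
                for j in range(m):
                    if j not in subset_b:
                        cost += diag_cost(b[j]) ** q
                best = min(best, cost)
    ea, eb = d1.essential_births, d2.essential_births
    kk = min(len(ea), len(eb))
    ess = sum(abs(ea[i] - eb[i]) ** q for i in range(kk))
    ess += sum(abs(x) ** q for x in ea[kk:]) + sum(abs(x) ** q for x in eb[kk:])
    return (best + ess) ** (1.0 / q)


def random_diagram(rng, n_pts, n_ess=0, dim=0):
    b = rng.uniform(0.3, 1.0, size=n_pts)
    d = b * rng.uniform(0.0, 1.0, size=n_pts)
    births = np.concatenate([b, rng.uniform(0.3, 1.0, size=n_ess)])
    deaths = np.concatenate([d, np.full(n_ess, ESSENTIAL_DEATH)])
    return PersistenceDiagram(dim, births, deaths)


class TestVesselness:
    def test_constant_image_zero_response(self):
        img = ImageVolume(np.full((48, 48), 3.0), 0.5)
        v = vesselness(img)
        assert np.all(v.values == 0)

    def test_tube_response_dominates_background(self):
        img = straight_tube_image()
        v = vesselness(img).values
        center = v[32, 10:54]
        bg = np.median(v[v < 0.5 * v.max()])
        assert center.min() > 5 * max(bg, 1e-12)

    def test_scale_selection_tracks_radius(self):
        # tube of radius ~0.9 mm: strongest single-scale response within one
        # scale step of that radius
        scales = (0.4, 0.6, 0.9, 1.35, 2.0)
        img = straight_tube_image(sigma=0.9 / 0.5 / 1.177)  # radius 0.9 mm
        per = vesselness_per_scale(img, scales)
        responses = per[:, 32, 32]
        best = int(np.argmax(responses))
        target = scales.index(0.9)
        assert abs(best - target) <= 1

    def test_requires_scales(self):
        with pytest.raises(ValueError):
            vesselness(straight_tube_image(), scales_mm=())


class TestExtractGraph:
    def test_straight_segment(self):
        img = straight_tube_image()
        g = extract_graph(vesselness(img), 0.12)
        kinds = [d["kind"] for _, d in g.g.nodes(data=True)]
        assert g.n_edges == 1
        assert sorted(kinds) == ["terminal", "terminal"]

    def test_y_junction(self):
        arr = np.ones((64, 64))
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        for (r0, c0, r1, c1) in [(32, 4, 32, 32), (32, 32, 12, 58),
                                 (32, 32, 52, 58)]:
            n = 60
            t = np.linspace(0, 1, n)[:, None]
            pts = (1 - t) * np.array([[r0, c0]]) + t * np.array([[r1, c1]])
            for p in pts:
                d2 = (yy - p[0]) ** 2 + (xx - p[1]) ** 2
                arr = np.maximum(arr, 6.0 * np.exp(-d2 / (2 * 1.2**2)))
        g = extract_graph(vesselness(ImageVolume(arr, 0.5)), 0.12)
        g = prune_graph(g)
        kinds = sorted(d["kind"] for _, d in g.g.nodes(data=True))
        assert g.n_edges == 3
        assert kinds == ["bifurcation", "terminal", "terminal", "terminal"]

    def test_ring_has_cycle_rank_one(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        r = np.sqrt((yy - 32) ** 2 + (xx - 32) ** 2)
        arr = 1.0 + 5.0 * np.exp(-((r - 18) ** 2) / (2 * 1.2**2))
        g = extract_graph(vesselness(ImageVolume(arr, 0.5)), 0.12)
        assert g.n_edges - g.n_nodes + g.betti0() == 1

    def test_empty_segmentation_gives_empty_graph(self):
        img = ImageVolume(np.full((48, 48), 2.0), 0.5)
        g = extract_graph(vesselness(img), 0.5)
        assert g.n_edges == 0 and g.n_nodes == 0

    def test_threshold_domain(self):
        img = straight_tube_image()
        with pytest.raises(ValueError):
            extract_graph(vesselness(img), 0.0)


class TestThinSlab3D:
    def test_3d_pipeline_runs_end_to_end(self):
        """Thin-slab phantoms exercise the 3-D skeletonization path."""
        from vascsense.phantom import PhantomSpec, generate_vascular_phantom
        spec = PhantomSpec(grid_shape=(64, 64, 12), n_main_branches=4,
                           n_collateral_loops=1, seed=2)
        img, truth = generate_vascular_phantom(spec)
        assert truth.betti1() == 1
        g = prune_graph(extract_graph(
            vesselness(img, scales_mm=(0.4, 0.6, 0.9)), 0.12))
        assert g.n_edges >= 1
        assert g.betti0() == 1  # main tree recovered in one piece
        assert g.total_length_mm() > 10.0


class TestPruneGraph:
    def make_trunk_with_spur(self, spur_len):
        g = VascularGraph()
        g.add_node(0, (0.0, 0.0))
        g.add_node(1, (20.0, 0.0))
        g.add_node(2, (40.0, 0.0))
        g.add_node(3, (20.0, spur_len))
        g.add_edge(0, 1, [(0, 0), (20, 0)], 1.0, 0.9)
        g.add_edge(1, 2, [(20, 0), (40, 0)], 1.0, 0.9)
        g.add_edge(1, 3, [(20, 0), (20, spur_len)], 0.5, 0.4)
        g.refresh_kinds()
        return g

    def test_short_spur_removed(self):
        g = prune_graph(self.make_trunk_with_spur(1.5))
        # spur gone; the two trunk edges merge across the pass-through node
        assert g.n_edges == 1
        assert abs(g.total_length_mm() - 40.0) < 1e-9

    def test_long_spur_retained(self):
        g = prune_graph(self.make_trunk_with_spur(4.0))
        assert g.n_edges == 3

    def test_idempotent(self):
        once = prune_graph(self.make_trunk_with_spur(1.5))
        twice = prune_graph(once)
        assert once.n_edges == twice.n_edges
        assert once.n_nodes == twice.n_nodes
        assert np.isclose(once.total_length_mm(), twice.total_length_mm())

    def test_cycle_edges_never_removed(self):
        # a short triangle (total 3 mm) is a cycle: must survive even though
        # each edge is below the pruning length
        pos = {0: (0.0, 0.0), 1: (1.0, 0.0), 2: (0.5, 0.9)}
        g = graph_from_edges([(0, 1, 0.9), (1, 2, 0.8), (0, 2, 0.7)], pos)
        out = prune_graph(g, min_length_mm=2.5)
        assert out.betti1() == 1

    def test_short_acyclic_component_removed(self):
        pos = {0: (0.0, 0.0), 1: (1.0, 0.0), 2: (30.0, 0.0), 3: (60.0, 0.0)}
        g = graph_from_edges([(0, 1, 0.9), (2, 3, 0.9)], pos)
        out = prune_graph(g, min_length_mm=2.5)
        assert out.betti0() == 1  # the 1 mm component is gone


class TestSuperlevelPersistence:
    def test_single_edge(self):
        g = graph_from_edges([(0, 1, 0.9)])
        d0, d1 = superlevel_persistence(g)
        assert d0.n_points == 1
        assert d0.births[0] == 0.9 and d0.deaths[0] == ESSENTIAL_DEATH
        assert d1.n_points == 0

    def test_two_edges_with_weak_bridge(self):
        g = graph_from_edges([(0, 1, 0.9), (2, 3, 0.8), (1, 2, 0.4)])
        d0, d1 = superlevel_persistence(g)
        fin = d0.finite_pairs
        assert len(fin) == 1
        assert tuple(fin[0]) == (0.8, 0.4)
        assert list(d0.essential_births) == [0.9]
        assert d1.n_points == 0

    def test_triangle_cycle_born_at_minimum(self):
        g = graph_from_edges([(0, 1, 0.9), (1, 2, 0.8), (0, 2, 0.5)])
        d0, d1 = superlevel_persistence(g)
        assert d1.n_points == 1
        assert d1.births[0] == 0.5
        assert d1.deaths[0] == ESSENTIAL_DEATH

    def test_matches_brute_force_on_random_small_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(40):
            n_nodes = int(rng.integers(2, 8))
            n_edges = int(rng.integers(1, 13))
            edges = []
            for _ in range(n_edges):
                u, v = rng.integers(0, n_nodes, size=2)
                if u == v:
                    continue
                conf = float(np.round(rng.uniform(0.1, 1.0), 2))
                edges.append((int(u), int(v), conf))
            if not edges:
                continue
            g = graph_from_edges(edges)
            mine = superlevel_persistence(g)
            oracle = brute_force_diagrams(g)
            assert diagrams_equal(mine[0], oracle[0]), (trial, edges)
            assert diagrams_equal(mine[1], oracle[1]), (trial, edges)

    def test_confidence_perturbation_moves_points_by_at_most_epsilon(self):
        rng = np.random.default_rng(3)
        edges = [(0, 1, 0.9), (1, 2, 0.7), (2, 3, 0.5), (1, 3, 0.45),
                 (3, 4, 0.6)]
        g = graph_from_edges(edges)
        d0a, d1a = superlevel_persistence(g)
        eps = 0.02
        edges_p = [(u, v, float(np.clip(c + rng.uniform(-eps, eps), 0, 1)))
                   for u, v, c in edges]
        gp = graph_from_edges(edges_p)
        d0b, d1b = superlevel_persistence(gp)
        for a, b in ((d0a, d0b), (d1a, d1b)):
            assert np.all(np.abs(np.sort(a.births) - np.sort(b.births))
                          <= eps + 1e-12)
            fa, fb = np.sort(a.finite_pairs[:, 1]), np.sort(b.finite_pairs[:, 1])
            assert np.all(np.abs(fa - fb) <= eps + 1e-12)


class TestWasserstein:
    def test_identical_diagrams_zero(self, rng):
        d = random_diagram(rng, 4, 1)
        assert wasserstein_distance(d, d) == 0.0

    def test_single_point_versus_empty(self):
        d1 = PersistenceDiagram(0, [1.0], [0.0])
        d2 = PersistenceDiagram(0, [], [])
        assert np.isclose(wasserstein_distance(d1, d2, q=2), 0.5)
        assert np.isclose(wasserstein_distance(d2, d1, q=2), 0.5)

    def test_dimension_mismatch_fails(self):
        d0 = PersistenceDiagram(0, [1.0], [0.5])
        d1 = PersistenceDiagram(1, [1.0], [0.5])
        with pytest.raises(ValueError):
            wasserstein_distance(d0, d1)

    @pytest.mark.parametrize("seed", range(8))
    def test_two_point_diagrams_match_exhaustive_matching(self, seed):
        rng = np.random.default_rng(seed)
        d1 = random_diagram(rng, 2)
        d2 = random_diagram(rng, 2)
        mine = wasserstein_distance(d1, d2, q=2)
        oracle = wasserstein_bruteforce(d1, d2, q=2)
        assert np.isclose(mine, oracle, atol=1e-10)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ds = [random_diagram(rng, int(rng.integers(0, 4)),
                                 int(rng.integers(0, 2))) for _ in range(3)]
            a, b, c = ds
            dab = wasserstein_distance(a, b)
            dba = wasserstein_distance(b, a)
            dac = wasserstein_distance(a, c)
            dbc = wasserstein_distance(b, c)
            assert dab >= 0
            assert np.isclose(dab, dba, atol=1e-10)
            assert dac <= dab + dbc + 1e-10
        # zero iff equal
        d = random_diagram(np.random.default_rng(1), 3, 1)
        d2 = PersistenceDiagram(d.dim, d.births + 0.01, d.deaths)
        assert wasserstein_distance(d, d2) > 0


class TestTopologyMetrics:
    def test_betti_deviation_cases(self):
        ref = graph_from_edges([(0, 1, 0.9), (1, 2, 0.9), (2, 0, 0.9),
                                (2, 3, 0.9), (3, 4, 0.9), (4, 2, 0.9)])
        assert ref.betti0() == 1 and ref.betti1() == 2
        assert betti_deviation(ref, ref) == 0.0
        g = graph_from_edges([(0, 1, 0.9), (1, 2, 0.9), (2, 0, 0.9),
                              (5, 6, 0.9)])  # b0=2, b1=1
        assert np.isclose(betti_deviation(g, ref), (1 + 1) / 3)
        empty = VascularGraph()
        ref10 = graph_from_edges([(0, 1, 0.9)])
        assert betti_deviation(empty, ref10) == 1.0

    def test_branch_completeness_cases(self):
        pos = {i: (10.0 * i, 0.0) for i in range(5)}
        ref = graph_from_edges(
            [(0, 1, 0.9), (1, 2, 0.9), (2, 3, 0.9), (3, 4, 0.9)], pos)
        assert branch_completeness(ref, ref) == 1.0
        assert branch_completeness(VascularGraph(), ref) == 0.0
        g = graph_from_edges([(0, 1, 0.9), (1, 2, 0.9), (2, 3, 0.9)], pos)
        assert branch_completeness(g, ref) == 0.75
        with pytest.raises(ValueError):
            branch_completeness(g, VascularGraph())

    def test_persistence_stability_arithmetic(self):
        ref = graph_from_edges([(0, 1, 0.9)])
        dref = superlevel_persistence(ref)
        # identical realizations -> stability 1
        assert persistence_stability([dref, dref], dref) == 1.0
        # U = 0.05, normalizer 0.5 -> 0.9
        shifted = (PersistenceDiagram(0, [0.85], [ESSENTIAL_DEATH]),
                   PersistenceDiagram(1, [], []))
        val = persistence_stability([shifted], dref, normalizer=0.5)
        assert np.isclose(val, 1 - 0.05 / 0.5)
        # U == normalizer -> 0
        val = persistence_stability([shifted], dref, normalizer=0.05)
        assert val == 0.0

    def test_macro_uncertainty(self):
        assert macro_uncertainty(0.0, 1.0, 0.0) == 0.0
        assert np.isclose(macro_uncertainty(0.1, 0.8, 0.04), 0.116)
        # strictly increasing as completeness drops
        assert (macro_uncertainty(0.1, 0.7, 0.04)
                > macro_uncertainty(0.1, 0.8, 0.04))
        with pytest.raises(ValueError):
            macro_uncertainty(-0.1, 0.8, 0.0)
        with pytest.raises(ValueError):
            macro_uncertainty(0.1, 1.2, 0.0)

    def test_topology_uncertainty_on_hand_built_diagrams(self):
        ref = (PersistenceDiagram(0, [0.9], [ESSENTIAL_DEATH]),
               PersistenceDiagram(1, [], []))
        r1 = (PersistenceDiagram(0, [0.7], [ESSENTIAL_DEATH]),
              PersistenceDiagram(1, [], []))  # distance 0.2
        r2 = (PersistenceDiagram(0, [0.5], [ESSENTIAL_DEATH]),
              PersistenceDiagram(1, [], []))  # distance 0.4
        u = topology_uncertainty([r1, r2], ref)
        assert np.isclose(u, 0.3)
        assert topology_uncertainty([ref, ref], ref) == 0.0

    def test_threshold_sensitivity_table(self, small_phantom, topo_cfg):
        img, truth = small_phantom
        thresholds = [0.1, 0.1, 0.1]
        df = threshold_sensitivity(img, thresholds, truth, topo_cfg)
        assert len(df) == 3
        assert df.drop(columns="threshold").nunique().max() == 1
        band = [0.08, 0.12, 0.2]
        df2 = threshold_sensitivity(img, band, truth, topo_cfg)
        assert len(df2) == len(band)
        # beta0 recount oracle at each threshold
        from scipy import ndimage
        v = vesselness(img, topo_cfg.scales_mm)
        for thr, b0 in zip(df2.threshold, df2.beta0):
            g = prune_graph(extract_graph(v, thr),
                            topo_cfg.prune_min_length_mm)
            assert g.betti0() == b0
        with pytest.raises(ValueError):
            threshold_sensitivity(img, [0.1], truth, topo_cfg)
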