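import numpy as np
import pytest

from wholeheart.errors import ConfigurationError, InsufficiencyError, SizeError
from wholeheart.conduction import (VisibilityGraph, all_pairs_activation,
                                   build_visibility_graph, floyd_warshall,
                                   ray_triangle_intersect,
                                   recover_front_velocity, segment_admissible,
                                   simulate_activation)
from wholeheart.phantom import (BoxRegion, Bundle, ConductionSystem,
                                LESION_PRESETS, LesionSpec, insert_lesion,
                                make_slab_phantom)
from wholeheart.topology import TissueProperties

UNIT_TRI = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])


def mt_linear_oracle(origin, direction, tri, eps=1e-9):
    """Independent classification: solve the 3x3 system
    ``origin + t d = v0 + u e1 + v e2`` directly."""
    v0, v1, v2 = np.asarray(tri, float)
    A = np.column_stack([-np.asarray(direction, float), v1 - v0, v2 - v0])
    if abs(np.linalg.det(A)) <= eps:
        return None
    t, u, v = np.linalg.solve(A, np.asarray(origin, float) - v0)
    if u < -eps or v < -eps or u + v > 1 + eps or t < -eps:
        return None
    return t, u, v


class TestMollerTrumbore:
    def test_axis_aligned_hit(self):
        t, u, v = ray_triangle_intersect((0.25, 0.25, -1), (0, 0, 1),
                                         UNIT_TRI)
        assert (t, u, v) == pytest.approx((1.0, 0.25, 0.25))

    def test_parallel_ray_misses(self):
        assert ray_triangle_intersect((0.25, 0.25, -1), (1, 0, 0),
                                      UNIT_TRI) is None

    def test_zero_direction_rejected(self):
        with pytest.raises(ConfigurationError):
            ray_triangle_intersect((0, 0, 0), (0, 0, 0), UNIT_TRI)

    def test_matches_linear_solve_oracle_on_random_pairs(self):
        """10^4 random ray/triangle pairs: identical hit classification and
        |dt| < 1e-9 on hits."""
        rng = np.random.default_rng(11)
        disagreements = 0
        for _ in range(10_000):
            tri = rng.normal(size=(3, 3))
            origin = rng.normal(size=3) * 2
            direction = rng.normal(size=3)
            mine = ray_triangle_intersect(origin, direction, tri)
            oracle = mt_linear_oracle(origin, direction, tri)
            if (mine is None) != (oracle is None):
                disagreements += 1
            elif mine is not None:
                assert abs(mine[0] - oracle[0]) < 1e-9
        assert disagreements == 0


class TestSegmentAdmissibility:
    def test_interior_nodes_of_convex_slab(self, slab):
        tris = slab.topology.hull_boundary_triangles("hulls.slab")
        assert segment_admissible(0, slab.n_nodes - 1, slab.vertices, tris)

    def test_self_segment_inadmissible(self, slab):
        tris = slab.topology.hull_boundary_triangles("hulls.slab")
        assert not segment_admissible(5, 5, slab.vertices, tris)

    def test_l_shaped_hull_corner_blocks(self):
        """Two lobes of an L-shaped hull have no line of sight past the
        reflex corner; verified against a midpoint containment oracle."""
        from wholeheart.phantom import VolumeMesh, _assemble
        from wholeheart.topology import TISSUE_PRESETS, point_in_hull
        from wholeheart.phantom import _lattice

        verts, tets = _lattice((5, 5, 2), 10.0)
        cen = verts[tets].mean(axis=1)
        keep = (cen[:, 0] < 10) | (cen[:, 1] < 10)   # L footprint
        tets = tets[keep]
        used, inv = np.unique(tets, return_inverse=True)
        mesh = VolumeMesh(verts[used], inv.reshape(-1, 4),
                          np.zeros(keep.sum(), np.int64), ("ell",))
        model = _assemble(mesh, {"ell": TISSUE_PRESETS["myocardium"]},
                          ConductionSystem(sources=[(0, 0.0)]), {})
        v = model.vertices
        a = int(np.argmin(np.linalg.norm(v - [35, 5, 5], axis=1)))
        b = int(np.argmin(np.linalg.norm(v - [5, 35, 5], axis=1)))
        tris = model.topology.hull_boundary_triangles("hulls.ell")
        assert not segment_admissible(a, b, v, tris)
        midpoint = 0.5 * (v[a] + v[b])
        assert not point_in_hull(midpoint, "hulls.ell", model.topology)
        # two points within one lobe do see each other
        c = int(np.argmin(np.linalg.norm(v - [5, 5, 5], axis=1)))
        assert segment_admissible(a, c, v, tris)


class TestVisibilityGraph:
    def test_convex_slab_has_all_pairs(self, slab, slab_graph):
        n = slab.n_nodes
        assert slab_graph.n_edges == n * (n - 1) // 2

    def test_edge_weights_equal_distance_over_speed(self, slab, slab_graph):
        v = slab.vertices
        recomputed = np.linalg.norm(v[slab_graph.edge_i]
                                    - v[slab_graph.edge_j], axis=1) / 0.6
        np.testing.assert_allclose(slab_graph.weights, recomputed, rtol=1e-12)

    def test_scar_interior_nodes_have_no_edges(self, scar_slab):
        g = build_visibility_graph(scar_slab)
        scar_nodes = set(scar_slab.hull_nodes["hulls.scar"])
        interface = (set(scar_slab.hull_nodes["hulls.slab"])
                     | set(scar_slab.hull_nodes["hulls.slab_2"]))
        interior = scar_nodes - interface
        assert interior
        touched = set(g.edge_i) | set(g.edge_j)
        assert not (interior & touched)

    def test_node_cap_enforced(self, slab):
        with pytest.raises(SizeError):
            build_visibility_graph(slab, node_cap=10)


class TestShortestPaths:
    def test_three_node_path(self):
        g = VisibilityGraph(3, np.array([0, 1]), np.array([1, 2]),
                            np.array([1.0, 2.0]), ["h", "h"])
        t = all_pairs_activation(g)
        assert t[0, 2] == pytest.approx(3.0)
        assert t[2, 0] == pytest.approx(3.0)
        assert np.all(np.diag(t) == 0)

    def test_disconnected_component_is_infinite(self):
        g = VisibilityGraph(4, np.array([0]), np.array([1]),
                            np.array([1.0]), ["h"])
        t = all_pairs_activation(g)
        assert np.isinf(t[0, 2]) and np.isinf(t[3, 1])

    def test_floyd_warshall_matches_dijkstra_on_random_graphs(self):
        """Exact equality against scipy's Dijkstra on 200-node graphs."""
        from scipy.sparse.csgraph import dijkstra
        rng = np.random.default_rng(7)
        for _ in range(3):
            n = 200
            k = 1200
            i = rng.integers(0, n, k)
            j = rng.integers(0, n, k)
            keep = i != j
            # dyadic-rational weights: every path sum is exactly
            # representable, so the two algorithms must agree bitwise
            w = rng.integers(1, 512, k).astype(float) / 64.0
            g = VisibilityGraph(n, i[keep], j[keep], w[keep],
                                ["r"] * int(keep.sum()))
            fw = all_pairs_activation(g)
            dj = dijkstra(g.to_csr(), directed=False)
            assert np.array_equal(fw, dj)

    def test_cap_advises_single_source(self):
        g = VisibilityGraph(3, np.array([0]), np.array([1]),
                            np.array([1.0]), ["h"])
        with pytest.raises(SizeError, match="single-source"):
            all_pairs_activation(g, node_cap=2)


class TestSimulation:
    def test_far_corner_of_slab_arrives_at_100ms(self, slab,
                                                 slab_activation):
        v = slab.vertices
        corner = int(np.argmin(np.linalg.norm(v - [60, 0, 0], axis=1)))
        assert slab_activation.times[corner] == pytest.approx(100.0)

    def test_convex_exactness(self, slab, slab_activation):
        d = np.linalg.norm(slab.vertices - slab.vertices[0], axis=1)
        np.testing.assert_allclose(slab_activation.times, d / 0.6,
                                   rtol=1e-9, atol=1e-9)

    def test_edema_band_arrival_is_piecewise_analytic(self, edema_slab):
        amap = simulate_activation(edema_slab)
        v = edema_slab.vertices
        corner = int(np.argmin(np.linalg.norm(v - [60, 0, 0], axis=1)))
        expected = 30 / 0.6 + 10 / 0.2 + 20 / 0.6
        assert amap.times[corner] == pytest.approx(expected, rel=1e-12)

    def test_edema_never_decreases_any_time(self, slab, slab_activation,
                                            edema_slab):
        amap = simulate_activation(edema_slab)
        assert np.all(amap.times >= slab_activation.times - 1e-9)

    def test_transmural_scar_blocks_distal_hull(self, scar_slab):
        amap = simulate_activation(scar_slab)
        distal = scar_slab.hull_nodes["hulls.slab_2"]
        assert np.all(amap.blocked[distal])
        proximal = scar_slab.hull_nodes["hulls.slab"]
        assert np.all(np.isfinite(amap.times[proximal]))

    def test_two_sources_take_earlier_arrival(self, slab, slab_graph):
        import copy
        m = copy.copy(slab)
        m.conduction = ConductionSystem(
            sources=[(0, 0.0), (slab.n_nodes - 1, 5.0)])
        amap = simulate_activation(m, graph=slab_graph)
        v = slab.vertices
        d0 = np.linalg.norm(v - v[0], axis=1) / 0.6
        d1 = np.linalg.norm(v - v[-1], axis=1) / 0.6 + 5.0
        np.testing.assert_allclose(amap.times, np.minimum(d0, d1),
                                   rtol=1e-12)
        # tie/metadata: the winning source index is the argmin
        expect_src = np.where(d0 <= d1, 0, 1)
        np.testing.assert_array_equal(amap.activating_source, expect_src)

    def test_no_sources_is_error(self, slab, slab_graph):
        import copy
        m = copy.copy(slab)
        m.conduction = ConductionSystem()
        with pytest.raises(ConfigurationError):
            simulate_activation(m, graph=slab_graph)

    def test_triangle_inequality_along_edges(self, slab_graph,
                                             slab_activation):
        t = slab_activation.times
        diff = np.abs(t[slab_graph.edge_i] - t[slab_graph.edge_j])
        assert np.all(diff <= slab_graph.weights + 1e-9)

    def test_methods_agree(self, heart, heart_activation):
        dj = simulate_activation(heart, method="dijkstra")
        fin = np.isfinite(heart_activation.times)
        np.testing.assert_allclose(dj.times[fin],
                                   heart_activation.times[fin], atol=1e-9)
        np.testing.assert_array_equal(dj.blocked, heart_activation.blocked)


class TestFrontVelocity:
    def test_uniform_slab_recovers_configured_speed(self, slab,
                                                    slab_activation):
        v = recover_front_velocity(slab_activation, np.arange(slab.n_nodes),
                                   slab.vertices, 0)
        assert v == pytest.approx(0.6, abs=1e-6)

    def test_bundle_polyline_recovers_2(self):
        model = make_slab_phantom((60, 10, 10), 5.0)
        row = [i for i in range(model.n_nodes)
               if model.vertices[i][1] == 0 and model.vertices[i][2] == 0]
        row.sort(key=lambda i: model.vertices[i][0])
        model.conduction.bundles.append(Bundle(
            tuple(row), TissueProperties("bundle_branch", 2.0, 0.2)))
        amap = simulate_activation(model)
        v = recover_front_velocity(amap, row, model.vertices, row[0])
        assert v == pytest.approx(2.0, abs=1e-6)

    def test_all_blocked_region_returns_zero(self, scar_slab):
        amap = simulate_activation(scar_slab)
        distal = scar_slab.hull_nodes["hulls.slab_2"]
        assert recover_front_velocity(amap, distal, scar_slab.vertices,
                                      0) == 0.0

    def test_too_few_usable_nodes_is_error(self, slab, slab_activation):
        with pytest.raises(InsufficiencyError):
            recover_front_velocity(slab_activation, [0, 1, 2],
                                   slab.vertices, 0)


class TestEpsMonotonicity:
    def test_removing_shrink_never_blocks_admissible_segments(self, slab):
        """A segment admissible with the endpoint shrink stays admissible
        when the shrink is removed only if it starts/ends strictly inside;
        conversely, shrinking can only ADD admissible segments."""
        from wholeheart.conduction import _segments_blocked
        rng = np.random.default_rng(3)
        tris = slab.vertices[
            slab.topology.hull_boundary_triangles("hulls.slab")]
        idx = rng.integers(0, slab.n_nodes, size=(200, 2))
        idx = idx[idx[:, 0] != idx[:, 1]]
        p = slab.vertices[idx[:, 0]]
        q = slab.vertices[idx[:, 1]]
        with_shrink = _segments_blocked(p, q, tris, 1e-6)
        tighter = _segments_blocked(p, q, tris, 1e-9)
        # a smaller shrink can only block MORE segments, never fewer
        assert np.all(with_shrink <= tighter)
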