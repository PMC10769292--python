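import numpy as np
import pytest
from osteolcn import SceneConfig, generate_scene
from osteolcn.connectomics import (
    connected_components,
    connection_length,
    connection_thickness,
    dilate_for_merging,
    extract_graph,
    network_metrics,
    prepare_masks,
)
from osteolcn.graph import DeadEnd, LcnEdge, LcnGraph, LcnNode
from osteolcn.metrics import evaluate_label
from _oracles import flood_fill_components, partition_from_labels
from conftest import noise_free


class TestPrepareMasks:
    def test_all_background(self):
        osteo, dend = prepare_masks(np.zeros((8, 8), np.uint8))
        assert not osteo.any() and not dend.any()

    def test_partition(self, rng):
        label = rng.integers(0, 3, (32, 32)).astype(np.uint8)
        osteo, dend = prepare_masks(label)
        assert np.array_equal(osteo | dend, label > 0)
        assert not (osteo & dend).any()

    def test_tallies_match_metric_counts(self, rng):
        label = rng.integers(0, 3, (16, 16)).astype(np.uint8)
        osteo, dend = prepare_masks(label)
        report = evaluate_label(label, label)
        assert report.pixel_counts[1][0] == osteo.sum()
        assert report.pixel_counts[2][0] == dend.sum()

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            prepare_masks(np.full((4, 4), 7, np.uint8))


class TestDilateForMerging:
    def test_empty_masks_stay_empty(self):
        o, d = dilate_for_merging(np.zeros((8, 8), bool), np.zeros((8, 8), bool))
        assert not o.any() and not d.any()

    def test_diagonal_gap_merged(self):
        dend = np.zeros((6, 6), bool)
        dend[1, 1] = dend[3, 3] = True  # 1-px diagonal gap at (2, 2)
        _, grown = dilate_for_merging(np.zeros_like(dend), dend)
        assert connected_components(grown, 8)[1] == 1

    def test_extensivity_chain(self, rng):
        osteo = rng.uniform(size=(24, 24)) < 0.1
        dend = rng.uniform(size=(24, 24)) < 0.1
        o1, d1 = dilate_for_merging(osteo, dend)
        o2, d2 = dilate_for_merging(o1, d1)
        assert (o1 >= osteo).all() and (d1 >= dend).all()
        assert (o2 >= o1).all() and (d2 >= d1).all()


class TestConnectedComponents:
    def test_empty(self):
        assert connected_components(np.zeros((8, 8), bool))[1] == 0

    def test_two_blocks(self):
        m = np.zeros((8, 8), bool)
        m[0:2, 0:2] = True
        m[5:7, 5:7] = True
        labels, n = connected_components(m, 4)
        assert n == 2
        assert sorted(np.bincount(labels.ravel())[1:]) == [4, 4]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(20):
            mask = rng.uniform(size=(32, 32)) < 0.4
            labels, _ = connected_components(mask, connectivity)
            oracle = flood_fill_components(mask, connectivity)
            assert partition_from_labels(labels) == partition_from_labels(oracle)

    def test_bad_connectivity(self):
        with pytest.raises(ValueError):
            connected_components(np.zeros((4, 4)), 6)


class TestBuildGraph:
    def test_two_somas_one_bridge(self):
        cfg = noise_free(SceneConfig(n_osteocytes=2, connection_probability=1.0,
                                     dead_end_rate=0.0, connection_radius_px=1e6,
                                     connection_length_scale_px=1e9, seed=7))
        scene = generate_scene(cfg)
        graph, _ = extract_graph(scene.mask)
        assert graph.n_nodes == 2 and graph.n_edges == 1
        assert not graph.dead_ends and not graph.isolated_dendrites

    def test_one_soma_one_stub(self):
        label = np.zeros((40, 40), np.uint8)
        label[10:20, 10:20] = 1
        label[14:16, 20:32] = 2  # stub touching the soma on one side
        graph, report = extract_graph(label)
        assert graph.n_nodes == 1 and graph.n_edges == 0
        assert len(graph.dead_ends) == 1
        assert report.dead_ends_per_node == 1.0

    def test_isolated_component_not_a_dead_end(self):
        label = np.zeros((40, 40), np.uint8)
        label[5:12, 5:12] = 1
        label[30:32, 5:25] = 2  # far from any soma
        graph, _ = extract_graph(label)
        assert len(graph.isolated_dendrites) == 1
        assert not graph.dead_ends

    def test_three_soma_overlap_uses_clique_rule(self):
        label = np.zeros((30, 60), np.uint8)
        for cx in (8, 28, 48):
            label[12:18, cx - 3 : cx + 3] = 1
        label[14:16, 4:56] = 2  # one dendrite crossing all three somas
        label[label.sum() == -1] = 0
        graph, _ = extract_graph(label)
        assert graph.n_nodes == 3
        assert graph.n_edges == 3  # all pairs of the shared component


class TestGeometry:
    def test_straight_line_length(self):
        comp = np.zeros((16, 16), bool)
        comp[8, 3:13] = True
        assert connection_length(comp, 1.0) == pytest.approx(10.0, abs=0.5)

    def test_diagonal_line_length(self):
        comp = np.eye(10, dtype=bool)
        expected = 10 * np.sqrt(2)
        assert connection_length(comp, 1.0) == pytest.approx(expected, rel=0.1)

    def test_bar_thickness(self):
        comp = np.zeros((30, 30), bool)
        comp[10:13, 4:24] = True  # 3 px wide, 20 px long
        assert connection_thickness(comp, 1.0) == pytest.approx(3.0, abs=0.5)

    def test_single_pixel_line_thickness(self):
        comp = np.zeros((16, 16), bool)
        comp[8, 2:14] = True
        assert connection_thickness(comp, 1.0) == pytest.approx(1.0, abs=0.2)

    def test_edt_thickness_agrees_on_bar(self):
        comp = np.zeros((30, 30), bool)
        comp[10:13, 4:24] = True
        assert connection_thickness(comp, 1.0, method="edt") == pytest.approx(3.0, abs=0.5)

    def test_unknown_thickness_method(self):
        with pytest.raises(ValueError):
            connection_thickness(np.ones((4, 4), bool), 1.0, method="calliper")

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            connection_length(np.zeros((4, 4), bool), 1.0)


def make_graph(n_nodes, edge_pairs, n_dead=0):
    nodes = [LcnNode(id=i, centroid=(0.0, float(i)), area=10.0) for i in range(n_nodes)]
    edges = [
        LcnEdge(node_a=a, node_b=b, component_id=k, length_um=5.0, thickness_um=0.5)
        for k, (a, b) in enumerate(edge_pairs)
    ]
    dead = [DeadEnd(node_id=0, component_id=100 + i, length_um=2.0) for i in range(n_dead)]
    return LcnGraph(nodes=nodes, edges=edges, dead_ends=dead)


class TestNetworkMetrics:
    def test_two_nodes_one_edge(self):
        rep = network_metrics(make_graph(2, [(0, 1)]))
        assert rep.connections_per_node == 1.0
        assert rep.mean_shortest_path == 1.0

    def test_path_graph_shortest_path(self):
        rep = network_metrics(make_graph(3, [(0, 1), (1, 2)]))
        assert rep.mean_shortest_path == pytest.approx((1 + 1 + 2) / 3)

    def test_empty_graph_flagged(self):
        rep = network_metrics(LcnGraph())
        assert rep.empty and rep.n_nodes == 0

    def test_handshake_identity(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 8))
            pairs = [tuple(sorted(rng.choice(n, 2, replace=False))) for _ in range(int(rng.integers(0, 10)))]
            rep = network_metrics(make_graph(n, pairs))
            assert rep.connections_per_node == pytest.approx(2 * len(pairs) / n)

    def test_random_graphs_match_brute_force(self, rng):
        """Shortest-path mean equals direct Floyd-Warshall on the adjacency."""
        for _ in range(10):
            n = int(rng.integers(2, 7))
            pairs = [tuple(sorted(rng.choice(n, 2, replace=False)))
                     for _ in range(int(rng.integers(1, 8)))]
            rep = network_metrics(make_graph(n, pairs))
            dist = np.full((n, n), np.inf)
            np.fill_diagonal(dist, 0)
            for a, b in pairs:
                dist[a, b] = dist[b, a] = 1
            for k in range(n):
                dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
            finite = dist[(dist > 0) & np.isfinite(dist)]
            expected = finite.mean() if finite.size else float("nan")
            if np.isnan(expected):
                assert np.isnan(rep.mean_shortest_path)
            else:
                assert rep.mean_shortest_path == pytest.approx(expected)

    def test_skeleton_endpoint_mode_counts_blunted_termini(self):
        """A dendrite with a free terminus registers one skeleton dead end;
        a soma-to-soma bridge registers none."""
        label = np.zeros((40, 60), np.uint8)
        label[15:25, 5:15] = 1
        label[19:21, 15:40] = 2  # stub ending in free space
        _, rep = extract_graph(label, dead_end_mode="skeleton_endpoint")
        assert rep.dead_ends_per_node == 1.0
        bridge = np.zeros((40, 60), np.uint8)
        bridge[15:25, 5:15] = 1
        bridge[15:25, 45:55] = 1
        bridge[19:21, 15:45] = 2
        _, rep = extract_graph(bridge, dead_end_mode="skeleton_endpoint")
        assert rep.dead_ends_per_node == 0.0

    def test_dead_end_and_edge_mutually_exclusive(self, noise_free_scenes_50):
        for scene in noise_free_scenes_50[:5]:
            graph, _ = extract_graph(scene.mask)
            edge_comps = {e.component_id for e in graph.edges}
            dead_comps = {d.component_id for d in graph.dead_ends}
            assert not edge_comps & dead_comps


def test_metrics_invariant_under_translation_and_rotation(noise_free_scenes_50):
    scene = noise_free_scenes_50[6]
    _, base = extract_graph(scene.mask, um_per_px=0.284)
    rolled = np.roll(scene.mask, (7, -5), axis=(0, 1))
    # guard: the roll must not wrap structures across the border
    if (scene.mask[:8].any() or scene.mask[:, -6:].any()):
        rolled = scene.mask
    _, moved = extract_graph(rolled, um_per_px=0.284)
    _, rotated = extract_graph(np.rot90(scene.mask), um_per_px=0.284)
    for rep in (moved, rotated):
        assert rep.n_nodes == base.n_nodes
        assert rep.n_edges == base.n_edges
        assert rep.dead_ends_per_node == pytest.approx(base.dead_ends_per_node)
        assert rep.mean_connection_length_um == pytest.approx(
            base.mean_connection_length_um, rel=0.05)
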