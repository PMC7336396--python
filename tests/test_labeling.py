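import math

import numpy as np
import pytest

from dtiwlnet import (
    Vertex,
    extract_enclosing_subgraph,
    geometric_mean_distance,
    initial_colors,
    palette_wl,
    wl_classical,
)

from conftest import random_network


class TestClassicalWL:
    def test_signature_worked_example(self):
        # vertex x (label 2, neighbor labels {1,2,3}) vs vertex y (label 3,
        # neighbor labels {2,2,4}): signature (2,"123") sorts before
        # (3,"224"), so x must receive the smaller refined label
        neighbors = {
            "x": ["a", "b", "c"],
            "y": ["e", "f", "g"],
            "a": ["x"], "b": ["x"], "c": ["x"],
            "e": ["y"], "f": ["y"], "g": ["y"],
        }
        init = {"x": 2, "y": 3, "a": 1, "b": 2, "c": 3, "e": 2, "f": 2, "g": 4}
        labels = wl_classical(neighbors, init, max_iters=1)
        assert labels["x"] < labels["y"]

    def test_vertex_transitive_cycle_never_separates(self):
        n = 6
        neighbors = {k: [(k - 1) % n, (k + 1) % n] for k in range(n)}
        labels = wl_classical(neighbors, max_iters=20)
        assert len(set(labels.values())) == 1

    def test_path_midpoint_separates_from_endpoints(self):
        neighbors = {0: [1], 1: [0, 2], 2: [1]}
        labels = wl_classical(neighbors, max_iters=1)
        assert labels[0] == labels[2] != labels[1]

    def test_empty_graph(self):
        assert wl_classical({}) == {}


@pytest.fixture
def chain_net():
    """d0-t0 anchor pair plus a chain: t0-d1, d1-t1, and isolated d2."""
    from dtiwlnet import DTINetwork

    Y = np.zeros((3, 2), dtype=np.int8)
    Y[0, 0] = 1  # anchor edge (masked in the subgraph)
    Y[1, 0] = 1  # t0 - d1
    Y[1, 1] = 1  # d1 - t1
    Y[0, 1] = 1  # d0 - t1 keeps the subgraph connected after masking
    return DTINetwork(["d0", "d1", "d2"], ["t0", "t1"], Y, np.eye(3), np.eye(2))


class TestGeometricMeanDistance:
    def test_anchors_score_zero(self, chain_net):
        sub = extract_enclosing_subgraph(chain_net, 0, 0, K=4)
        assert geometric_mean_distance(sub, sub.anchor_drug) == 0.0
        assert geometric_mean_distance(sub, sub.anchor_target) == 0.0

    def test_bfs_oracle_on_chain(self, chain_net):
        # subgraph edges after anchor masking: d0-t1, t1-d1, d1-t0
        # d1: 2 hops to d0, 1 hop to t0 -> sqrt(2); t1: 1 and 2 -> sqrt(2)
        sub = extract_enclosing_subgraph(chain_net, 0, 0, K=4)
        assert geometric_mean_distance(sub, Vertex("drug", 1)) == pytest.approx(
            math.sqrt(2)
        )
        assert geometric_mean_distance(sub, Vertex("target", 1)) == pytest.approx(
            math.sqrt(2)
        )

    def test_complete_bipartite_square(self):
        # bipartite parity means no vertex can sit at one hop from both
        # anchors; the closest non-anchor case is hops (1, 2) -> sqrt(2)
        from dtiwlnet import DTINetwork

        Y = np.ones((2, 2), dtype=np.int8)
        net = DTINetwork(["d0", "d1"], ["t0", "t1"], Y, np.eye(2), np.eye(2))
        sub = extract_enclosing_subgraph(net, 0, 0, K=4)
        # d1: adjacent to t0 (anchor target), 2 hops to d0 -> sqrt(2)
        assert geometric_mean_distance(sub, Vertex("drug", 1)) == pytest.approx(
            math.sqrt(2)
        )

    def test_unreachable_capped_at_2k(self, isolated_pair_net):
        net = isolated_pair_net
        Y = net.Y.copy()
        Y[1, 1] = 1  # a second component: d1-t1
        Y[0, 1] = 1  # link it to the anchor drug so it enters the subgraph
        net = net.replace_interactions(Y)
        sub = extract_enclosing_subgraph(net, 0, 0, K=6)
        # anchor target t0's only edge is the masked anchor edge: it is
        # unreachable from everything, so distances to it hit the 2K cap
        d1 = Vertex("drug", 1)
        assert geometric_mean_distance(sub, d1) == pytest.approx(
            math.sqrt(2 * 2 * sub.K)
        )

    def test_foreign_vertex_rejected(self, toy_net):
        sub = extract_enclosing_subgraph(toy_net, 0, 0, K=4)
        with pytest.raises(ValueError, match="not in subgraph"):
            geometric_mean_distance(sub, Vertex("drug", 2))


class TestInitialColors:
    def test_anchors_share_color_one(self, toy_net):
        sub = extract_enclosing_subgraph(toy_net, 0, 0, K=4)
        colors = initial_colors(sub)
        assert colors[sub.anchor_drug] == 1 and colors[sub.anchor_target] == 1

    def test_dense_ranking_of_distances(self, toy_net):
        # toy K=4 subgraph distances: anchors 0, d2 sqrt(2), t2 sqrt(2)
        sub = extract_enclosing_subgraph(toy_net, 0, 0, K=4)
        colors = initial_colors(sub)
        assert sorted(colors.values()) == [1, 1, 2, 2]

    def test_colors_consecutive_from_one(self):
        net = random_network(np.random.default_rng(8), 10, 10, density=0.25)
        sub = extract_enclosing_subgraph(net, 0, 0, K=8)
        values = sorted(set(initial_colors(sub).values()))
        assert values == list(range(1, len(values) + 1))


class TestPaletteWL:
    def test_toy_subgraph_hand_refinement(self, toy_net):
        # hand trace: anchors color 1; d2, t2 color 2; one refinement
        # iteration leaves the partition unchanged (each non-anchor sees one
        # color-1 neighbor), so ties break (init, drug<target, id):
        # d1 -> 1, t1 -> 2, d2 -> 3, t2 -> 4
        sub = extract_enclosing_subgraph(toy_net, 0, 0, K=4)
        ranks = palette_wl(sub).ranks
        assert ranks == {
            Vertex("drug", 0): 1,
            Vertex("target", 0): 2,
            Vertex("drug", 1): 3,
            Vertex("target", 1): 4,
        }

    @pytest.mark.parametrize("seed", range(10))
    def test_bijective_and_order_preserving(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, 12, 12, density=0.2)
        i, j = int(rng.integers(net.m)), int(rng.integers(net.n))
        sub = extract_enclosing_subgraph(net, i, j, K=8)
        ordering = palette_wl(sub)
        ranks, init = ordering.ranks, ordering.initial_colors
        assert sorted(ranks.values()) == list(range(1, len(sub.vertices) + 1))
        for u in sub.vertices:
            for v in sub.vertices:
                if init[u] < init[v]:
                    assert ranks[u] < ranks[v]

    def test_anchors_always_rank_first(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            net = random_network(rng, 10, 10, density=0.25)
            i, j = int(rng.integers(net.m)), int(rng.integers(net.n))
            sub = extract_enclosing_subgraph(net, i, j, K=6)
            ranks = palette_wl(sub).ranks
            assert ranks[sub.anchor_drug] == 1
            assert ranks[sub.anchor_target] == 2

    def test_automorphic_vertices_get_adjacent_ranks(self, toy_net):
        # d2 and t2 are structurally exchangeable images in the toy
        # subgraph; their pre-tie-break colors coincide so their final ranks
        # must be adjacent
        sub = extract_enclosing_subgraph(toy_net, 0, 0, K=4)
        ranks = palette_wl(sub).ranks
        assert abs(ranks[Vertex("drug", 1)] - ranks[Vertex("target", 1)]) == 1
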