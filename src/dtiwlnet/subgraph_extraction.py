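"""Enclosing-subgraph extraction around a candidate (drug, target) pair.

For each anchor pair the K-vertex local environment is collected: first the
anchors, then all of their interaction-edge neighbors, then further
interaction hops.  When a hop would overflow K, the candidate pool is ranked
by similarity to the anchors (drugs by S_D to the anchor drug, targets by
S_T to the anchor target, compared directly on the common [0,1] scale) and
only the top of the pool is admitted.  When the first hop alone overflows K,
the whole provisional subgraph is vertex-ordered by Palette-WL and the
lowest-ranked non-anchor vertices are discarded.  Subgraphs smaller than K
are padded downstream with isolated placeholder slots.

The anchor pair's own interaction edge, when present, is removed from the
induced subgraph so that a positive training pair cannot reveal its label
through its own edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_core import DTINetwork, Vertex

__all__ = ["EnclosingSubgraph", "extract_enclosing_subgraph"]


@dataclass
class EnclosingSubgraph:
    """K-bounded local environment of one anchor (drug, target) pair.

    ``vertices`` lists the anchors first; ``len(vertices) + padded_count == K``
    after extraction.  ``dti_edges`` holds the induced interaction edges as
    (drug-vertex, target-vertex) pairs, never including the anchor pair
    itself.  Similarity blocks are induced from the parent network on demand.
    """

    anchor_drug: Vertex
    anchor_target: Vertex
    vertices: list[Vertex]
    K: int
    padded_count: int
    dti_edges: frozenset[tuple[Vertex, Vertex]]
    network: DTINetwork = field(repr=False)

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("subgraph size K must be at least 2")
        if self.vertices[:2] != [self.anchor_drug, self.anchor_target]:
            raise ValueError("anchors must occupy the first two vertex slots")
        if (self.anchor_drug, self.anchor_target) in self.dti_edges:
            raise ValueError("anchor pair edge must be removed from dti_edges")

    def vertex_id(self, v: Vertex) -> str:
        return self.network.vertex_id(v)

    def adjacency(self) -> dict[Vertex, set[Vertex]]:
        """Interaction-edge adjacency restricted to the subgraph."""
        adj: dict[Vertex, set[Vertex]] = {v: set() for v in self.vertices}
        for d, t in self.dti_edges:
            adj[d].add(t)
            adj[t].add(d)
        return adj

    @property
    def drug_sim_block(self) -> np.ndarray:
        idx = [v.index for v in self.vertices if v.role == "drug"]
        return self.network.S_D[np.ix_(idx, idx)]

    @property
    def target_sim_block(self) -> np.ndarray:
        idx = [v.index for v in self.vertices if v.role == "target"]
        return self.network.S_T[np.ix_(idx, idx)]


def _induced_edges(
    net: DTINetwork, vertices: list[Vertex], anchor_drug: Vertex, anchor_target: Vertex
) -> frozenset[tuple[Vertex, Vertex]]:
    drugs = [v for v in vertices if v.role == "drug"]
    targets = [v for v in vertices if v.role == "target"]
    edges = set()
    for d in drugs:
        row = net.Y[d.index]
        for t in targets:
            if row[t.index] == 1:
                edges.add((d, t))
    edges.discard((anchor_drug, anchor_target))
    return frozenset(edges)


def _grow_vertices(net: DTINetwork, i: int, j: int, K: int) -> list[Vertex]:
    """Breadth-first vertex collection before any truncation.

    Returns the anchors, the full first interaction hop, and then
    similarity-ranked pool additions until K is reached or the frontier is
    exhausted.  May exceed K only through the first hop.
    """
    d_a, t_a = Vertex("drug", i), Vertex("target", j)
    included: dict[Vertex, None] = {d_a: None, t_a: None}

    def sort_key(v: Vertex) -> tuple:
        return (v.role, net.vertex_id(v))

    first_hop = sorted(
        (net.dti_neighbors(d_a) | net.dti_neighbors(t_a)) - included.keys(),
        key=sort_key,
    )
    for v in first_hop:
        included[v] = None
    frontier = list(first_hop)

    while len(included) < K and frontier:
        pool = set()
        for v in frontier:
            pool |= net.dti_neighbors(v)
        pool -= included.keys()
        if not pool:
            break
        # one merged ranking over both roles; similarity to the matching anchor
        def score(v: Vertex) -> float:
            if v.role == "drug":
                return float(net.S_D[i, v.index])
            return float(net.S_T[j, v.index])

        ranked = sorted(pool, key=lambda v: (-score(v), v.role, net.vertex_id(v)))
        added = []
        for v in ranked:
            if len(included) >= K:
                break
            included[v] = None
            added.append(v)
        frontier = added
    return list(included)


def extract_enclosing_subgraph(
    net: DTINetwork, i: int, j: int, K: int
) -> EnclosingSubgraph:
    """Extract the K-vertex enclosing subgraph of the pair (drug i, target j)."""
    if K < 2:
        raise ValueError("subgraph size K must be at least 2")
    if not (0 <= i < net.m and 0 <= j < net.n):
        raise IndexError(f"pair ({i}, {j}) out of range for {net.m}x{net.n} network")
    d_a, t_a = Vertex("drug", i), Vertex("target", j)
    vertices = _grow_vertices(net, i, j, K)

    if len(vertices) > K:
        provisional = EnclosingSubgraph(
            anchor_drug=d_a,
            anchor_target=t_a,
            vertices=vertices,
            K=len(vertices),
            padded_count=0,
            dti_edges=_induced_edges(net, vertices, d_a, t_a),
            network=net,
        )
        from .labeling import palette_wl  # deferred: labeling consumes subgraphs

        ranks = palette_wl(provisional).ranks
        # anchors hold ranks 1 and 2 by construction, so keeping the top K
        # ranks never discards them
        vertices = sorted(vertices, key=lambda v: ranks[v])[:K]
        vertices = [d_a, t_a] + [v for v in vertices if v not in (d_a, t_a)]

    return EnclosingSubgraph(
        anchor_drug=d_a,
        anchor_target=t_a,
        vertices=vertices,
        K=K,
        padded_count=max(0, K - len(vertices)),
        dti_edges=_induced_edges(net, vertices, d_a, t_a),
        network=net,
    )
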