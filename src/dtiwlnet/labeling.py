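"""Vertex ordering by Palette-WL color refinement.

A fixed-length encoding of an enclosing subgraph needs a canonical vertex
order, and vertices playing the same structural role in different subgraphs
should land at similar positions.  Classical Weisfeiler-Lehman refinement
(iterated signature sorting) provides such an order but treats all vertices
identically; here the anchors must come first and proximity to the anchor
pair must dominate.  Palette-WL therefore seeds each vertex's color with the
rank of its geometric-mean hop distance to the two anchors and refines with
an order-preserving hash: each iteration adds to the integer color a
fractional term, strictly below 1, accumulated from prime logarithms of the
neighbor colors.  Because the fraction never reaches 1, a vertex can never
overtake one with a smaller initial color — refinement only splits ties.

Classical WL is implemented alongside as a reference for ordering behavior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Hashable, Iterable, Mapping

import networkx as nx

from .graph_core import Vertex

if TYPE_CHECKING:  # pragma: no cover
    from .subgraph_extraction import EnclosingSubgraph

__all__ = [
    "VertexOrdering",
    "wl_classical",
    "geometric_mean_distance",
    "initial_colors",
    "palette_wl",
]


@dataclass
class VertexOrdering:
    """Bijective vertex -> rank map (ranks 1..|vertices|) with its seed colors."""

    ranks: dict[Vertex, int]
    initial_colors: dict[Vertex, int]

    @property
    def order(self) -> list[Vertex]:
        return sorted(self.ranks, key=self.ranks.__getitem__)


# -- classical WL (reference) -------------------------------------------------


def wl_classical(
    neighbors: Mapping[Hashable, Iterable[Hashable]],
    initial_labels: Mapping[Hashable, int] | None = None,
    max_iters: int = 100,
) -> dict[Hashable, int]:
    """Iterated signature-sort relabeling until labels stabilize.

    Each vertex forms the signature (own label, sorted neighbor labels);
    signatures are sorted lexicographically and dense-relabeled from 1.
    Equal signatures keep equal labels, so symmetric vertices never separate.
    """
    nodes = list(neighbors)
    labels = (
        {v: 1 for v in nodes}
        if initial_labels is None
        else {v: int(initial_labels[v]) for v in nodes}
    )
    for _ in range(max_iters):
        signatures = {
            v: (labels[v], tuple(sorted(labels[u] for u in neighbors[v])))
            for v in nodes
        }
        new_labels = _dense_rank(signatures)
        if new_labels == labels:
            break
        labels = new_labels
    return labels


def _dense_rank(values: Mapping[Hashable, object]) -> dict[Hashable, int]:
    distinct = sorted(set(values.values()))
    pos = {s: k + 1 for k, s in enumerate(distinct)}
    return {v: pos[s] for v, s in values.items()}


# -- Palette-WL ---------------------------------------------------------------


def _anchor_distances(sub: "EnclosingSubgraph") -> dict[Vertex, tuple[int, int]]:
    """Hop distances of every subgraph vertex to both anchors.

    Distances run over the induced interaction edges only (the anchor pair's
    own edge is already removed); unreachable vertices are capped at 2K.
    """
    G = nx.Graph()
    G.add_nodes_from(sub.vertices)
    G.add_edges_from(sub.dti_edges)
    cap = 2 * sub.K
    from_drug = nx.single_source_shortest_path_length(G, sub.anchor_drug)
    from_target = nx.single_source_shortest_path_length(G, sub.anchor_target)
    return {
        v: (min(from_drug.get(v, cap), cap), min(from_target.get(v, cap), cap))
        for v in sub.vertices
    }


def geometric_mean_distance(sub: "EnclosingSubgraph", v: Vertex) -> float:
    """sqrt(hops to anchor drug x hops to anchor target); anchors score 0."""
    dists = _anchor_distances(sub)
    if v not in dists:
        raise ValueError(f"vertex {v} not in subgraph")
    a, b = dists[v]
    return math.sqrt(a * b)


def initial_colors(sub: "EnclosingSubgraph") -> dict[Vertex, int]:
    """Dense ranking of geometric-mean anchor distances into colors 1, 2, ...

    Equal distances share a color; both anchors always receive color 1.
    """
    dists = _anchor_distances(sub)
    gm = {v: math.sqrt(a * b) for v, (a, b) in dists.items()}
    return _dense_rank(gm)


_PRIMES = [2]


def _prime(k: int) -> int:
    """k-th prime, 1-based (prime(1) == 2)."""
    while len(_PRIMES) < k:
        c = _PRIMES[-1] + 1
        while not all(c % p for p in _PRIMES if p * p <= c):
            c += 1
        _PRIMES.append(c)
    return _PRIMES[k - 1]


def palette_wl(sub: "EnclosingSubgraph") -> VertexOrdering:
    """Order-preserving color refinement to a bijective vertex ranking.

    Iterates h(v) = c(v) + g(v) with

        g(v) = sum_{u in N(v)} log p(c(u)) / (1 + sum_{u in V} log p(c(u)))

    where p(c) is the c-th prime, then dense-reranks h.  g < 1, so the
    integer part dominates and the initial color order is preserved at every
    iteration; refinement only separates vertices of equal color whose
    neighborhoods differ.  Residual ties after convergence are broken by
    (initial color, drug before target, identifier).
    """
    verts = sub.vertices
    if not verts:
        raise ValueError("empty subgraph")
    adj = sub.adjacency()
    init = initial_colors(sub)
    colors = dict(init)
    max_iters = 2 * len(verts)
    converged = False
    for _ in range(max_iters):
        logp = {v: math.log(_prime(colors[v])) for v in verts}
        # summation over sorted addends keeps the result independent of
        # vertex storage order (bit-stable under permutation)
        total = math.fsum(sorted(logp.values()))
        h = {
            v: colors[v] + math.fsum(sorted(logp[u] for u in adj[v])) / (1.0 + total)
            for v in verts
        }
        new_colors = _dense_rank(h)
        if new_colors == colors:
            converged = True
            break
        colors = new_colors
    if not converged and len(set(colors.values())) < len(verts):
        warnings.warn(
            "palette_wl did not converge to unique colors; "
            "applying deterministic tie-break",
            stacklevel=2,
        )
    # anchors are pinned to ranks 1 and 2 (drug first): they alone hold
    # initial color 1, and fixed anchor positions keep the encoded anchor
    # cell at the same vector slot in every subgraph
    anchor_rank = {sub.anchor_drug: 0, sub.anchor_target: 1}
    final_order = sorted(
        verts,
        key=lambda v: (
            anchor_rank.get(v, 2),
            colors[v],
            init[v],
            v.role,
            sub.vertex_id(v),
        ),
    )
    ranks = {v: r + 1 for r, v in enumerate(final_order)}
    return VertexOrdering(ranks=ranks, initial_colors=init)
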