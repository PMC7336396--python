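"""Fixed-length adjacency encoding of ordered enclosing subgraphs.

An ordered K-vertex subgraph is written as a symmetric K x K matrix in rank
order: interaction edges contribute 1, drug-drug cells carry S_D, target-
target cells carry S_T, absent interactions and padded slots are 0.  The
cell of the anchor pair itself (ranks 1 and 2) is forced to 0 so that a
training vector can never read off its own label.  Since the matrix is
symmetric, only the strict upper triangle is kept, flattened column by
column into a vector of length K(K-1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import DTINetwork
from .labeling import VertexOrdering, palette_wl
from .negative_sampling import PairSample
from .subgraph_extraction import EnclosingSubgraph, extract_enclosing_subgraph

__all__ = [
    "EmbeddingVector",
    "encode_subgraph",
    "flatten_upper",
    "unflatten_upper",
    "embed_pair",
    "embed_samples",
]


@dataclass
class EmbeddingVector:
    """Length-K(K-1)/2 feature vector for one (drug, target) pair."""

    values: np.ndarray
    K: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.K * (self.K - 1) // 2
        if self.values.shape != (expected,):
            raise ValueError(
                f"embedding length {self.values.shape} != K(K-1)/2 = {expected}"
            )


def flatten_upper(A: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a square matrix, column-major (vertical) order."""
    K = A.shape[0]
    return np.concatenate([A[:j, j] for j in range(1, K)]) if K > 1 else np.empty(0)


def unflatten_upper(vec: np.ndarray, K: int) -> np.ndarray:
    """Inverse of :func:`flatten_upper`; returns the symmetric K x K matrix."""
    if len(vec) != K * (K - 1) // 2:
        raise ValueError("vector length does not match K(K-1)/2")
    A = np.zeros((K, K))
    pos = 0
    for j in range(1, K):
        A[:j, j] = vec[pos : pos + j]
        pos += j
    return A + A.T


def encode_subgraph(
    sub: EnclosingSubgraph, ordering: VertexOrdering
) -> EmbeddingVector:
    """Encode an ordered subgraph as its flattened upper-triangle vector."""
    ranks = ordering.ranks
    if set(ranks) != set(sub.vertices) or len(set(ranks.values())) != len(ranks):
        raise ValueError("ordering is not a bijection over the subgraph vertices")
    K = sub.K
    A = np.zeros((K, K))
    pos = {v: ranks[v] - 1 for v in sub.vertices}  # padded slots stay all-zero
    verts = sub.vertices
    for a_i, u in enumerate(verts):
        for w in verts[a_i + 1 :]:
            if u.role == "drug" and w.role == "drug":
                val = sub.network.S_D[u.index, w.index]
            elif u.role == "target" and w.role == "target":
                val = sub.network.S_T[u.index, w.index]
            else:
                d, t = (u, w) if u.role == "drug" else (w, u)
                val = 1.0 if (d, t) in sub.dti_edges else 0.0
            A[pos[u], pos[w]] = A[pos[w], pos[u]] = val
    A[0, 1] = A[1, 0] = 0.0  # mask the anchor pair cell: no label leakage
    return EmbeddingVector(values=flatten_upper(A), K=K)


def embed_pair(net: DTINetwork, i: int, j: int, K: int) -> EmbeddingVector:
    """Full per-pair pipeline: extract, order, encode."""
    sub = extract_enclosing_subgraph(net, i, j, K)
    return encode_subgraph(sub, palette_wl(sub))


def embed_samples(
    net: DTINetwork, samples: list[PairSample], K: int
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and 0/1 label vector for a list of pair samples."""
    X = np.empty((len(samples), K * (K - 1) // 2))
    y = np.empty(len(samples), dtype=int)
    for r, s in enumerate(samples):
        X[r] = embed_pair(net, s.drug_index, s.target_index, K).values
        y[r] = s.y
    return X, y
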