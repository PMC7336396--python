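"""Semi-bipartite drug-target network container and TSV I/O.

The network couples a binary drug-target interaction matrix ``Y`` (m x n)
with two weighted intra-side similarity matrices: drug-drug ``S_D`` (m x m)
and target-target ``S_T`` (n x n), both symmetric with unit diagonal and
entries in [0, 1].  Interaction edges and similarity edges play different
roles downstream: neighborhood queries traverse interaction edges only,
while similarities enter candidate ranking and feature encoding.  The
similarity graphs are treated as complete weighted graphs (a zero weight is
an absent edge); no thresholding is applied.

All file I/O is by string identifier; indices are 0-based internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Vertex",
    "DTINetwork",
    "load_network",
    "write_network",
    "load_similarity_matrix",
]

#: strict symmetry tolerance; asymmetries up to _REPAIR_ATOL are symmetrized
#: with a warning, anything larger is an error.
_SYMMETRY_ATOL = 1e-9
_REPAIR_ATOL = 1e-6


@dataclass(frozen=True, order=True)
class Vertex:
    """Uniform handle for a node on either side of the bipartition.

    Ordering is lexicographic on (role, index); since ``'drug' < 'target'``
    this matches the drug-before-target convention used in tie-breaks.
    """

    role: str  # 'drug' | 'target'
    index: int

    def __post_init__(self) -> None:
        if self.role not in ("drug", "target"):
            raise ValueError(f"unknown vertex role {self.role!r}")


@dataclass
class DTINetwork:
    """Validated semi-bipartite DTI network.

    Parameters
    ----------
    drug_ids, target_ids
        Ordered unique string identifiers; their order fixes row/column
        order of all matrices.
    Y
        m x n binary interaction matrix (1 = known interaction, 0 = unknown).
    S_D, S_T
        Drug-drug (m x m) and target-target (n x n) similarity matrices,
        symmetric, unit diagonal, entries in [0, 1].
    """

    drug_ids: list[str]
    target_ids: list[str]
    Y: np.ndarray
    S_D: np.ndarray
    S_T: np.ndarray
    _drug_adj: list[np.ndarray] | None = field(default=None, repr=False, compare=False)
    _target_adj: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.target_ids = [str(t) for t in self.target_ids]
        self.Y = np.asarray(self.Y)
        self.S_D = np.asarray(self.S_D, dtype=float)
        self.S_T = np.asarray(self.S_T, dtype=float)
        self._validate()
        self._drug_lookup = {d: i for i, d in enumerate(self.drug_ids)}
        self._target_lookup = {t: j for j, t in enumerate(self.target_ids)}

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug identifiers")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("duplicate target identifiers")
        m, n = len(self.drug_ids), len(self.target_ids)
        if self.Y.shape != (m, n):
            raise ValueError(
                f"dimension mismatch: Y is {self.Y.shape}, expected ({m}, {n})"
            )
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")
        self.Y = self.Y.astype(np.int8)
        self.S_D = _check_similarity(self.S_D, m, "drug")
        self.S_T = _check_similarity(self.S_T, n, "target")

    # -- basic accessors ----------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.drug_ids)

    @property
    def n(self) -> int:
        return len(self.target_ids)

    def drug(self, i: int) -> Vertex:
        return Vertex("drug", int(i))

    def target(self, j: int) -> Vertex:
        return Vertex("target", int(j))

    def drug_index(self, drug_id: str) -> int:
        return self._drug_lookup[drug_id]

    def target_index(self, target_id: str) -> int:
        return self._target_lookup[target_id]

    def vertex_id(self, v: Vertex) -> str:
        return self.drug_ids[v.index] if v.role == "drug" else self.target_ids[v.index]

    # -- neighborhood queries -----------------------------------------------

    def _adjacency(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        if self._drug_adj is None:
            self._drug_adj = [np.flatnonzero(self.Y[i]) for i in range(self.m)]
            self._target_adj = [np.flatnonzero(self.Y[:, j]) for j in range(self.n)]
        return self._drug_adj, self._target_adj

    def drug_targets(self, i: int) -> np.ndarray:
        """Indices of targets known to interact with drug ``i`` (T_d)."""
        if not 0 <= i < self.m:
            raise IndexError(f"drug index {i} out of range")
        return self._adjacency()[0][i]

    def target_drugs(self, j: int) -> np.ndarray:
        """Indices of drugs known to interact with target ``j`` (D_t)."""
        if not 0 <= j < self.n:
            raise IndexError(f"target index {j} out of range")
        return self._adjacency()[1][j]

    def dti_neighbors(self, v: Vertex) -> set[Vertex]:
        """Interaction-edge neighbors of ``v``.

        For a drug this is its set of known targets, for a target its set of
        known drugs.  Similarity edges are never traversed.
        """
        if v.role == "drug":
            return {Vertex("target", int(j)) for j in self.drug_targets(v.index)}
        return {Vertex("drug", int(i)) for i in self.target_drugs(v.index)}

    def interacting_pairs(self) -> list[tuple[int, int]]:
        """All (drug, target) index pairs with a known interaction."""
        return [(int(i), int(j)) for i, j in zip(*np.nonzero(self.Y))]

    def unknown_pairs(self) -> list[tuple[int, int]]:
        """All (drug, target) index pairs without a known interaction."""
        return [(int(i), int(j)) for i, j in zip(*np.nonzero(self.Y == 0))]

    # -- derived networks ----------------------------------------------------

    def replace_interactions(self, Y: np.ndarray) -> "DTINetwork":
        """New network sharing identifiers and similarities with a fresh Y."""
        return DTINetwork(self.drug_ids, self.target_ids, np.array(Y), self.S_D, self.S_T)


def _check_similarity(S: np.ndarray, size: int, side: str) -> np.ndarray:
    if S.shape != (size, size):
        raise ValueError(
            f"dimension mismatch: {side} similarity is {S.shape}, expected ({size}, {size})"
        )
    if np.isnan(S).any():
        raise ValueError(f"{side} similarity contains NaN")
    if S.min() < 0 or S.max() > 1:
        raise ValueError(f"{side} similarity out of range [0, 1]")
    asym = np.abs(S - S.T).max() if size else 0.0
    if asym > _SYMMETRY_ATOL:
        if asym <= _REPAIR_ATOL:
            warnings.warn(
                f"{side} similarity asymmetric up to {asym:.2e}; symmetrizing",
                stacklevel=3,
            )
            S = (S + S.T) / 2.0
        else:
            raise ValueError(f"non-symmetric {side} similarity (max dev {asym:.2e})")
    if size and not np.allclose(np.diag(S), 1.0):
        warnings.warn(
            f"{side} similarity diagonal not 1; forcing unit diagonal", stacklevel=3
        )
        S = S.copy()
        np.fill_diagonal(S, 1.0)
    return S


# -- TSV I/O -----------------------------------------------------------------
#
# Matrix dialect: first row = column identifiers, first column = row
# identifiers, tab-separated, '.' decimal.  Edge-list dialect: two
# tab-separated identifier columns (drug, target); an optional third weight
# column is ignored (interactions are binary by presence).


def load_similarity_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square identifier-labelled similarity matrix TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if ids != col_ids:
        raise ValueError(f"{path}: row and column identifiers differ")
    return ids, df.to_numpy(dtype=float)


def _load_interactions(
    path: str | Path, drug_ids: list[str], target_ids: list[str]
) -> np.ndarray:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    fields = first.split("\t")
    target_set = set(target_ids)
    # dialect detection precedence: an empty leading cell marks a matrix
    # header; otherwise 2-3 columns are read as an edge list (identifiers
    # validated below); otherwise a target-id header marks a matrix
    if fields[0] == "" and all(f in target_set for f in fields[1:]):
        is_matrix = True
    elif len(fields) in (2, 3):
        is_matrix = False
    elif all(f in target_set for f in fields[1:]):
        is_matrix = True
    else:
        raise ValueError(f"{path}: neither a matrix TSV nor a 2-3 column edge list")
    Y = np.zeros((len(drug_ids), len(target_ids)), dtype=np.int8)
    drug_pos = {d: i for i, d in enumerate(drug_ids)}
    target_pos = {t: j for j, t in enumerate(target_ids)}
    if is_matrix:
        df = pd.read_csv(path, sep="\t", index_col=0)
        for d in df.index:
            if str(d) not in drug_pos:
                raise ValueError(f"interaction drug {d!r} absent from similarity file")
        for t in df.columns:
            if str(t) not in target_pos:
                raise ValueError(f"interaction target {t!r} absent from similarity file")
        sub = df.to_numpy()
        if not np.isin(sub, (0, 1)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")
        rows = [drug_pos[str(d)] for d in df.index]
        cols = [target_pos[str(t)] for t in df.columns]
        Y[np.ix_(rows, cols)] = sub
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] not in (2, 3):
            raise ValueError(f"{path}: expected 2 or 3 columns in edge list")
        for d, t in zip(df[0], df[1]):
            d, t = str(d), str(t)
            if d not in drug_pos:
                raise ValueError(f"interaction drug {d!r} absent from similarity file")
            if t not in target_pos:
                raise ValueError(f"interaction target {t!r} absent from similarity file")
            Y[drug_pos[d], target_pos[t]] = 1
    return Y


def load_network(
    interaction_path: str | Path,
    drug_sim_path: str | Path,
    target_sim_path: str | Path,
) -> DTINetwork:
    """Load a DTI network from three TSV files.

    Identifier order is taken from the similarity-matrix headers.  The
    interaction file may be a full 0/1 matrix TSV or a two-column edge list;
    interaction identifiers absent from the similarity headers are an error.
    """
    drug_ids, S_D = load_similarity_matrix(drug_sim_path)
    target_ids, S_T = load_similarity_matrix(target_sim_path)
    Y = _load_interactions(interaction_path, drug_ids, target_ids)
    return DTINetwork(drug_ids, target_ids, Y, S_D, S_T)


def write_network(
    net: DTINetwork,
    interaction_path: str | Path,
    drug_sim_path: str | Path,
    target_sim_path: str | Path,
) -> None:
    """Write the three TSV files consumed by :func:`load_network`.

    Floats are written with ``repr`` precision so a load/write round trip
    reproduces the matrices bit-exactly.
    """
    pd.DataFrame(net.Y, index=net.drug_ids, columns=net.target_ids).to_csv(
        interaction_path, sep="\t"
    )
    pd.DataFrame(net.S_D, index=net.drug_ids, columns=net.drug_ids).to_csv(
        drug_sim_path, sep="\t", float_format=lambda x: repr(float(x))
    )
    pd.DataFrame(net.S_T, index=net.target_ids, columns=net.target_ids).to_csv(
        target_sim_path, sep="\t", float_format=lambda x: repr(float(x))
    )
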