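"""Reliable-negative scoring and labeled sample assembly.

Only positive interactions are observed in a DTI network; everything else is
unknown rather than negative.  Training a classifier therefore requires
choosing negatives among the unknown pairs.  A pair (d_i, t_j) is a
*reliable* negative when d_i is dissimilar to every known drug of t_j and
t_j is dissimilar to every known target of d_i ("guilt by association" in
reverse).  Each unknown pair is scored

    s_ij = exp(-(s_DT + s_TD)),
    s_DT = sum of S_T[t_j, t_k] over targets t_k interacting with d_i,
    s_TD = sum of S_D[d_i, d_k] over drugs d_k interacting with t_j,

so s_ij lies in (0, 1] and equals 1 exactly when both sums are empty; the
highest-scoring pairs are the most reliable negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph_core import DTINetwork

__all__ = [
    "PairSample",
    "SamplingConfig",
    "negative_score",
    "negative_score_matrix",
    "rank_reliable_negatives",
    "assemble_samples",
]

ALL_UNKNOWN = "all_unknown"


@dataclass(frozen=True)
class PairSample:
    """A labeled (drug, target) pair; negatives carry a reliability score."""

    drug_index: int
    target_index: int
    label: str  # 'positive' | 'negative'
    reliability: float | None = None

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.reliability is not None and not 0.0 < self.reliability <= 1.0:
            raise ValueError("reliability must lie in (0, 1]")

    @property
    def y(self) -> int:
        return 1 if self.label == "positive" else 0


@dataclass
class SamplingConfig:
    """How many samples to draw and at which positive:negative ratio.

    ``ratio_alpha`` is positives/negatives (1.0 = balanced, 0.1 = ten
    negatives per positive); the sentinel ``"all_unknown"`` takes every
    unknown pair as a negative.
    """

    ratio_alpha: float | str = 1.0
    n_positives: int | str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio_alpha != ALL_UNKNOWN and not self.ratio_alpha > 0:
            raise ValueError("ratio_alpha must be positive or 'all_unknown'")


def negative_score(net: DTINetwork, i: int, j: int) -> float:
    """Reliability score of the unknown pair (drug i, target j)."""
    if net.Y[i, j] == 1:
        raise ValueError(f"pair ({i}, {j}) is a known interaction")
    s_dt = float(net.S_T[j, net.drug_targets(i)].sum())
    s_td = float(net.S_D[i, net.target_drugs(j)].sum())
    return math.exp(-(s_dt + s_td))


def negative_score_matrix(net: DTINetwork) -> np.ndarray:
    """Vectorized reliability scores for every pair (valid where Y == 0).

    ``(Y @ S_T)[i, j]`` sums S_T[t_k, t_j] over the targets of drug i and
    ``(S_D @ Y)[i, j]`` sums S_D[d_i, d_k] over the drugs of target j.
    """
    Y = net.Y.astype(float)
    return np.exp(-(Y @ net.S_T + net.S_D @ Y))


def rank_reliable_negatives(net: DTINetwork, top_k: int) -> list[PairSample]:
    """The ``top_k`` unknown pairs ranked by reliability, descending.

    Candidate pool excludes known interactions; ties are broken by
    (drug identifier, target identifier) lexicographic order.
    """
    scores = negative_score_matrix(net)
    pool = net.unknown_pairs()
    if top_k > len(pool):
        raise ValueError(f"top_k={top_k} exceeds pool of {len(pool)} unknown pairs")
    pool.sort(key=lambda ij: (-scores[ij], net.drug_ids[ij[0]], net.target_ids[ij[1]]))
    return [
        PairSample(i, j, "negative", float(scores[i, j])) for i, j in pool[:top_k]
    ]


def assemble_samples(
    net: DTINetwork, config: SamplingConfig, mode: str = "reliable"
) -> list[PairSample]:
    """Assemble a shuffled labeled sample list at the configured ratio.

    Positives are drawn uniformly without replacement from the known
    interactions.  Negatives number round(n_positives / ratio_alpha): in
    ``reliable`` mode the deterministic top of the reliability ranking, in
    ``random`` mode a uniform draw of unknown pairs.  All randomness flows
    from ``config.seed``.
    """
    if mode not in ("reliable", "random"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    rng = np.random.default_rng(config.seed)

    positives_pool = sorted(
        net.interacting_pairs(),
        key=lambda ij: (net.drug_ids[ij[0]], net.target_ids[ij[1]]),
    )
    if config.n_positives == "all":
        n_pos = len(positives_pool)
    else:
        n_pos = int(config.n_positives)
        if n_pos > len(positives_pool):
            raise ValueError(
                f"{n_pos} positives requested but only {len(positives_pool)} known"
            )
    chosen = rng.choice(len(positives_pool), size=n_pos, replace=False)
    samples = [
        PairSample(*positives_pool[k], "positive") for k in sorted(chosen)
    ]

    n_unknown = net.m * net.n - len(net.interacting_pairs())
    if config.ratio_alpha == ALL_UNKNOWN:
        n_neg = n_unknown
    else:
        n_neg = int(round(n_pos / float(config.ratio_alpha)))
    if n_neg > n_unknown:
        raise ValueError(
            f"{n_neg} negatives requested but only {n_unknown} unknown pairs"
        )

    if mode == "reliable":
        samples.extend(rank_reliable_negatives(net, n_neg))
    else:
        scores = negative_score_matrix(net)
        pool = sorted(
            net.unknown_pairs(),
            key=lambda ij: (net.drug_ids[ij[0]], net.target_ids[ij[1]]),
        )
        picked = rng.choice(len(pool), size=n_neg, replace=False)
        samples.extend(
            PairSample(*pool[k], "negative", float(scores[pool[k]]))
            for k in sorted(picked)
        )

    rng.shuffle(samples)
    return samples
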