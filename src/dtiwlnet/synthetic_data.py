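"""Seeded synthetic semi-bipartite DTI networks with planted structure.

The generator produces the statistical structure the prediction method
assumes — nothing more.  Drugs and targets receive latent vectors in a
shared space; similarity between two drugs (or two targets) is the cosine
of their latents mapped into [0, 1] by (1 + cos)/2, which automatically
yields symmetric unit-diagonal matrices.  The interaction probability of a
pair is a logistic function of the drug-target latent cosine scaled by
``assoc_strength``, plus Gaussian noise — so similar drugs literally tend
to share targets ("guilt by association"), and at ``assoc_strength = 0``
interactions are independent of the similarities.  The logistic intercept
is calibrated by bisection so the realized density of Y matches the
requested density; a held-out fraction of the realized interactions is
zeroed in Y and returned separately as recoverable test links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .graph_core import DTINetwork

__all__ = ["SyntheticConfig", "generate_network"]

#: relative tolerance on the realized interaction density
_DENSITY_RTOL = 0.2
_MAX_REDRAWS = 25


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic network.

    ``density`` is the target fraction of 1-entries in Y after holdout
    removal; ``assoc_strength`` scales how strongly latent affinity (and
    hence similarity) drives interactions; ``noise`` is the SD of the
    Gaussian term added inside the logistic link.
    """

    m: int = 60
    n: int = 80
    latent_dim: int = 8
    density: float = 0.02
    assoc_strength: float = 4.0
    noise: float = 0.1
    seed: int = 0
    holdout_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.density < 0.5:
            raise ValueError("density must lie in (0, 0.5)")
        if self.m < 4 or self.n < 4:
            raise ValueError("m and n must be at least 4")
        if self.assoc_strength < 0:
            raise ValueError("assoc_strength must be non-negative")
        if not 0 <= self.noise <= 1:
            raise ValueError("noise must lie in [0, 1]")
        if not 0 <= self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in [0, 1)")


def _unit_rows(X: np.ndarray) -> np.ndarray:
    return X / np.linalg.norm(X, axis=1, keepdims=True)


def _cosine_similarity_matrix(U: np.ndarray) -> np.ndarray:
    S = (1.0 + U @ U.T) / 2.0
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_network(
    config: SyntheticConfig,
) -> tuple[DTINetwork, list[tuple[int, int]]]:
    """Generate one seeded network plus its held-out true interactions.

    Returns
    -------
    net
        Validated :class:`DTINetwork`; the held-out links are zeroed in Y.
    held_out
        (drug index, target index) pairs that truly interact under the
        generative model but are hidden from Y.
    """
    rng = np.random.default_rng(config.seed)
    U = _unit_rows(rng.normal(size=(config.m, config.latent_dim)))
    V = _unit_rows(rng.normal(size=(config.n, config.latent_dim)))
    S_D = _cosine_similarity_matrix(U)
    S_T = _cosine_similarity_matrix(V)

    affinity = U @ V.T  # drug-target latent cosine in [-1, 1]
    eta = config.assoc_strength * affinity + config.noise * rng.normal(
        size=affinity.shape
    )

    # pre-holdout density so that the post-holdout expectation hits target
    target_density = config.density / (1.0 - config.holdout_fraction)
    if target_density >= 1.0:
        raise ValueError("density unachievable at this holdout fraction")
    intercept = _calibrate_intercept(eta, target_density)
    p = expit(eta + intercept)

    want = config.density * config.m * config.n
    for _ in range(_MAX_REDRAWS):
        Y_full = (rng.uniform(size=p.shape) < p).astype(np.int8)
        positives = list(zip(*np.nonzero(Y_full)))
        n_hold = int(round(config.holdout_fraction * len(positives)))
        if abs(len(positives) - n_hold - want) <= _DENSITY_RTOL * want:
            break
    else:
        raise RuntimeError(
            "density calibration failure: realized interaction count never "
            f"reached {want:.0f} +/- {100 * _DENSITY_RTOL:.0f}%"
        )

    held_out: list[tuple[int, int]] = []
    if n_hold:
        picked = rng.choice(len(positives), size=n_hold, replace=False)
        held_out = [
            (int(positives[k][0]), int(positives[k][1])) for k in sorted(picked)
        ]
        Y = Y_full.copy()
        for i, j in held_out:
            Y[i, j] = 0
    else:
        Y = Y_full

    drug_ids = [f"D{i:04d}" for i in range(config.m)]
    target_ids = [f"T{j:04d}" for j in range(config.n)]
    return DTINetwork(drug_ids, target_ids, Y, S_D, S_T), held_out


def _calibrate_intercept(
    eta: np.ndarray, density: float, lo: float = -40.0, hi: float = 40.0
) -> float:
    """Bisection on the logistic intercept so that mean(expit(eta + b)) = density."""
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if expit(eta + mid).mean() < density:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
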