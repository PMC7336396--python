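"""Canned synthetic-data experiments.

Each function runs one complete study on generated networks under the
package's standard conditions (m=60 drugs, n=80 targets, interaction
density 0.02, association strength 4, noise 0.1, subgraph size K=10,
10-fold cross-validation) and returns summary numbers.  They back both the
test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .classifier import ClassifierConfig
from .evaluation import (
    CVReport,
    cross_validate,
    heuristic_cross_validate,
    with_identity_similarity,
)
from .negative_sampling import SamplingConfig, assemble_samples
from .pipeline import stage_seeds
from .synthetic_data import SyntheticConfig, generate_network

__all__ = [
    "planted_signal_experiment",
    "negative_sampling_experiment",
    "ablation_experiment",
    "null_control_experiment",
]

DEFAULT_K = 10
DEFAULT_FOLDS = 10


def _run_cv(net, samples, seed: int, K: int = DEFAULT_K,
            folds: int = DEFAULT_FOLDS) -> CVReport:
    return cross_validate(
        net, samples, K=K,
        classifier_config=ClassifierConfig(seed=seed),
        n_folds=folds, seed=seed,
    )


def planted_signal_experiment(
    seeds: tuple[int, ...] = (0, 1, 2), baseline: str = "PA"
) -> dict:
    """Balanced-sampling recovery of planted interactions vs a heuristic.

    For each seed: generate a network, assemble balanced samples with
    reliable negatives, cross-validate the learned pipeline, and score the
    identical folds with the preferential-attachment heuristic.
    """
    ours, base = [], []
    for seed in seeds:
        net_seed, sample_seed, cv_seed, _ = stage_seeds(seed)
        net, _ = generate_network(SyntheticConfig(seed=net_seed))
        samples = assemble_samples(
            net, SamplingConfig(ratio_alpha=1.0, seed=sample_seed)
        )
        ours.append(_run_cv(net, samples, cv_seed).mean_auroc)
        base.append(
            heuristic_cross_validate(
                net, samples, baseline, n_folds=DEFAULT_FOLDS, seed=cv_seed
            ).mean_auroc
        )
    return {
        "mean_auroc": float(np.mean(ours)),
        "baseline_mean_auroc": float(np.mean(base)),
        "per_seed_auroc": ours,
        "n_seeds": len(seeds),
    }


def negative_sampling_experiment(
    seeds: tuple[int, ...] = (0, 1, 2), ratio_alpha: float = 0.10
) -> dict:
    """Reliable vs random negative sampling at an imbalanced ratio."""
    reliable, random_ = [], []
    for seed in seeds:
        net_seed, sample_seed, cv_seed, _ = stage_seeds(seed)
        net, _ = generate_network(SyntheticConfig(seed=net_seed))
        cfg = SamplingConfig(ratio_alpha=ratio_alpha, seed=sample_seed)
        for mode, sink in (("reliable", reliable), ("random", random_)):
            samples = assemble_samples(net, cfg, mode=mode)
            sink.append(_run_cv(net, samples, cv_seed).mean_aupr)
    return {
        "reliable_mean_aupr": float(np.mean(reliable)),
        "random_mean_aupr": float(np.mean(random_)),
        "n_seeds": len(seeds),
    }


def ablation_experiment(seeds: tuple[int, ...] = (0, 1, 2)) -> dict:
    """All-networks vs interaction-only (similarities ablated to identity)."""
    full, dt_only = [], []
    for seed in seeds:
        net_seed, sample_seed, cv_seed, _ = stage_seeds(seed)
        net, _ = generate_network(SyntheticConfig(seed=net_seed))
        samples = assemble_samples(
            net, SamplingConfig(ratio_alpha=1.0, seed=sample_seed)
        )
        full.append(_run_cv(net, samples, cv_seed).mean_auroc)
        dt_only.append(
            _run_cv(with_identity_similarity(net), samples, cv_seed).mean_auroc
        )
    return {
        "all_networks_mean_auroc": float(np.mean(full)),
        "dt_only_mean_auroc": float(np.mean(dt_only)),
        "n_seeds": len(seeds),
    }


def null_control_experiment(seeds: tuple[int, ...] = tuple(range(10))) -> dict:
    """No-signal control: interactions independent of the similarities.

    Negatives are drawn at random — the clean null, since reliability
    ranking deliberately selects a distinguishable subpopulation even when
    the network carries no association signal.
    """
    aurocs = []
    for seed in seeds:
        net_seed, sample_seed, cv_seed, _ = stage_seeds(seed)
        net, _ = generate_network(
            SyntheticConfig(assoc_strength=0.0, seed=net_seed)
        )
        samples = assemble_samples(
            net, SamplingConfig(ratio_alpha=1.0, seed=sample_seed), mode="random"
        )
        aurocs.append(_run_cv(net, samples, cv_seed).mean_auroc)
    return {"mean_auroc": float(np.mean(aurocs)), "n_seeds": len(seeds)}
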