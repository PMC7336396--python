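"""End-to-end orchestration: sample -> extract -> order -> encode -> train
-> evaluate, with every intermediate artifact persisted and reloadable.

All randomness flows from one root seed, fanned out per stage via
``numpy.random.SeedSequence`` so runs are auditable and repeatable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import ClassifierConfig, DTIClassifier
from .encoding import embed_samples
from .evaluation import CVReport, cross_validate
from .graph_core import DTINetwork, load_network
from .negative_sampling import PairSample, SamplingConfig, assemble_samples

__all__ = [
    "RunConfig",
    "run_pipeline",
    "stage_seeds",
    "write_samples_tsv",
    "read_samples_tsv",
    "write_embeddings_tsv",
    "read_embeddings_tsv",
]

log = logging.getLogger("dtiwlnet")


def stage_seeds(root_seed: int, n: int = 4) -> list[int]:
    """Fan one root seed out into per-stage seeds (kept below 2**31)."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class RunConfig:
    """One reproducible evaluation run."""

    interaction_path: str | None = None
    drug_sim_path: str | None = None
    target_sim_path: str | None = None
    K: int = 10
    ratio_alpha: float | str = 1.0
    n_positives: int | str = "all"
    sampling_mode: str = "reliable"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    folds: int = 10
    seed: int = 0
    output_dir: str = "dtiwlnet-run"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")


def run_pipeline(config: RunConfig, net: DTINetwork | None = None) -> CVReport:
    """Execute the full pipeline and persist samples, embeddings, model and
    report under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if net is None:
        for p in (config.interaction_path, config.drug_sim_path, config.target_sim_path):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"network file missing: {p}")
        net = load_network(
            config.interaction_path, config.drug_sim_path, config.target_sim_path
        )
    log.info("network: %d drugs, %d targets, %d interactions",
             net.m, net.n, int(net.Y.sum()))

    sample_seed, clf_seed, cv_seed, _ = stage_seeds(config.seed)
    sampling = SamplingConfig(
        ratio_alpha=config.ratio_alpha,
        n_positives=config.n_positives,
        seed=sample_seed,
    )
    samples = assemble_samples(net, sampling, mode=config.sampling_mode)
    n_pos = sum(s.y for s in samples)
    log.info("samples: %d positives, %d negatives (mode=%s, seed=%d)",
             n_pos, len(samples) - n_pos, config.sampling_mode, sample_seed)
    write_samples_tsv(net, samples, out / "samples.tsv")

    X, y = embed_samples(net, samples, config.K)
    log.info("embeddings: %d x %d (K=%d)", *X.shape, config.K)
    write_embeddings_tsv(net, samples, X, out / "embeddings.tsv")

    clf_config = ClassifierConfig(**{**config.classifier.__dict__, "seed": clf_seed})
    report = cross_validate(
        net, samples, K=config.K, classifier_config=clf_config,
        n_folds=config.folds, seed=cv_seed,
    )
    log.info("CV: AUROC %.3f +/- %.3f, AUPR %.3f +/- %.3f",
             report.mean_auroc, report.sd_auroc, report.mean_aupr, report.sd_aupr)

    # final model trained on all samples, for downstream prediction
    clf = DTIClassifier(clf_config).fit(X, y)
    clf.save(out / "model.joblib")
    with open(out / "report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
    return report


# -- artifact serialization ---------------------------------------------------


def write_samples_tsv(net: DTINetwork, samples: list[PairSample], path) -> None:
    rows = [
        {
            "drug_id": net.drug_ids[s.drug_index],
            "target_id": net.target_ids[s.target_index],
            "label": s.label,
            "reliability": "" if s.reliability is None else repr(s.reliability),
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_samples_tsv(net: DTINetwork, path) -> list[PairSample]:
    df = pd.read_csv(path, sep="\t", dtype={"reliability": str}, keep_default_na=False)
    return [
        PairSample(
            net.drug_index(str(r.drug_id)),
            net.target_index(str(r.target_id)),
            str(r.label),
            float(r.reliability) if r.reliability else None,
        )
        for r in df.itertuples()
    ]


def write_embeddings_tsv(
    net: DTINetwork, samples: list[PairSample], X: np.ndarray, path
) -> None:
    df = pd.DataFrame(X, columns=[f"f{k}" for k in range(X.shape[1])])
    df.insert(0, "drug_id", [net.drug_ids[s.drug_index] for s in samples])
    df.insert(1, "target_id", [net.target_ids[s.target_index] for s in samples])
    df.insert(2, "label", [s.label for s in samples])
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def read_embeddings_tsv(path) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    feat_cols = [c for c in df.columns if c.startswith("f")]
    X = df[feat_cols].to_numpy(dtype=float)
    y = (df["label"] == "positive").to_numpy(dtype=int)
    return df[["drug_id", "target_id", "label"]], X, y
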