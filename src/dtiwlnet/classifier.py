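"""Fully-connected classifier over subgraph embedding vectors.

Three ReLU hidden layers of 32, 32 and 16 units map the K(K-1)/2-length
embedding to a 2-class probability (for two classes the logistic output is
numerically identical to a 2-way softmax).  Inputs already lie in [0, 1], so
no feature scaling is applied.  The remaining hyperparameters (adam,
learning rate 1e-3, batch size 32, up to 100 epochs with early stopping,
patience 10) are conventional defaults and fully overridable via
:class:`ClassifierConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.neural_network import MLPClassifier

__all__ = ["ClassifierConfig", "PredictionResult", "DTIClassifier", "train", "predict"]


@dataclass
class ClassifierConfig:
    hidden_sizes: tuple[int, int, int] = (32, 32, 16)
    activation: str = "relu"
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    early_stopping: bool = True
    patience: int = 10
    #: oversample the minority class to balance (off by default: training is
    #: run on the assembled ratio as-is, even at heavy imbalance)
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.hidden_sizes):
            raise ValueError("hidden layer sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass(frozen=True)
class PredictionResult:
    drug_index: int
    target_index: int
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


class DTIClassifier:
    """Seeded wrapper around an MLP with the fixed 32/32/16 architecture."""

    def __init__(self, config: ClassifierConfig | None = None) -> None:
        self.config = config or ClassifierConfig()
        self._mlp: MLPClassifier | None = None
        self._n_features: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DTIClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        if self.config.class_weighting:
            X, y = _oversample_minority(X, y, self.config.seed)
        cfg = self.config
        self._mlp = MLPClassifier(
            hidden_layer_sizes=tuple(cfg.hidden_sizes),
            activation=cfg.activation,
            solver="adam",
            learning_rate_init=cfg.learning_rate,
            batch_size=min(cfg.batch_size, len(y)),
            max_iter=cfg.epochs,
            early_stopping=cfg.early_stopping and len(y) >= 50,
            n_iter_no_change=cfg.patience,
            validation_fraction=0.1,
            random_state=cfg.seed,
        )
        self._n_features = X.shape[1]
        import warnings

        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            self._mlp.fit(X, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Interaction probability (positive-class component) per row."""
        if self._mlp is None:
            raise RuntimeError("classifier is not trained")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._n_features:
            raise ValueError(
                f"feature length {X.shape[1]} != training length {self._n_features}"
            )
        proba = self._mlp.predict_proba(X)
        return proba[:, list(self._mlp.classes_).index(1)]

    def save(self, path: str | Path) -> None:
        joblib.dump({"config": self.config, "mlp": self._mlp,
                     "n_features": self._n_features}, path)

    @classmethod
    def load(cls, path: str | Path) -> "DTIClassifier":
        state = joblib.load(path)
        clf = cls(state["config"])
        clf._mlp = state["mlp"]
        clf._n_features = state["n_features"]
        return clf


def _oversample_minority(
    X: np.ndarray, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    counts = {c: int((y == c).sum()) for c in np.unique(y)}
    majority = max(counts.values())
    parts_X, parts_y = [X], [y]
    for c, cnt in counts.items():
        if cnt < majority:
            idx = np.flatnonzero(y == c)
            extra = rng.choice(idx, size=majority - cnt, replace=True)
            parts_X.append(X[extra])
            parts_y.append(y[extra])
    return np.concatenate(parts_X), np.concatenate(parts_y)


def train(X: np.ndarray, y: np.ndarray, config: ClassifierConfig | None = None
          ) -> DTIClassifier:
    """Train the classifier on embedding vectors with 0/1 labels."""
    return DTIClassifier(config).fit(X, y)


def predict(
    model: DTIClassifier, X: np.ndarray, pairs: list[tuple[int, int]] | None = None
) -> list[PredictionResult]:
    """Score vectors; ``pairs`` supplies the (drug, target) indices reported."""
    proba = model.predict_proba(X)
    if pairs is None:
        pairs = [(-1, -1)] * len(proba)
    return [
        PredictionResult(i, j, float(p)) for (i, j), p in zip(pairs, proba)
    ]
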