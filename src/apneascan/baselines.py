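"""Feature-engineering comparison classifiers behind one fit/predict contract.

The four standard baselines — SVM (RBF), logistic regression, k-nearest
neighbours and a single-hidden-layer MLP — consume the 18-feature HRV vectors
(min-max normalized) rather than raw windows, providing the hand-crafted
counterpart to the CNN's automatic feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .ecg_io import APNEA, NORMAL

__all__ = ["BaselineConfig", "FittedBaseline", "fit_baseline", "predict_baseline"]

BASELINE_NAMES = ("svm", "lr", "knn", "mlp")


@dataclass
class BaselineConfig:
    """Which baseline to fit and its hyperparameters."""

    name: str
    seed: int = 0
    svm_c: float = 1.0
    svm_kernel: str = "rbf"
    knn_neighbors: int = 5
    mlp_hidden: tuple[int, ...] = (32,)
    mlp_max_iter: int = 500

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(f"unknown baseline {self.name!r}; choose from {BASELINE_NAMES}")
        if self.svm_c <= 0 or self.knn_neighbors < 1 or self.mlp_max_iter < 1:
            raise ValueError("hyperparameters must be positive")


@dataclass
class FittedBaseline:
    config: BaselineConfig
    estimator: object
    n_features: int


def _make_estimator(cfg: BaselineConfig):
    if cfg.name == "svm":
        return SVC(kernel=cfg.svm_kernel, C=cfg.svm_c, random_state=cfg.seed)
    if cfg.name == "lr":
        return LogisticRegression(max_iter=1000, random_state=cfg.seed)
    if cfg.name == "knn":
        return KNeighborsClassifier(n_neighbors=cfg.knn_neighbors)
    return MLPClassifier(
        hidden_layer_sizes=cfg.mlp_hidden,
        max_iter=cfg.mlp_max_iter,
        random_state=cfg.seed,
    )


def fit_baseline(cfg: BaselineConfig, x: np.ndarray, y) -> FittedBaseline:
    """Fit one baseline on normalized features and string A/N labels."""
    x = np.asarray(x, dtype=float)
    y_int = np.asarray([1 if lbl == APNEA else 0 for lbl in y])
    if len(np.unique(y_int)) < 2:
        raise ValueError("training set must contain both classes")
    est = _make_estimator(cfg)
    est.fit(x, y_int)
    return FittedBaseline(config=cfg, estimator=est, n_features=x.shape[1])


def predict_baseline(model: FittedBaseline, x: np.ndarray) -> tuple[tuple[str, ...], np.ndarray]:
    """Hard A/N labels plus a continuous apnea score usable for ROC/AUC."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} feature columns, got {x.shape}")
    est = model.estimator
    if hasattr(est, "predict_proba"):
        scores = est.predict_proba(x)[:, list(est.classes_).index(1)]
    else:
        scores = est.decision_function(x)
        if list(est.classes_) == [0, 1]:
            pass  # positive score already means apnea
        else:
            scores = -scores
    labels = tuple(APNEA if p == 1 else NORMAL for p in est.predict(x))
    return labels, np.asarray(scores, dtype=float)
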