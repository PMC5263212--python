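"""Extremely-randomized-trees superpixel classifier.

At every internal node the ensemble draws K candidate attributes, one
uniform random cut-point per attribute within the node's range, and keeps
the best-scoring split; class probability for a test point is the
arithmetic mean of the T trees' leaf class frequencies. Backed by
scikit-learn's ExtraTreesClassifier, which implements exactly this scheme
(no bootstrap: every tree sees the whole training set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

__all__ = ["ERTModel", "ert_train", "ert_predict_proba", "ert_predict"]


@dataclass
class ERTModel:
    """Trained extra-trees ensemble plus its hyperparameters."""

    T: int
    K: int
    n_min: int
    max_depth: int
    seed: int
    estimator: ExtraTreesClassifier = field(repr=False, default=None)
    classes_: np.ndarray = field(default=None)
    n_features: int = 0


def ert_train(X: np.ndarray, y: np.ndarray, T: int = 20, K: int = 5, n_min: int = 2,
              max_depth: int = 15, seed: int = 0, criterion: str = "entropy",
              class_weight: str | None = None) -> ERTModel:
    """Train the ensemble. K is capped at the number of features.

    criterion: "entropy" (Shannon information gain, default) or "gini".
    class_weight: None (default, no reweighting) or "balanced".
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("training requires a 2D X with at least 2 samples")
    if K > X.shape[1]:
        raise ValueError("K cannot exceed the number of features")
    est = ExtraTreesClassifier(
        n_estimators=T,
        criterion=criterion,
        max_features=K,
        min_samples_split=n_min,
        max_depth=max_depth,
        bootstrap=False,
        random_state=seed,
        class_weight=class_weight,
        n_jobs=1,
    ).fit(X, y)
    return ERTModel(T=T, K=K, n_min=n_min, max_depth=max_depth, seed=seed,
                    estimator=est, classes_=est.classes_, n_features=X.shape[1])


def _as_matrix(model: ERTModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature vector length {x.shape[1]} does not match "
            f"training dimension {model.n_features}"
        )
    return x


def ert_predict_proba(model: ERTModel, x: np.ndarray) -> np.ndarray:
    """Mean of per-tree leaf class frequencies; rows sum to 1.

    A 1D input returns a 1D probability vector over model.classes_.
    """
    squeeze = np.asarray(x).ndim == 1
    proba = model.estimator.predict_proba(_as_matrix(model, x))
    return proba[0] if squeeze else proba


def ert_predict(model: ERTModel, x: np.ndarray, threshold: float = 0.5,
                positive_class=1) -> np.ndarray | int:
    """Label prediction: positive iff P(positive) >= threshold.

    The >= convention means a probability exactly at the threshold is
    called positive.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    squeeze = np.asarray(x).ndim == 1
    proba = model.estimator.predict_proba(_as_matrix(model, x))
    pos_col = int(np.nonzero(model.classes_ == positive_class)[0][0])
    pred = (proba[:, pos_col] >= threshold).astype(int)
    if positive_class != 1:
        pred = np.where(pred == 1, positive_class, model.classes_[model.classes_ != positive_class][0])
    return int(pred[0]) if squeeze else pred
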