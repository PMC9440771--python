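"""Nearest-neighbour reference predictors.

AA-KNN predicts a label distribution as the mean of the k nearest training
distributions; plain KNN predicts a hard class by majority vote.  Both use
Euclidean distance; distance ties are broken by training index order and
vote ties by the lowest class index.  With extreme imbalance and large k,
plain KNN collapses to all-majority prediction — the pathology that makes
cost sensitivity worth having.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["AaKnn", "KnnClassifier"]


def _neighbor_indices(stored: np.ndarray, x: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest stored rows for each query row (stable ties)."""
    d = cdist(np.atleast_2d(x), stored)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


@dataclass
class AaKnn:
    """Algorithm-adapted KNN over label distributions."""

    k: int = 5
    features_: np.ndarray | None = None
    distributions_: np.ndarray | None = None

    def fit(self, X: np.ndarray, D: np.ndarray) -> "AaKnn":
        X = np.asarray(X, dtype=float)
        D = np.asarray(D, dtype=float)
        if self.k < 1 or self.k > X.shape[0]:
            raise ValueError(f"k={self.k} must be in [1, N={X.shape[0]}]")
        if D.shape[0] != X.shape[0]:
            raise ValueError("X and D row counts disagree")
        self.features_ = X
        self.distributions_ = D
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.features_ is None:
            raise RuntimeError("model not fitted")
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        idx = _neighbor_indices(self.features_, x, self.k)
        out = self.distributions_[idx].mean(axis=1)
        return out[0] if single else out


@dataclass
class KnnClassifier:
    """Instance-based hard classifier by majority vote."""

    k: int = 5
    features_: np.ndarray | None = None
    classes_: np.ndarray | None = None
    n_classes_: int | None = None

    def fit(self, X: np.ndarray, labels: np.ndarray) -> "KnnClassifier":
        X = np.asarray(X, dtype=float)
        lab = np.asarray(labels)
        classes = np.argmax(lab, axis=1) if lab.ndim == 2 else lab.astype(int)
        if self.k < 1 or self.k > X.shape[0]:
            raise ValueError(f"k={self.k} must be in [1, N={X.shape[0]}]")
        self.features_ = X
        self.classes_ = classes
        self.n_classes_ = (lab.shape[1] if lab.ndim == 2 else int(classes.max()) + 1)
        return self

    def predict(self, x: np.ndarray) -> int | np.ndarray:
        if self.features_ is None:
            raise RuntimeError("model not fitted")
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        idx = _neighbor_indices(self.features_, x, self.k)
        votes = np.stack([
            np.bincount(self.classes_[row], minlength=self.n_classes_) for row in idx
        ])
        pred = np.argmax(votes, axis=1)  # argmax ties -> lowest class index
        return int(pred[0]) if single else pred
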