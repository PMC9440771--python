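"""Evaluation measures for label distributions and hard multiclass decisions.

Six distribution measures (Chebyshev, Kullback-Leibler, Clark, Canberra,
intersection, cosine) compare a predicted simplex vector with the ground
truth; two multiclass measures (precision, macro-average precision) score
the hard argmax decision.  Every measure carries a direction: distances are
lower-is-better, similarities and the multiclass measures higher-is-better.
KL is asymmetric and is always evaluated as KL(truth || prediction).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "METRIC_DIRECTIONS",
    "MetricReport",
    "chebyshev",
    "kl_divergence",
    "clark",
    "canberra",
    "intersection",
    "cosine",
    "precision_metric",
    "macro_average_precision",
    "evaluate_all",
]

#: direction of each measure: "lower" = smaller is better, "higher" = larger is better
METRIC_DIRECTIONS = {
    "chebyshev": "lower",
    "kl": "lower",
    "clark": "lower",
    "canberra": "lower",
    "intersection": "higher",
    "cosine": "higher",
    "precision": "higher",
    "map": "higher",
}

_KL_CLIP = 1e-12


def _pair(d: np.ndarray, dhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.atleast_2d(np.asarray(d, dtype=float))
    dhat = np.atleast_2d(np.asarray(dhat, dtype=float))
    if d.shape != dhat.shape:
        raise ValueError("distribution shapes disagree")
    return d, dhat


def _reduce(values: np.ndarray, single: bool) -> float | np.ndarray:
    return float(values[0]) if single else values


def chebyshev(d: np.ndarray, dhat: np.ndarray) -> float | np.ndarray:
    """max_j |d_j - dhat_j| (Chebyshev distance, lower is better)."""
    single = np.asarray(d).ndim == 1
    d, dhat = _pair(d, dhat)
    return _reduce(np.max(np.abs(d - dhat), axis=1), single)


def kl_divergence(d: np.ndarray, dhat: np.ndarray) -> float | np.ndarray:
    """KL(truth || prediction) with dhat clipped below at 1e-12; 0 ln 0 = 0."""
    single = np.asarray(d).ndim == 1
    d, dhat = _pair(d, dhat)
    dhat = np.clip(dhat, _KL_CLIP, None)
    terms = np.where(d > 0, d * np.log(np.where(d > 0, d, 1.0) / dhat), 0.0)
    return _reduce(terms.sum(axis=1), single)


def clark(d: np.ndarray, dhat: np.ndarray) -> float | np.ndarray:
    """sqrt(sum_j (d_j - dhat_j)^2 / (d_j + dhat_j)^2); empty components contribute 0."""
    single = np.asarray(d).ndim == 1
    d, dhat = _pair(d, dhat)
    s = d + dhat
    terms = np.where(s > 0, ((d - dhat) / np.where(s > 0, s, 1.0)) ** 2, 0.0)
    return _reduce(np.sqrt(terms.sum(axis=1)), single)


def canberra(d: np.ndarray, dhat: np.ndarray) -> float | np.ndarray:
    """sum_j |d_j - dhat_j| / (d_j + dhat_j); empty components contribute 0."""
    single = np.asarray(d).ndim == 1
    d, dhat = _pair(d, dhat)
    s = d + dhat
    terms = np.where(s > 0, np.abs(d - dhat) / np.where(s > 0, s, 1.0), 0.0)
    return _reduce(terms.sum(axis=1), single)


def intersection(d: np.ndarray, dhat: np.ndarray) -> float | np.ndarray:
    """sum_j min(d_j, dhat_j) (histogram intersection, higher is better)."""
    single = np.asarray(d).ndim == 1
    d, dhat = _pair(d, dhat)
    return _reduce(np.minimum(d, dhat).sum(axis=1), single)


def cosine(d: np.ndarray, dhat: np.ndarray) -> float | np.ndarray:
    """(d . dhat) / (||d|| ||dhat||) (cosine similarity, higher is better)."""
    single = np.asarray(d).ndim == 1
    d, dhat = _pair(d, dhat)
    num = (d * dhat).sum(axis=1)
    den = np.linalg.norm(d, axis=1) * np.linalg.norm(dhat, axis=1)
    if np.any(den == 0):
        raise ValueError("cosine undefined for an all-zero vector")
    return _reduce(num / den, single)


def _as_classes(labels: np.ndarray) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.ndim == 2:
        return np.argmax(lab, axis=1)
    return lab.astype(int)


def precision_metric(true_labels: np.ndarray, predicted_classes: np.ndarray) -> float:
    """Fraction of samples whose predicted class matches the true class exactly."""
    truth = _as_classes(true_labels)
    pred = np.asarray(predicted_classes, dtype=int)
    if truth.shape != pred.shape:
        raise ValueError("label shapes disagree")
    return float(np.mean(truth == pred))


def macro_average_precision(
    true_labels: np.ndarray, predicted_classes: np.ndarray, n_classes: int
) -> float:
    """Macro average of per-class precision P_j over the K classes.

    P_j = (# class-j samples predicted j) / (# class-j samples).  Classes
    absent from the truth set are excluded from the mean, so a 3-class set
    predicted entirely as the majority class scores exactly 1/3.
    """
    truth = _as_classes(true_labels)
    pred = np.asarray(predicted_classes, dtype=int)
    per_class = []
    for j in range(n_classes):
        mask = truth == j
        if mask.any():
            per_class.append(float(np.mean(pred[mask] == j)))
    if not per_class:
        raise ValueError("no classes present in the truth set")
    return float(np.mean(per_class))


@dataclass
class MetricReport:
    """Sample-averaged distribution measures plus the two multiclass measures."""

    chebyshev: float
    kl: float
    clark: float
    canberra: float
    intersection: float
    cosine: float
    precision: float
    map: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def evaluate_all(
    D_true: np.ndarray,
    D_pred: np.ndarray,
    true_labels: np.ndarray,
    n_classes: int,
) -> MetricReport:
    """Full metric report: distribution measures averaged over samples, hard
    measures from the argmax of the predicted distributions."""
    D_true = np.asarray(D_true, dtype=float)
    D_pred = np.asarray(D_pred, dtype=float)
    pred_classes = np.argmax(D_pred, axis=1)
    return MetricReport(
        chebyshev=float(np.mean(chebyshev(D_true, D_pred))),
        kl=float(np.mean(kl_divergence(D_true, D_pred))),
        clark=float(np.mean(clark(D_true, D_pred))),
        canberra=float(np.mean(canberra(D_true, D_pred))),
        intersection=float(np.mean(intersection(D_true, D_pred))),
        cosine=float(np.mean(cosine(D_true, D_pred))),
        precision=precision_metric(true_labels, pred_classes),
        map=macro_average_precision(true_labels, pred_classes, n_classes),
    )
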