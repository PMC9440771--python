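"""Functional-connectivity features from ROI time series.

A subject's T x R time-series matrix is reduced to the R x R matrix of
pairwise Pearson correlations between ROIs; the strictly-upper-triangular
entries, concatenated row-major, form the subject's feature vector of
length q = R(R-1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import SubjectRecord

__all__ = [
    "FcMatrix",
    "FeatureMatrix",
    "pearson_fc_matrix",
    "upper_triangle_vector",
    "build_feature_matrix",
    "pair_names",
    "write_features",
    "read_features",
]


@dataclass
class FcMatrix:
    """Pearson functional-connectivity matrix for one subject."""

    values: np.ndarray  # R x R
    roi_count: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != self.roi_count:
            raise ValueError("values must be a square R x R matrix")
        self.values = v


@dataclass
class FeatureMatrix:
    """Subjects x q feature matrix with aligned subject ids."""

    values: np.ndarray  # N x q
    subject_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.subject_ids):
            raise ValueError("row count must match subject_ids")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def pearson_fc_matrix(time_series: np.ndarray) -> FcMatrix:
    """Pairwise Pearson correlation between the columns (ROIs) of a series.

    Raises if the series has fewer than 3 time points or any ROI has zero
    sample variance (a dead ROI would silently produce NaNs otherwise).
    """
    ts = np.asarray(time_series, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time_series must be a T x R matrix")
    t, r = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    variances = ts.var(axis=0)
    dead = np.flatnonzero(variances == 0)
    if dead.size:
        raise ValueError(f"constant time series at ROI index(es) {dead.tolist()}")
    corr = np.corrcoef(ts, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return FcMatrix(values=corr, roi_count=r)


def upper_triangle_vector(fc: FcMatrix) -> np.ndarray:
    """Strictly-upper-triangular entries of the FC matrix, row-major.

    Order: (r12, r13, ..., r1R, r23, ..., r(R-1)R); length R(R-1)/2.
    """
    iu = np.triu_indices(fc.roi_count, k=1)
    return fc.values[iu].copy()


def pair_names(n_rois: int) -> list[str]:
    """Column names for the vectorized upper triangle ("roi1-roi2", ...)."""
    a, b = np.triu_indices(n_rois, k=1)
    return [f"roi{i + 1}-roi{j + 1}" for i, j in zip(a, b)]


def build_feature_matrix(records: Sequence[SubjectRecord]) -> FeatureMatrix:
    """Stack each subject's vectorized FC upper triangle, preserving order."""
    if not records:
        raise ValueError("no subjects")
    r = records[0].time_series.shape[1]
    rows = []
    for rec in records:
        if rec.time_series.shape[1] != r:
            raise ValueError(
                f"subject {rec.subject_id} has {rec.time_series.shape[1]} ROIs, "
                f"expected {r}"
            )
        rows.append(upper_triangle_vector(pearson_fc_matrix(rec.time_series)))
    return FeatureMatrix(values=np.vstack(rows), subject_ids=[rec.subject_id for rec in records])


def write_features(features: FeatureMatrix, path: str | Path, n_rois: int | None = None) -> None:
    """Write a features CSV: subject_id column + one column per ROI pair."""
    q = features.n_features
    if n_rois is None:
        n_rois = int(round((1 + np.sqrt(1 + 8 * q)) / 2))
    cols = pair_names(n_rois) if n_rois * (n_rois - 1) // 2 == q else [f"f{i}" for i in range(q)]
    df = pd.DataFrame(features.values, columns=cols)
    df.insert(0, "subject_id", features.subject_ids)
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    ids = df["subject_id"].astype(str).tolist()
    return FeatureMatrix(values=df.drop(columns="subject_id").to_numpy(float), subject_ids=ids)
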