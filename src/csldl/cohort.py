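"""Synthetic ABIDE-like cohort generation.

Emulates imbalanced multiclass resting-state fMRI cohorts (e.g. Normal /
Autism / Asperger's syndrome) at the level of per-subject ROI time series.
Each subject's series is drawn from a zero-mean multivariate normal whose
correlation matrix is a shared AR(1)-style base plus a class-specific block
perturbation, so classes differ only in their connectivity structure — the
premise under which functional-connectivity features carry the diagnostic
signal.  Observed one-hot labels can be corrupted by injectable label noise
while the ground-truth class is kept for scoring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "generate_cohort",
    "inject_label_noise",
    "write_cohort",
    "read_cohort",
    "class_correlation_matrix",
]

_BASE_RHO = 0.3  # lag-1 autocorrelation of the shared AR(1)-style base matrix
_MIN_EIG = 1e-6  # eigenvalue floor when projecting to a valid correlation matrix


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for one synthetic cohort.

    Parameters
    ----------
    class_sizes
        Subjects per diagnostic class; its length sets K.  The bundled
        defaults elsewhere mirror real multi-site compositions such as
        52 subjects split 37/7/8.
    n_rois
        Number of brain parcels R (default 90, an AAL-like parcellation count).
    n_timepoints
        Scan length T in volumes (default 150).
    separation
        Magnitude of the class-specific perturbation added to a disjoint
        block of correlation entries; 0 means all classes share one
        connectivity structure (no signal).
    noise_rate
        Fraction of subjects whose observed one-hot label is flipped to a
        different class.
    adjacent_only_noise
        If True, flips occur only between the two ASD subcategories
        (classes 1 and 2), mimicking blurred subcategory boundaries.
    """

    class_sizes: tuple[int, ...]
    n_rois: int = 90
    n_timepoints: int = 150
    separation: float = 0.0
    noise_rate: float = 0.0
    adjacent_only_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.class_sizes)
        object.__setattr__(self, "class_sizes", sizes)
        if len(sizes) < 2:
            raise ValueError("need at least 2 classes")
        if any(s < 1 for s in sizes):
            raise ValueError(f"all class sizes must be >= 1, got {sizes}")
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")

    @property
    def n_classes(self) -> int:
        return len(self.class_sizes)

    @property
    def n_subjects(self) -> int:
        return sum(self.class_sizes)


@dataclass
class SubjectRecord:
    """One simulated subject: ROI time series plus true and observed labels."""

    subject_id: str
    time_series: np.ndarray  # T x R
    true_class: int
    observed_logical_label: np.ndarray  # one-hot, length K

    def __post_init__(self) -> None:
        lab = np.asarray(self.observed_logical_label)
        if lab.ndim != 1 or int(lab.sum()) != 1 or not np.isin(lab, (0, 1)).all():
            raise ValueError("observed_logical_label must be one-hot")


def _nearest_correlation(mat: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at a small positive floor and the diagonal is
    renormalized to 1.
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, _MIN_EIG, None)
    pos = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(pos))
    corr = pos / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    min_eig = np.linalg.eigvalsh((corr + corr.T) / 2.0).min()
    if min_eig <= 0:
        raise ValueError(
            f"projection failed to produce a positive-definite correlation "
            f"matrix (min eigenvalue {min_eig:.3e}); reduce `separation`"
        )
    return corr


def class_correlation_matrix(
    n_rois: int, n_classes: int, class_index: int, separation: float
) -> np.ndarray:
    """Target ROI correlation matrix for one class.

    Base matrix: AR(1)-style, entry (a, b) = 0.3^|a-b|.  Class c perturbs a
    disjoint block of ROIs (block c of K contiguous blocks) by adding
    +separation to its within-block off-diagonal entries, then the result is
    projected back to a valid correlation matrix.
    """
    if not 0 <= class_index < n_classes:
        raise ValueError("class_index out of range")
    idx = np.arange(n_rois)
    base = _BASE_RHO ** np.abs(idx[:, None] - idx[None, :])
    if separation == 0:
        return base
    bounds = np.linspace(0, n_rois, n_classes + 1).astype(int)
    lo, hi = bounds[class_index], bounds[class_index + 1]
    if hi - lo < 2:
        raise ValueError(
            f"class block {class_index} spans fewer than 2 ROIs "
            f"(n_rois={n_rois}, n_classes={n_classes}); increase n_rois"
        )
    pert = base.copy()
    block = np.s_[lo:hi, lo:hi]
    pert[block] = np.clip(pert[block] + separation, -0.99, 0.99)
    np.fill_diagonal(pert, 1.0)
    return _nearest_correlation(pert)


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw a full cohort; a pure, bit-reproducible function of the config.

    Subjects are emitted class by class; class c contributes exactly
    ``config.class_sizes[c]`` subjects.  Label noise at ``config.noise_rate``
    is injected afterwards with a seed derived from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    k = config.n_classes
    sid = 0
    for c, size in enumerate(config.class_sizes):
        corr = class_correlation_matrix(config.n_rois, k, c, config.separation)
        chol = np.linalg.cholesky(corr)
        for _ in range(size):
            z = rng.standard_normal((config.n_timepoints, config.n_rois))
            series = z @ chol.T
            # degenerate draws are astronomically unlikely but would poison
            # Pearson features downstream, so regenerate defensively
            while np.any(series.std(axis=0) == 0):
                z = rng.standard_normal((config.n_timepoints, config.n_rois))
                series = z @ chol.T
            label = np.zeros(k, dtype=int)
            label[c] = 1
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{sid:04d}",
                    time_series=series,
                    true_class=c,
                    observed_logical_label=label,
                )
            )
            sid += 1
    if config.noise_rate > 0:
        records = inject_label_noise(
            records,
            config.noise_rate,
            seed=config.seed + 1,
            adjacent_only=config.adjacent_only_noise,
        )
    return records


def inject_label_noise(
    records: list[SubjectRecord],
    noise_rate: float,
    seed: int,
    adjacent_only: bool = False,
) -> list[SubjectRecord]:
    """Flip the observed labels of floor(noise_rate * N) subjects.

    Flip targets are drawn uniformly from the other K-1 classes;
    ``true_class`` is never touched, so noise recovery can be scored.  With
    ``adjacent_only`` the flips swap only the two ASD subcategory labels
    (class 1 <-> class 2) and only subjects observed in those classes are
    eligible.
    """
    if not 0 <= noise_rate < 1:
        raise ValueError("noise_rate must be in [0, 1)")
    out = [dataclasses.replace(r, observed_logical_label=r.observed_logical_label.copy())
           for r in records]
    n = len(out)
    n_flip = int(np.floor(noise_rate * n))
    if n_flip == 0:
        return out
    k = out[0].observed_logical_label.size
    rng = np.random.default_rng(seed)
    if adjacent_only:
        if k < 3:
            raise ValueError("adjacent-only noise needs at least 3 classes")
        eligible = [i for i, r in enumerate(out)
                    if int(np.argmax(r.observed_logical_label)) in (1, 2)]
        n_flip = min(n_flip, len(eligible))
        chosen = rng.choice(eligible, size=n_flip, replace=False)
        for i in chosen:
            cur = int(np.argmax(out[i].observed_logical_label))
            new = 3 - cur  # 1 <-> 2
            label = np.zeros(k, dtype=int)
            label[new] = 1
            out[i].observed_logical_label = label
        return out
    chosen = rng.choice(n, size=n_flip, replace=False)
    for i in chosen:
        cur = int(np.argmax(out[i].observed_logical_label))
        others = [c for c in range(k) if c != cur]
        new = int(rng.choice(others))
        label = np.zeros(k, dtype=int)
        label[new] = 1
        out[i].observed_logical_label = label
    return out


def write_cohort(records: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write per-subject time-series CSVs plus a cohort manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = records[0].observed_logical_label.size
    rows = []
    for rec in records:
        pd.DataFrame(rec.time_series).to_csv(
            out / f"{rec.subject_id}.csv", index=False, header=False
        )
        row = {"subject_id": rec.subject_id, "true_class": rec.true_class}
        for j in range(k):
            row[f"label_{j}"] = int(rec.observed_logical_label[j])
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(in_dir: str | Path) -> list[SubjectRecord]:
    """Load a cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    label_cols = [c for c in manifest.columns if c.startswith("label_")]
    records = []
    for _, row in manifest.iterrows():
        series = pd.read_csv(in_dir / f"{row.subject_id}.csv", header=None).to_numpy(float)
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                time_series=series,
                true_class=int(row.true_class),
                observed_logical_label=np.array([int(row[c]) for c in label_cols]),
            )
        )
    return records
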