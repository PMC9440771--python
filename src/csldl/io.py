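"""CSV readers/writers for labels and label distributions.

Both formats are a ``subject_id`` column followed by K numeric columns
(``label_0..`` for one-hot logical labels, ``d_0..`` for simplex rows).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_labels", "read_labels", "write_distributions", "read_distributions"]


def write_labels(labels: np.ndarray, subject_ids: list[str], path: str | Path) -> None:
    lab = np.asarray(labels, dtype=int)
    df = pd.DataFrame(lab, columns=[f"label_{j}" for j in range(lab.shape[1])])
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    ids = df["subject_id"].astype(str).tolist()
    lab = df.drop(columns="subject_id").to_numpy(int)
    if not np.all(lab.sum(axis=1) == 1):
        raise ValueError(f"{path}: labels must be one-hot rows")
    return lab, ids


def write_distributions(D: np.ndarray, subject_ids: list[str], path: str | Path) -> None:
    D = np.asarray(D, dtype=float)
    df = pd.DataFrame(D, columns=[f"d_{j}" for j in range(D.shape[1])])
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, index=False)


def read_distributions(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    ids = df["subject_id"].astype(str).tolist()
    D = df.drop(columns="subject_id").to_numpy(float)
    if np.any(D < 0) or np.any(np.abs(D.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError(f"{path}: rows must lie on the probability simplex")
    return D, ids
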