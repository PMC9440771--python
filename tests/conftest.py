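import numpy as np
import pytest

from csldl import CohortConfig, build_feature_matrix, generate_cohort


@pytest.fixture(scope="session")
def separated_cohort():
    """Three-class cohort whose classes form distinct blobs in FC-feature space.

    Long scans (T=1200) shrink the Pearson sampling noise and a strong block
    perturbation (0.6) pushes the class centroids far apart relative to the
    within-class spread, so fuzzy clustering can resolve the class structure.
    """
    cfg = CohortConfig(
        class_sizes=(60, 50, 40),
        n_rois=12,
        n_timepoints=1200,
        separation=0.6,
        seed=1,
    )
    records = generate_cohort(cfg)
    features = build_feature_matrix(records)
    labels = np.stack([r.observed_logical_label for r in records])
    return records, features, labels


@pytest.fixture(scope="session")
def kki_like_cohort():
    """Small imbalanced cohort mirroring a 37/7/8 site composition."""
    cfg = CohortConfig(
        class_sizes=(37, 7, 8),
        n_rois=12,
        n_timepoints=600,
        separation=0.6,
        seed=2,
    )
    records = generate_cohort(cfg)
    features = build_feature_matrix(records)
    labels = np.stack([r.observed_logical_label for r in records])
    return records, features, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_simplex(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Uniform Dirichlet(1,...,1) rows."""
    g = rng.gamma(1.0, size=(n, k))
    return g / g.sum(axis=1, keepdims=True)
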