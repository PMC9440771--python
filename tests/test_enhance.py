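import numpy as np
import pytest

from csldl import (
    LabelEnhancer,
    build_association_matrix,
    enhance_labels,
    fcm_fit,
    fcm_membership,
    fuzzy_compose,
    kl_divergence,
)


class TestFcmMembership:
    def test_hand_worked_one_dimensional_example(self):
        # centers {0,1}, beta=2, x=0.25: m1 = 1/(1 + 0.25/0.75) = 0.75
        m = fcm_membership(np.array([0.25]), np.array([[0.0], [1.0]]), beta=2.0)
        np.testing.assert_allclose(m, [0.75, 0.25], atol=1e-12)

    def test_point_on_center_gets_indicator(self):
        centers = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        m = fcm_membership(np.array([1.0, 1.0]), centers, beta=2.0)
        np.testing.assert_array_equal(m, [0.0, 1.0, 0.0])

    def test_tie_between_coincident_centers_is_uniform(self):
        centers = np.array([[1.0], [1.0], [5.0]])
        m = fcm_membership(np.array([1.0]), centers, beta=2.0)
        np.testing.assert_allclose(m, [0.5, 0.5, 0.0])

    def test_equidistant_point_gets_uniform_membership(self):
        centers = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        m = fcm_membership(np.zeros(2), centers, beta=3.0)
        np.testing.assert_allclose(m, np.full(4, 0.25), atol=1e-12)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            fcm_membership(np.zeros(1), np.array([[0.0], [1.0]]), beta=1.0)


class TestFcmFit:
    def test_recovers_blob_means_in_one_dimension(self, rng):
        x = np.concatenate([rng.normal(0.0, 0.02, 40), rng.normal(1.0, 0.02, 40)])[:, None]
        model = fcm_fit(x, p=2, beta=2.0, tol=1e-12, seed=0)
        centers = np.sort(model.centers.ravel())
        blob_means = np.sort([x[:40].mean(), x[40:].mean()])
        np.testing.assert_allclose(centers, blob_means, atol=0.05)

    def test_objective_trace_non_increasing_on_blob_data(self, rng):
        x = np.vstack([rng.normal(c, 0.3, size=(40, 3)) for c in (0.0, 4.0, -4.0)])
        model = fcm_fit(x, p=3, beta=2.0, tol=1e-12, seed=1)
        trace = np.asarray(model.objective_trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-9)

    def test_memberships_rows_on_simplex(self, rng):
        x = rng.normal(size=(30, 4))
        model = fcm_fit(x, p=3, seed=0)
        assert model.memberships.min() >= 0
        np.testing.assert_allclose(model.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_final_memberships_consistent_with_final_centers(self, rng):
        x = rng.normal(size=(25, 3))
        model = fcm_fit(x, p=4, beta=2.5, seed=3)
        recomputed = np.stack([
            fcm_membership(row, model.centers, 2.5) for row in x
        ])
        np.testing.assert_allclose(model.memberships, recomputed, atol=1e-9)

    def test_degenerate_duplicate_input_flagged(self):
        x = np.ones((10, 2))
        with pytest.raises(ValueError, match="distinct"):
            fcm_fit(x, p=2)

    def test_parameter_validation(self, rng):
        x = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            fcm_fit(x, p=6)
        with pytest.raises(ValueError):
            fcm_fit(x, p=2, beta=1.0)
        with pytest.raises(ValueError):
            fcm_fit(x, p=1)


class TestAssociationMatrix:
    def test_single_sample_per_class_is_identity_of_rows(self):
        memberships = np.array([[0.6, 0.4], [0.1, 0.9]])
        labels = np.eye(2, dtype=int)
        np.testing.assert_allclose(build_association_matrix(memberships, labels), memberships)

    def test_hand_averaged_row(self):
        # class 0 has memberships (0.8,0.2) and (0.6,0.4) -> row (1.4,0.6)/2
        memberships = np.array([[0.8, 0.2], [0.6, 0.4], [0.3, 0.7]])
        labels = np.array([[1, 0], [1, 0], [0, 1]])
        a = build_association_matrix(memberships, labels)
        np.testing.assert_allclose(a[0], [0.7, 0.3], atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        memberships = rng.dirichlet(np.ones(4), size=20)
        labels = np.eye(3, dtype=int)[rng.integers(0, 3, 20)]
        a = build_association_matrix(memberships, labels)
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_class_error_names_the_class(self):
        memberships = np.full((4, 2), 0.5)
        labels = np.array([[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0]])
        with pytest.raises(ValueError, match=r"\[2\]"):
            build_association_matrix(memberships, labels)


class TestFuzzyCompose:
    def test_identity_association_sum_product_returns_membership(self):
        m = np.array([0.2, 0.5, 0.3])
        np.testing.assert_allclose(fuzzy_compose(np.eye(3), m, "sum_product"), m)

    def test_sum_product_hand_example(self):
        a = np.array([[0.8, 0.2], [0.3, 0.7]])
        out = fuzzy_compose(a, np.array([0.9, 0.1]), "sum_product")
        np.testing.assert_allclose(out, [0.74, 0.34], atol=1e-12)

    def test_max_min_hand_example(self):
        a = np.array([[0.8, 0.2], [0.3, 0.7]])
        out = fuzzy_compose(a, np.array([0.9, 0.1]), "max_min")
        np.testing.assert_allclose(out, [0.8, 0.3], atol=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            fuzzy_compose(np.eye(2), np.array([0.5, 0.5]), "owa")


class TestEnhanceLabels:
    def test_rows_on_simplex(self, kki_like_cohort):
        _, features, labels = kki_like_cohort
        d = enhance_labels(features.values, labels, seed=0)
        assert d.shape == labels.shape
        assert d.min() >= 0
        np.testing.assert_allclose(d.sum(axis=1), 1.0, atol=1e-9)

    def test_tight_blobs_give_dominant_true_class_description(self, rng):
        # p=K clusters aligned with classes, large separation: the true class
        # should carry most of the description degree
        centers = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
        x = np.vstack([rng.normal(c, 0.05, size=(30, 2)) for c in centers])
        labels = np.repeat(np.eye(3, dtype=int), 30, axis=0)
        d = enhance_labels(x, labels, seed=0, tol=1e-12)
        truth = np.argmax(labels, axis=1)
        assert d[np.arange(90), truth].mean() > 0.9

    def test_argmax_matches_labels_at_least_as_often_as_centroid_classifier(
        self, separated_cohort
    ):
        _, features, labels = separated_cohort
        x = features.values
        truth = np.argmax(labels, axis=1)
        cents = np.stack([x[truth == c].mean(axis=0) for c in range(3)])
        centroid_pred = np.argmin(
            np.linalg.norm(x[:, None, :] - cents[None], axis=2), axis=1
        )
        centroid_acc = np.mean(centroid_pred == truth)
        d = enhance_labels(x, labels, seed=0, tol=1e-12)
        assert np.mean(np.argmax(d, axis=1) == truth) >= centroid_acc

    def test_restart_insensitivity_on_separated_data(self, separated_cohort):
        _, features, labels = separated_cohort
        runs = [
            enhance_labels(features.values, labels, seed=s, tol=1e-12)
            for s in range(3)
        ]
        for other in runs[1:]:
            assert np.max(np.abs(runs[0] - other)) <= 1e-6
            assert np.max(kl_divergence(runs[0], other)) <= 1e-6

    def test_transform_extends_to_unseen_points(self, separated_cohort):
        _, features, labels = separated_cohort
        enh = LabelEnhancer(seed=0).fit(features.values[:120], labels[:120])
        d = enh.transform(features.values[120:])
        np.testing.assert_allclose(d.sum(axis=1), 1.0, atol=1e-9)
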