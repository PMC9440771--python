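import dataclasses

import numpy as np
import pytest

from csldl import (
    CsldsvrModel,
    CsldsvrParams,
    KernelSpec,
    compute_class_weights,
    fit,
    kernel_matrix,
    kl_divergence,
    predict_class,
    predict_distribution,
)
from tests.conftest import random_simplex


class TestKernelMatrix:
    def test_gaussian_self_similarity_is_one(self, rng):
        a = rng.normal(size=(1, 5))
        k = kernel_matrix(KernelSpec("gaussian", gaussian_bandwidth=0.7), a, a)
        assert k[0, 0] == pytest.approx(1.0, abs=1e-15)

    def test_linear_on_orthogonal_vectors_is_zero(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.0, 3.0]])
        assert kernel_matrix(KernelSpec("linear"), a, b)[0, 0] == 0.0

    def test_gaussian_unit_distance_closed_form(self):
        a = np.array([[0.0]])
        b = np.array([[1.0]])
        k = kernel_matrix(KernelSpec("gaussian", gaussian_bandwidth=1.0), a, b)
        assert k[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_polynomial_closed_form(self):
        a = np.array([[1.0, 2.0]])
        b = np.array([[3.0, 0.5]])
        k = kernel_matrix(KernelSpec("polynomial", poly_degree=3, poly_coef0=1.0), a, b)
        assert k[0, 0] == pytest.approx((1 * 3 + 2 * 0.5 + 1.0) ** 3, abs=1e-10)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            KernelSpec("gaussian")
        with pytest.raises(ValueError):
            KernelSpec("gaussian", gaussian_bandwidth=-1.0)
        with pytest.raises(ValueError):
            KernelSpec("linear", gaussian_bandwidth=1.0)
        with pytest.raises(ValueError):
            KernelSpec("sigmoid")


class TestClassWeights:
    def test_balanced_classes_always_uniform(self):
        labels = np.repeat(np.eye(3, dtype=int), 10, axis=0)
        for flag in (True, False):
            w = compute_class_weights(labels, flag)
            np.testing.assert_allclose(w.per_class, 1.0)

    def test_imbalanced_site_composition_weights(self):
        # N_j = (37, 7, 8): w_j = N/(K N_j) = (52/111, 52/21, 52/24)
        labels = np.repeat(np.eye(3, dtype=int), (37, 7, 8), axis=0)
        w = compute_class_weights(labels, cost_sensitive=True)
        np.testing.assert_allclose(w.per_class, [52 / 111, 52 / 21, 52 / 24], atol=1e-12)

    def test_mean_per_sample_weight_is_one(self, rng):
        labels = np.eye(4, dtype=int)[rng.integers(0, 4, 100)]
        w = compute_class_weights(labels, cost_sensitive=True)
        assert w.per_sample.mean() == pytest.approx(1.0, abs=1e-12)

    def test_empty_class_rejected(self):
        labels = np.array([[1, 0, 0], [0, 1, 0]])
        with pytest.raises(ValueError):
            compute_class_weights(labels, True)


@pytest.fixture(scope="module")
def tiny_problem():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(40, 6))
    d = random_simplex(rng, 40, 3)
    labels = np.eye(3, dtype=int)[np.argmax(d, axis=1)]
    return x, d, labels


class TestFit:
    def test_constant_distribution_reproduced_everywhere(self, rng):
        dstar = np.array([0.2, 0.5, 0.3])
        x = rng.normal(size=(30, 5))
        d = np.tile(dstar, (30, 1))
        labels = np.eye(3, dtype=int)[rng.integers(0, 3, 30)]
        params = CsldsvrParams(kernel=KernelSpec("gaussian", gaussian_bandwidth=2.0))
        model = fit(x, d, labels, params)
        pred = predict_distribution(model, rng.normal(size=(10, 5)))
        assert np.max(kl_divergence(np.tile(dstar, (10, 1)), pred)) < 1e-3

    def test_objective_trace_monotone_decreasing(self, tiny_problem):
        x, d, labels = tiny_problem
        model = fit(x, d, labels, CsldsvrParams(C=10.0))
        trace = np.asarray(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8)

    def test_deterministic_given_same_inputs(self, tiny_problem):
        x, d, labels = tiny_problem
        params = CsldsvrParams(C=5.0, kernel=KernelSpec("gaussian", gaussian_bandwidth=3.0))
        m1 = fit(x, d, labels, params, seed=1)
        m2 = fit(x, d, labels, params, seed=99)
        np.testing.assert_allclose(m1.dual_coefficients, m2.dual_coefficients, atol=1e-10)
        np.testing.assert_allclose(m1.biases, m2.biases, atol=1e-10)

    def test_uniform_flag_matches_cost_sensitive_when_balanced(self, rng):
        x = rng.normal(size=(30, 4))
        d = random_simplex(rng, 30, 3)
        labels = np.repeat(np.eye(3, dtype=int), 10, axis=0)
        base = CsldsvrParams(C=2.0)
        m_cs = fit(x, d, labels, dataclasses.replace(base, cost_sensitive=True))
        m_u = fit(x, d, labels, dataclasses.replace(base, cost_sensitive=False))
        np.testing.assert_allclose(m_cs.dual_coefficients, m_u.dual_coefficients, atol=1e-12)
        assert m_cs.objective_trace[-1] == pytest.approx(m_u.objective_trace[-1], abs=1e-12)

    def test_larger_c_never_increases_training_loss(self, tiny_problem):
        # regularization-path sanity on a tiny instance
        from scipy.special import logit

        x, d, labels = tiny_problem
        clip = 1e-3
        targets = logit(np.clip(d, clip, 1 - clip))

        def loss_term(model, eps):
            f = model.decision_scores(x)
            r = np.linalg.norm(targets - f, axis=1)
            return float((np.maximum(r - eps, 0.0) ** 2).sum())

        params1 = CsldsvrParams(C=1.0, epsilon=0.01, cost_sensitive=False)
        params2 = dataclasses.replace(params1, C=2.0)
        l1 = loss_term(fit(x, d, labels, params1), 0.01)
        l2 = loss_term(fit(x, d, labels, params2), 0.01)
        assert l2 <= l1 + 1e-6

    def test_non_simplex_targets_rejected(self, rng):
        x = rng.normal(size=(5, 2))
        d = np.full((5, 3), 0.5)
        labels = np.eye(3, dtype=int)[[0, 1, 2, 0, 1]]
        with pytest.raises(ValueError, match="simplex"):
            fit(x, d, labels, CsldsvrParams())


class TestPredict:
    def test_distribution_is_on_simplex(self, tiny_problem, rng):
        x, d, labels = tiny_problem
        model = fit(x, d, labels, CsldsvrParams())
        pred = predict_distribution(model, rng.normal(size=(20, 6)))
        assert pred.min() > 0
        np.testing.assert_allclose(pred.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_coefficient_model_is_normalized_sigmoid_of_biases(self):
        from scipy.special import expit

        biases = np.array([0.5, -1.0, 2.0])
        model = CsldsvrModel(
            kernel=KernelSpec("linear"),
            support_inputs=np.zeros((4, 3)),
            dual_coefficients=np.zeros((4, 3)),
            biases=biases,
            params=CsldsvrParams(),
            target_clip=1e-3,
        )
        expected = expit(biases) / expit(biases).sum()
        np.testing.assert_allclose(predict_distribution(model, np.ones(3)), expected, atol=1e-12)

    def test_class_is_argmax_with_low_index_ties(self, tiny_problem, rng):
        x, d, labels = tiny_problem
        model = fit(x, d, labels, CsldsvrParams())
        queries = rng.normal(size=(50, 6))
        dist = predict_distribution(model, queries)
        np.testing.assert_array_equal(predict_class(model, queries), np.argmax(dist, axis=1))
        # argmax semantics on exact ties
        assert int(np.argmax(np.array([0.5, 0.5]))) == 0

    def test_argmax_agrees_with_brute_force_on_random_simplex(self, rng):
        d = random_simplex(rng, 1000, 4)
        brute = np.array([max(range(4), key=lambda j: row[j]) for row in d])
        np.testing.assert_array_equal(np.argmax(d, axis=1), brute)


def test_model_json_roundtrip_is_exact(tmp_path, tiny_problem):
    x, d, labels = tiny_problem
    params = CsldsvrParams(C=3.0, epsilon=0.01,
                           kernel=KernelSpec("gaussian", gaussian_bandwidth=1.5))
    model = fit(x, d, labels, params)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = CsldsvrModel.from_json(path)
    np.testing.assert_array_equal(loaded.dual_coefficients, model.dual_coefficients)
    np.testing.assert_array_equal(loaded.biases, model.biases)
    np.testing.assert_array_equal(loaded.support_inputs, model.support_inputs)
    assert loaded.kernel == model.kernel
    assert loaded.params == model.params
    q = np.linspace(-1, 1, 6)
    np.testing.assert_array_equal(
        predict_distribution(loaded, q), predict_distribution(model, q)
    )
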