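"""Cost-sensitive label-distribution support vector regression (CSLDSVR).

The model maps a feature vector x to a simplex-valued label distribution
through K per-class score functions

    f_j(x) = sum_i alpha_ij kappa(x_i, x) + b_j,
    dhat_j(x) = sigmoid(f_j(x)) / sum_l sigmoid(f_l(x)),

fitted by regressing the logits t_i = logit(clip(d_i)) of the training
distributions with a vector-valued epsilon-insensitive loss.  The training
objective is

    (1/2) sum_j alpha_.j' K alpha_.j
        + C sum_i w_i max(0, ||t_i - f(x_i)||_2 - eps)^2

where K is the kernel Gram matrix and w_i is the cost weight of sample i's
logical class.  Cost sensitivity sets w_j proportional to 1/N_j (scaled to
mean 1 over samples) so minority-class residuals cost more, countering the
majority-class bias of imbalanced cohorts; uniform weights recover plain
LDSVR.  The problem is smooth and is solved by deterministic L-BFGS from a
zero start, so identical data and parameters give identical coefficients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.special import expit, logit

__all__ = [
    "KernelSpec",
    "CsldsvrParams",
    "ClassWeights",
    "CsldsvrModel",
    "kernel_matrix",
    "compute_class_weights",
    "fit",
    "predict_distribution",
    "predict_class",
]

_KERNEL_KINDS = ("linear", "polynomial", "gaussian")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and its hyper-parameters.

    gaussian uses kappa(a,b) = exp(-||a-b||^2 / (2 sigma^2)) with
    sigma = gaussian_bandwidth; polynomial uses (a.b + coef0)^degree.
    """

    kind: str = "gaussian"
    gaussian_bandwidth: float | None = None
    poly_degree: int = 3
    poly_coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; use one of {_KERNEL_KINDS}")
        if self.kind == "gaussian":
            if self.gaussian_bandwidth is None or self.gaussian_bandwidth <= 0:
                raise ValueError("gaussian kernel requires a positive gaussian_bandwidth")
        elif self.gaussian_bandwidth is not None:
            raise ValueError("gaussian_bandwidth only applies to the gaussian kernel")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be a positive integer")


@dataclass(frozen=True)
class CsldsvrParams:
    """Training hyper-parameters.

    C is the loss weight factor, epsilon the radius of the insensitive tube
    on the joint logit residual, cost_sensitive toggles 1/N_j class weights.
    """

    C: float = 1.0
    epsilon: float = 0.001
    kernel: KernelSpec = field(default_factory=lambda: KernelSpec("linear"))
    cost_sensitive: bool = True
    optimizer_tol: float = 1e-9
    max_iter: int = 2000
    target_clip: float = 1e-3

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if not 0 < self.target_clip < 0.5:
            raise ValueError("target_clip must lie in (0, 0.5)")


@dataclass
class ClassWeights:
    per_class: np.ndarray  # length K
    per_sample: np.ndarray  # length N


def kernel_matrix(spec: KernelSpec, a_rows: np.ndarray, b_rows: np.ndarray) -> np.ndarray:
    """Gram (cross-)matrix between two row sets under the given kernel."""
    a = np.atleast_2d(np.asarray(a_rows, dtype=float))
    b = np.atleast_2d(np.asarray(b_rows, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions disagree")
    if spec.kind == "linear":
        return a @ b.T
    if spec.kind == "polynomial":
        return (a @ b.T + spec.poly_coef0) ** spec.poly_degree
    sq = cdist(a, b, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * spec.gaussian_bandwidth**2))


def compute_class_weights(labels: np.ndarray, cost_sensitive: bool) -> ClassWeights:
    """Per-class misclassification-cost weights.

    Cost-sensitive: w_j = N / (K * N_j), i.e. proportional to 1/N_j and
    scaled so the mean per-sample weight is exactly 1 (C keeps its scale
    across imbalance levels).  Uniform otherwise.
    """
    lab = np.asarray(labels)
    if lab.ndim != 2:
        raise ValueError("labels must be one-hot N x K")
    n, k = lab.shape
    counts = lab.sum(axis=0)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"class(es) {empty.tolist()} have no samples")
    if cost_sensitive:
        per_class = n / (k * counts.astype(float))
    else:
        per_class = np.ones(k)
    classes = np.argmax(lab, axis=1)
    return ClassWeights(per_class=per_class, per_sample=per_class[classes])


@dataclass
class CsldsvrModel:
    """Fitted model: kernel spec, training inputs, dual coefficients, biases."""

    kernel: KernelSpec
    support_inputs: np.ndarray  # N x q
    dual_coefficients: np.ndarray  # N x K
    biases: np.ndarray  # length K
    params: CsldsvrParams
    target_clip: float
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def n_classes(self) -> int:
        return self.biases.size

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        xq = np.atleast_2d(np.asarray(x, dtype=float))
        if xq.shape[1] != self.support_inputs.shape[1]:
            raise ValueError(
                f"expected {self.support_inputs.shape[1]} features, got {xq.shape[1]}"
            )
        kx = kernel_matrix(self.kernel, xq, self.support_inputs)
        return kx @ self.dual_coefficients + self.biases

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kernel": asdict(self.kernel),
            "support_inputs": self.support_inputs.tolist(),
            "dual_coefficients": self.dual_coefficients.tolist(),
            "biases": self.biases.tolist(),
            "params": {
                "C": self.params.C,
                "epsilon": self.params.epsilon,
                "kernel": asdict(self.params.kernel),
                "cost_sensitive": self.params.cost_sensitive,
                "optimizer_tol": self.params.optimizer_tol,
                "max_iter": self.params.max_iter,
                "target_clip": self.params.target_clip,
            },
            "target_clip": self.target_clip,
            "converged": self.converged,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CsldsvrModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        kernel = KernelSpec(**payload["kernel"])
        pp = dict(payload["params"])
        pp["kernel"] = KernelSpec(**pp["kernel"])
        return cls(
            kernel=kernel,
            support_inputs=np.asarray(payload["support_inputs"], dtype=float),
            dual_coefficients=np.asarray(payload["dual_coefficients"], dtype=float),
            biases=np.asarray(payload["biases"], dtype=float),
            params=CsldsvrParams(**pp),
            target_clip=payload["target_clip"],
            converged=payload["converged"],
        )


def _objective_and_grad(
    theta: np.ndarray,
    gram: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    c: float,
    eps: float,
) -> tuple[float, np.ndarray]:
    n, k = targets.shape
    alpha = theta[: n * k].reshape(n, k)
    bias = theta[n * k:]
    ka = gram @ alpha
    f = ka + bias
    v = targets - f
    r = np.linalg.norm(v, axis=1)
    h = np.maximum(r - eps, 0.0)
    loss = c * float(weights @ h**2)
    reg = 0.5 * float((alpha * ka).sum())
    active = h > 0
    g = np.zeros_like(v)
    if active.any():
        scale = -2.0 * c * weights[active] * h[active] / r[active]
        g[active] = scale[:, None] * v[active]
    grad_alpha = ka + gram @ g
    grad_bias = g.sum(axis=0)
    return reg + loss, np.concatenate([grad_alpha.ravel(), grad_bias])


def fit(
    X: np.ndarray,
    D: np.ndarray,
    labels: np.ndarray,
    params: CsldsvrParams,
    seed: int | None = None,
) -> CsldsvrModel:
    """Train CSLDSVR on features X, target distributions D and logical labels.

    ``seed`` is accepted for interface uniformity; the solver is
    deterministic (zero initialization, L-BFGS) and does not consume it.
    """
    X = np.asarray(X, dtype=float)
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n, k = D.shape
    if X.shape[0] != n or labels.shape != (n, k):
        raise ValueError("X, D and labels row counts / widths disagree")
    if np.any(D < 0) or np.any(np.abs(D.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("rows of D must lie on the probability simplex")

    clip = params.target_clip
    targets = logit(np.clip(D, clip, 1.0 - clip))
    gram = kernel_matrix(params.kernel, X, X)
    gram = (gram + gram.T) / 2.0
    weights = compute_class_weights(labels, params.cost_sensitive).per_sample

    trace: list[float] = []

    def cb(theta: np.ndarray) -> None:
        val, _ = _objective_and_grad(theta, gram, targets, weights, params.C, params.epsilon)
        trace.append(val)

    x0 = np.zeros(n * k + k)
    trace.append(_objective_and_grad(x0, gram, targets, weights, params.C, params.epsilon)[0])
    res = minimize(
        _objective_and_grad,
        x0,
        args=(gram, targets, weights, params.C, params.epsilon),
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={
            "maxiter": params.max_iter,
            "ftol": params.optimizer_tol,
            "gtol": params.optimizer_tol,
        },
    )
    if not res.success:
        warnings.warn(
            f"CSLDSVR optimizer did not report convergence: {res.message} "
            f"(final objective {res.fun:.6g}, {len(trace)} evaluations)",
            RuntimeWarning,
            stacklevel=2,
        )
    alpha = res.x[: n * k].reshape(n, k)
    bias = res.x[n * k:]
    return CsldsvrModel(
        kernel=params.kernel,
        support_inputs=X.copy(),
        dual_coefficients=alpha,
        biases=bias,
        params=params,
        target_clip=clip,
        objective_trace=trace,
        converged=bool(res.success),
    )


def predict_distribution(model: CsldsvrModel, x: np.ndarray) -> np.ndarray:
    """Simplex-valued prediction(s): normalized sigmoids of the scores.

    Accepts a single feature vector (returns length-K) or a matrix
    (returns N x K).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    s = expit(model.decision_scores(x))
    d = s / s.sum(axis=1, keepdims=True)
    return d[0] if single else d


def predict_class(model: CsldsvrModel, x: np.ndarray) -> int | np.ndarray:
    """Hard decision: argmax of the predicted distribution, ties -> lowest index."""
    d = predict_distribution(model, x)
    if d.ndim == 1:
        return int(np.argmax(d))
    return np.argmax(d, axis=1)
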