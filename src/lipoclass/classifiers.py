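"""Two-class classifiers: LDA, QDA, kernel SVM and KNN.

All four families operate on whatever feature representation the
pipeline hands them (PCA scores, GA-selected m/z columns, or the full
ROI matrix) and are strictly two-class, matching the NILM-vs-SIL
problem.

Discriminant scores (lower is better; classify by argmin):

    L_ik = (x_i - xbar_k)^T S_pooled^{-1} (x_i - xbar_k) - 2 ln pi_k
    Q_ik = (x_i - xbar_k)^T S_k^{-1}     (x_i - xbar_k) + ln|S_k| - 2 ln pi_k

SVM kernels: linear x'z; quadratic (tau + x'z)^2; cubic (tau + x'z)^3;
RBF exp(-gamma ||x - z||^2); MLP tanh(k1 x'z + k2).  The soft-margin
dual is solved by deterministic SMO-style pairwise optimization; the
decision function is f(z) = sign(sum_i alpha_i y_i k(x_i, z) + b), with
the raw pre-sign score exposed for ROC analysis.  The MLP kernel is
indefinite, so its training carries an iteration cap and may raise
:class:`~lipoclass.errors.ConvergenceError`.

KNN: Euclidean majority vote with odd k (no vote ties); k is chosen on
the validation set by balanced accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    ConvergenceError,
    InputError,
    NumericalError,
    StateError,
)
from .reduction import ClassStats, fit_class_stats, regularize_covariance

# ---------------------------------------------------------------------------
# Discriminant analysis


@dataclass
class DiscriminantModel:
    """LDA or QDA model over fitted :class:`ClassStats`."""

    kind: str                    # "LDA" | "QDA"
    class_stats: ClassStats | None = None

    @property
    def classes(self) -> list[str]:
        if self.class_stats is None:
            raise StateError(f"{self.kind} model is not fitted")
        return self.class_stats.classes


def fit_discriminant(
    kind: str, X: np.ndarray, y: np.ndarray, equal_priors: bool = False
) -> DiscriminantModel:
    if kind not in ("LDA", "QDA"):
        raise ConfigurationError("kind must be 'LDA' or 'QDA'")
    return DiscriminantModel(kind=kind, class_stats=fit_class_stats(X, y, equal_priors))


def _maha_sq_many(X: np.ndarray, mean: np.ndarray, inv: np.ndarray) -> np.ndarray:
    D = X - mean
    return np.maximum(np.einsum("ij,jk,ik->i", D, inv, D), 0.0)


def lda_score(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Per-class L scores for each row of ``X`` (n x K, lower = closer)."""
    stats = model.class_stats
    if stats is None:
        raise StateError("LDA model is not fitted")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cov = regularize_covariance(stats.pooled_covariance)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular pooled covariance") from exc
    K = len(stats.classes)
    out = np.empty((X.shape[0], K))
    for k in range(K):
        out[:, k] = _maha_sq_many(X, stats.means[k], inv) - 2.0 * np.log(
            stats.priors[k]
        )
    return out


def qda_score(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Per-class Q scores (adds the per-class log-determinant term)."""
    stats = model.class_stats
    if stats is None:
        raise StateError("QDA model is not fitted")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = len(stats.classes)
    out = np.empty((X.shape[0], K))
    for k in range(K):
        cov = regularize_covariance(stats.class_covariances[k])
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"singular covariance for class {stats.classes[k]!r}"
            ) from exc
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise NumericalError(
                f"non-positive-definite covariance for class {stats.classes[k]!r}"
            )
        out[:, k] = (
            _maha_sq_many(X, stats.means[k], inv)
            + logdet
            - 2.0 * np.log(stats.priors[k])
        )
    return out


def discriminant_classify(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    scores = lda_score(model, X) if model.kind == "LDA" else qda_score(model, X)
    return np.array([model.classes[i] for i in np.argmin(scores, axis=1)])


def discriminant_roc_score(
    model: DiscriminantModel, X: np.ndarray, positive: str
) -> np.ndarray:
    """Signed score oriented so larger = more like the positive class:
    the score difference L(negative) - L(positive)."""
    scores = lda_score(model, X) if model.kind == "LDA" else qda_score(model, X)
    classes = model.classes
    pos = classes.index(positive)
    neg = 1 - pos
    return scores[:, neg] - scores[:, pos]


# ---------------------------------------------------------------------------
# Kernels


_KERNEL_NAMES = ("linear", "quadratic", "poly3", "rbf", "mlp")


@dataclass
class KernelSpec:
    """Kernel name plus the parameters that name requires.

    ``tau`` (>= 0) applies to the quadratic and cubic kernels, ``gamma``
    (> 0) to the RBF, and ``k1``/``k2`` to the MLP sigmoid kernel.  A
    ``gamma`` of None is resolved to 1/p at training time.
    """

    name: str
    tau: float | None = None
    gamma: float | None = None
    k1: float | None = None
    k2: float | None = None

    def validate(self) -> None:
        if self.name not in _KERNEL_NAMES:
            raise ConfigurationError(f"unknown kernel {self.name!r}")
        if self.name in ("quadratic", "poly3"):
            if self.tau is None or self.tau < 0:
                raise ConfigurationError(f"{self.name} kernel requires tau >= 0")
        if self.name == "rbf" and self.gamma is not None and self.gamma <= 0:
            raise ConfigurationError("rbf kernel requires gamma > 0")
        if self.name == "mlp" and (self.k1 is None or self.k2 is None):
            raise ConfigurationError("mlp kernel requires k1 and k2")

    def resolved(self, n_features: int) -> "KernelSpec":
        """Fill defaults that depend on the data dimension."""
        spec = KernelSpec(self.name, self.tau, self.gamma, self.k1, self.k2)
        if spec.name in ("quadratic", "poly3") and spec.tau is None:
            spec.tau = 1.0
        if spec.name == "rbf" and spec.gamma is None:
            spec.gamma = 1.0 / n_features
        if spec.name == "mlp":
            if spec.k1 is None:
                spec.k1 = 1.0
            if spec.k2 is None:
                spec.k2 = -1.0
        spec.validate()
        return spec


def kernel_gram(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Gram matrix k(a_i, b_j) for rows of A and B."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise InputError("kernel arguments have different dimensions")
    spec = spec.resolved(A.shape[1])
    dot = A @ B.T
    if spec.name == "linear":
        return dot
    if spec.name == "quadratic":
        return (spec.tau + dot) ** 2
    if spec.name == "poly3":
        return (spec.tau + dot) ** 3
    if spec.name == "rbf":
        sq = (
            np.sum(A * A, axis=1)[:, None]
            + np.sum(B * B, axis=1)[None, :]
            - 2.0 * dot
        )
        np.maximum(sq, 0.0, out=sq)
        return np.exp(-spec.gamma * sq)
    return np.tanh(spec.k1 * dot + spec.k2)


def kernel_eval(spec: KernelSpec, x: np.ndarray, z: np.ndarray) -> float:
    """Scalar kernel value for two vectors."""
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.shape != z.shape:
        raise InputError("kernel arguments have different lengths")
    return float(kernel_gram(spec, x[None, :], z[None, :])[0, 0])


# ---------------------------------------------------------------------------
# SVM (SMO)


@dataclass
class SvmModel:
    """Soft-margin SVM solution: support vectors, multipliers, bias."""

    support_vectors: np.ndarray   # (n_sv, p)
    alphas: np.ndarray            # (n_sv,)
    signed_labels: np.ndarray     # (n_sv,), in {-1, +1}
    bias: float
    box_constraint: float
    kernel: KernelSpec
    n_features: int = 0

    @property
    def n_sv(self) -> int:
        return int(self.alphas.size)


_SV_EPS = 1e-8


def svm_train(
    X: np.ndarray,
    y_signed: np.ndarray,
    spec: KernelSpec,
    C: float = 1.0,
    tol: float = 1e-3,
    max_sweeps: int = 1000,
) -> SvmModel:
    """Solve the soft-margin dual by deterministic SMO.

    Outer loop sweeps all samples in index order and optimizes every
    KKT-violating multiplier against the partner maximizing |E_i - E_j|
    (falling back to an ordered scan); repeated until a full sweep makes
    no change.  For indefinite kernels (MLP) the pair objective is
    evaluated at the box ends.  Exceeding ``max_sweeps`` raises
    :class:`ConvergenceError` with a duality-gap proxy.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y_signed, dtype=float).ravel()
    n = X.shape[0]
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise InputError("y_signed must contain both -1 and +1")
    if C <= 0:
        raise ConfigurationError("box constraint C must be > 0")
    spec = spec.resolved(X.shape[1])

    K = kernel_gram(spec, X, X)
    alpha = np.zeros(n)
    b = 0.0

    def scores() -> np.ndarray:
        return (alpha * y) @ K + b

    E = scores() - y

    def take_step(i: int, j: int) -> bool:
        nonlocal b, E
        if i == j:
            return False
        a1, a2 = alpha[i], alpha[j]
        y1, y2 = y[i], y[j]
        E1, E2 = E[i], E[j]
        s = y1 * y2
        if s < 0:
            L, H = max(0.0, a2 - a1), min(C, C + a2 - a1)
        else:
            L, H = max(0.0, a1 + a2 - C), min(C, a1 + a2)
        if L >= H:
            return False
        k11, k12, k22 = K[i, i], K[i, j], K[j, j]
        eta = k11 + k22 - 2.0 * k12
        if eta > 0:
            a2new = a2 + y2 * (E1 - E2) / eta
            a2new = min(max(a2new, L), H)
        else:
            # Indefinite direction: evaluate the pair objective at the ends.
            f1 = y1 * (E1 + b) - a1 * k11 - s * a2 * k12
            f2 = y2 * (E2 + b) - s * a1 * k12 - a2 * k22
            L1 = a1 + s * (a2 - L)
            H1 = a1 + s * (a2 - H)
            psiL = (
                L1 * f1 + L * f2 + 0.5 * L1 * L1 * k11 + 0.5 * L * L * k22
                + s * L * L1 * k12
            )
            psiH = (
                H1 * f1 + H * f2 + 0.5 * H1 * H1 * k11 + 0.5 * H * H * k22
                + s * H * H1 * k12
            )
            if psiL < psiH - 1e-12:
                a2new = L
            elif psiL > psiH + 1e-12:
                a2new = H
            else:
                return False
        if abs(a2new - a2) < 1e-12 * (a2new + a2 + 1e-12):
            return False
        a1new = a1 + s * (a2 - a2new)
        # Bias update (Platt's b1/b2 rule).
        b1 = b - E1 - y1 * (a1new - a1) * k11 - y2 * (a2new - a2) * k12
        b2 = b - E2 - y1 * (a1new - a1) * k12 - y2 * (a2new - a2) * k22
        if 0.0 < a1new < C:
            b = b1
        elif 0.0 < a2new < C:
            b = b2
        else:
            b = (b1 + b2) / 2.0
        alpha[i], alpha[j] = a1new, a2new
        E = scores() - y
        return True

    converged = False
    for _ in range(max_sweeps):
        changed = 0
        for i in range(n):
            r = E[i] * y[i]
            if (r < -tol and alpha[i] < C) or (r > tol and alpha[i] > 0):
                j = int(np.argmax(np.abs(E[i] - E)))
                if take_step(i, j):
                    changed += 1
                    continue
                for j in range(n):
                    if take_step(i, j):
                        changed += 1
                        break
        if changed == 0:
            converged = True
            break
    if not converged:
        obj = float(alpha.sum() - 0.5 * (alpha * y) @ K @ (alpha * y))
        raise ConvergenceError(
            f"SMO hit the sweep cap ({max_sweeps}); dual objective proxy {obj:.6g}"
        )

    # Bias from margin support vectors when available.
    margin = (alpha > _SV_EPS) & (alpha < C - _SV_EPS)
    if margin.any():
        g = (alpha * y) @ K  # decision without bias
        b = float(np.mean(y[margin] - g[margin]))

    sv = alpha > _SV_EPS
    return SvmModel(
        support_vectors=X[sv].copy(),
        alphas=alpha[sv].copy(),
        signed_labels=y[sv].copy(),
        bias=float(b),
        box_constraint=C,
        kernel=spec,
        n_features=X.shape[1],
    )


def svm_decision(model: SvmModel, Z: np.ndarray) -> np.ndarray:
    """Raw decision scores sum_i alpha_i y_i k(x_i, z) + b (pre-sign)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != model.n_features:
        raise InputError("dimension mismatch with the trained SVM")
    if model.n_sv == 0:
        return np.full(Z.shape[0], model.bias)
    Kzs = kernel_gram(model.kernel, Z, model.support_vectors)
    return Kzs @ (model.alphas * model.signed_labels) + model.bias


def svm_classify(model: SvmModel, Z: np.ndarray) -> np.ndarray:
    """+1/-1 class by the sign of the decision score (0 maps to +1)."""
    return np.where(svm_decision(model, Z) >= 0.0, 1.0, -1.0)


# ---------------------------------------------------------------------------
# KNN


def knn_classify(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X: np.ndarray,
    k: int,
    positive: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean majority vote among the k nearest training samples.

    ``k`` must be odd (no vote ties with two classes) and at most the
    training size.  Returns (predicted labels, positive-class vote
    fraction); the vote fraction serves as the ROC score.
    """
    if k % 2 == 0:
        raise ConfigurationError("k must be odd to avoid vote ties")
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_train = np.asarray(y_train)
    n = X_train.shape[0]
    if k > n:
        raise ConfigurationError(f"k={k} exceeds the training size {n}")
    levels = sorted(set(y_train.tolist()))
    if positive is None:
        positive = levels[-1]
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(X_train * X_train, axis=1)[None, :]
        - 2.0 * X @ X_train.T
    )
    # Stable sort -> ties resolved toward the lowest training index.
    nearest = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes_pos = (y_train[nearest] == positive).sum(axis=1)
    frac = votes_pos / k
    neg = [c for c in levels if c != positive]
    negative = neg[0] if neg else positive
    pred = np.where(frac > 0.5, positive, negative)
    return pred, frac


def knn_select_k(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    k_grid: tuple[int, ...] = (1, 3, 5, 7, 9),
) -> int:
    """Return the k in ``k_grid`` maximizing validation balanced accuracy
    (mean of per-class recall); ties break toward the smallest k."""
    y_val = np.asarray(y_val)
    levels = sorted(set(np.asarray(y_train).tolist()))
    best_k, best_acc = None, -1.0
    for k in sorted(k_grid):
        if k % 2 == 0:
            raise ConfigurationError("k_grid must contain odd values only")
        if k > len(np.asarray(y_train)):
            continue
        pred, _ = knn_classify(X_train, y_train, X_val, k)
        recalls = [
            np.mean(pred[y_val == c] == c) for c in levels if np.any(y_val == c)
        ]
        acc = float(np.mean(recalls))
        if acc > best_acc:
            best_k, best_acc = k, acc
    if best_k is None:
        raise InputError("no feasible k in the grid")
    return best_k


# ---------------------------------------------------------------------------
# Serialization (JSON-ready dicts)


def class_stats_to_dict(stats: ClassStats) -> dict:
    return {
        "classes": stats.classes,
        "means": stats.means.tolist(),
        "pooled_covariance": stats.pooled_covariance.tolist(),
        "class_covariances": stats.class_covariances.tolist(),
        "priors": stats.priors.tolist(),
        "n_per_class": stats.n_per_class.tolist(),
    }


def class_stats_from_dict(d: dict) -> ClassStats:
    return ClassStats(
        classes=list(d["classes"]),
        means=np.array(d["means"]),
        pooled_covariance=np.array(d["pooled_covariance"]),
        class_covariances=np.array(d["class_covariances"]),
        priors=np.array(d["priors"]),
        n_per_class=np.array(d["n_per_class"]),
    )


def discriminant_to_dict(model: DiscriminantModel) -> dict:
    return {"kind": model.kind, "class_stats": class_stats_to_dict(model.class_stats)}


def discriminant_from_dict(d: dict) -> DiscriminantModel:
    return DiscriminantModel(
        kind=d["kind"], class_stats=class_stats_from_dict(d["class_stats"])
    )


def kernel_to_dict(spec: KernelSpec) -> dict:
    return {
        "name": spec.name,
        "tau": spec.tau,
        "gamma": spec.gamma,
        "k1": spec.k1,
        "k2": spec.k2,
    }


def svm_to_dict(model: SvmModel) -> dict:
    return {
        "support_vectors": model.support_vectors.tolist(),
        "alphas": model.alphas.tolist(),
        "signed_labels": model.signed_labels.tolist(),
        "bias": model.bias,
        "box_constraint": model.box_constraint,
        "kernel": kernel_to_dict(model.kernel),
        "n_features": model.n_features,
    }


def svm_from_dict(d: dict) -> SvmModel:
    return SvmModel(
        support_vectors=np.array(d["support_vectors"]),
        alphas=np.array(d["alphas"]),
        signed_labels=np.array(d["signed_labels"]),
        bias=float(d["bias"]),
        box_constraint=float(d["box_constraint"]),
        kernel=KernelSpec(**d["kernel"]),
        n_features=int(d["n_features"]),
    )
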