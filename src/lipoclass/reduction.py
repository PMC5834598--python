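"""Feature reduction: PCA scores and genetic-algorithm variable selection.

Two complementary routes shrink the ROI-compressed matrix before
classification:

* **PCA** — unsupervised; the classifiers consume the scores of the
  first ``k`` (default 10) principal components, fitted on the training
  rows only (column-mean centred, no variance scaling, since every row
  is already unit-norm).

* **GA** — supervised wrapper selection over binary chromosomes (one bit
  per m/z column).  The fitness is the average risk of misclassification
  evaluated on the validation set:

      G = (1/N_V) * sum_n g_n,
      g_n = r^2(x_n, m_true) / min_{wrong k} r^2(x_n, m_k),

  with r^2 the squared Mahalanobis distance to a class mean under the
  pooled training covariance of the selected variables (per-class
  covariance available for the QDA pairing).  g_n < 1 means the sample
  sits nearer its own class; the GA minimizes G.

GA operators: tournament selection (size 2), single-point crossover,
per-bit mutation, elitism of one.  The run is repeated from independent
random initial populations (default 3 restarts) and the best chromosome
over all restarts is returned.  Chromosomes with more than
``max_variables`` active bits receive infinite fitness, which keeps the
selected subsets small and the covariances well-posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InputError, NumericalError

# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Training-set PCA: mean, orthonormal loadings, variance fractions."""

    mean_vector: np.ndarray             # (p,)
    loadings: np.ndarray                # (p, k), orthonormal columns
    explained_variance: np.ndarray      # (k,) eigenvalues of sample cov
    explained_variance_fraction: np.ndarray  # (k,), of total variance
    k: int


def pca_fit(X_train: np.ndarray, k: int = 10) -> PCAModel:
    """Column-mean-centred SVD of the training matrix.

    Sign convention: the largest-magnitude entry of each loading is
    positive.  ``k`` may not exceed min(n - 1, p).
    """
    X_train = np.asarray(X_train, dtype=float)
    n, p = X_train.shape
    if k > min(n - 1, p) or k < 1:
        raise ConfigurationError(
            f"k={k} must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    mean = X_train.mean(axis=0)
    Xc = X_train - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev_all = (s * s) / (n - 1)
    total = float(ev_all.sum())
    loadings = Vt[:k].T.copy()
    # Deterministic sign: largest-|.| entry of each loading positive.
    for j in range(k):
        imax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[imax, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(
        mean_vector=mean,
        loadings=loadings,
        explained_variance=ev_all[:k].copy(),
        explained_variance_fraction=ev_all[:k] / total if total > 0 else ev_all[:k],
        k=k,
    )


def pca_scores(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project (centred on the *training* mean) onto the loadings."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.mean_vector.size:
        raise InputError("feature count does not match the fitted PCA model")
    return (X - model.mean_vector) @ model.loadings


def pca_model_to_json(model: PCAModel, path: str | Path) -> None:
    payload = {
        "mean_vector": model.mean_vector.tolist(),
        "loadings": model.loadings.tolist(),
        "explained_variance": model.explained_variance.tolist(),
        "explained_variance_fraction": model.explained_variance_fraction.tolist(),
        "k": model.k,
    }
    Path(path).write_text(json.dumps(payload))


def pca_model_from_json(path: str | Path) -> PCAModel:
    d = json.loads(Path(path).read_text())
    return PCAModel(
        mean_vector=np.array(d["mean_vector"]),
        loadings=np.array(d["loadings"]),
        explained_variance=np.array(d["explained_variance"]),
        explained_variance_fraction=np.array(d["explained_variance_fraction"]),
        k=int(d["k"]),
    )


# ---------------------------------------------------------------------------
# Class statistics and Mahalanobis machinery


#: Condition-number threshold above which a ridge is added.
_COND_LIMIT = 1e10
#: Ridge scale: lambda = 1e-6 * trace(S)/p.
_RIDGE = 1e-6


@dataclass
class ClassStats:
    """Per-class means, pooled and per-class covariances, priors."""

    classes: list[str]
    means: np.ndarray            # (K, p)
    pooled_covariance: np.ndarray  # (p, p)
    class_covariances: np.ndarray  # (K, p, p)
    priors: np.ndarray           # (K,), sums to 1
    n_per_class: np.ndarray      # (K,)


def regularize_covariance(cov: np.ndarray) -> np.ndarray:
    """Add a small ridge ``lambda I`` when the matrix is ill-conditioned.

    ``lambda = 1e-6 * trace(cov) / p``, applied only when the condition
    number exceeds 1e10 (or the matrix is outright singular).
    """
    cov = np.asarray(cov, dtype=float)
    p = cov.shape[0]
    try:
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        lam = _RIDGE * (np.trace(cov) / p if p else 1.0)
        if lam <= 0:
            lam = _RIDGE
        cov = cov + lam * np.eye(p)
    return cov


def fit_class_stats(
    X: np.ndarray, y: np.ndarray, equal_priors: bool = False
) -> ClassStats:
    """Means, covariances and priors from labelled training data.

    The pooled covariance is the bias-corrected within-class scatter
    ``sum_k (n_k - 1) S_k / (n - K)``; priors default to the class
    proportions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    K = len(classes)
    n, p = X.shape
    if K < 2:
        raise InputError("need at least two classes")
    means = np.zeros((K, p))
    covs = np.zeros((K, p, p))
    counts = np.zeros(K, dtype=int)
    pooled = np.zeros((p, p))
    for k, c in enumerate(classes):
        rows = X[y == c]
        counts[k] = rows.shape[0]
        means[k] = rows.mean(axis=0)
        if rows.shape[0] > 1:
            covs[k] = np.cov(rows, rowvar=False, ddof=1).reshape(p, p)
            pooled += (counts[k] - 1) * covs[k]
    if n - K <= 0:
        raise InputError("not enough samples to estimate a pooled covariance")
    pooled /= n - K
    priors = (
        np.full(K, 1.0 / K) if equal_priors else counts.astype(float) / n
    )
    return ClassStats(
        classes=classes,
        means=means,
        pooled_covariance=pooled,
        class_covariances=covs,
        priors=priors,
        n_per_class=counts,
    )


def mahalanobis_sq(
    x: np.ndarray, m: np.ndarray, cov: np.ndarray
) -> float:
    """Squared Mahalanobis distance ``(x - m)^T cov^{-1} (x - m)``.

    ``cov`` is regularized (ridge) if ill-conditioned; a covariance that
    stays singular raises :class:`NumericalError`.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    if x.shape != m.shape:
        raise InputError("x and mean have different dimensions")
    cov = regularize_covariance(cov)
    d = x - m
    try:
        sol = np.linalg.solve(cov, d)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"singular covariance of size {cov.shape[0]} after regularization"
        ) from exc
    return float(max(d @ sol, 0.0))


def fitness_G(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    selected: np.ndarray,
    covariance: str = "pooled",
) -> float:
    """Average risk of misclassification over the validation set.

    For each validation sample, the squared Mahalanobis distance to its
    own class mean is divided by the distance to the closest wrong class
    mean; G is the mean of these ratios.  Covariances and means come from
    the training rows restricted to ``selected`` variables; ``covariance``
    is ``"pooled"`` (shared, the LDA pairing) or ``"class"`` (per class,
    the QDA pairing).
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise InputError("no variables selected")
    if covariance not in ("pooled", "class"):
        raise ConfigurationError("covariance must be 'pooled' or 'class'")
    Xt = np.asarray(X_train, dtype=float)[:, selected]
    Xv = np.asarray(X_val, dtype=float)[:, selected]
    stats = fit_class_stats(Xt, y_train)
    K = len(stats.classes)
    p = selected.size

    # Pre-factor the (regularized) covariance(s) once.
    inv = np.empty((K, p, p))
    for k in range(K):
        cov = (
            stats.pooled_covariance
            if covariance == "pooled"
            else stats.class_covariances[k]
        )
        cov = regularize_covariance(cov)
        try:
            inv[k] = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"singular covariance for subset of size {p}"
            ) from exc

    cls_index = {c: k for k, c in enumerate(stats.classes)}
    y_val = np.asarray(y_val)
    total = 0.0
    for n in range(Xv.shape[0]):
        x = Xv[n]
        r2 = np.empty(K)
        for k in range(K):
            d = x - stats.means[k]
            r2[k] = max(float(d @ inv[k] @ d), 0.0)
        own = cls_index[y_val[n]]
        num = r2[own]
        den = min(r2[k] for k in range(K) if k != own)
        if den == 0.0:
            # Both distances zero: the sample is (degenerately) equidistant,
            # g_n = 1; zero wrong-class distance with nonzero own distance
            # is the worst case.
            total += 1.0 if num == 0.0 else np.inf
        else:
            total += num / den
    return total / Xv.shape[0]


# ---------------------------------------------------------------------------
# Genetic algorithm


@dataclass
class GAConfig:
    """GA settings; defaults follow the study protocol (40 generations of
    80 chromosomes, 60 % crossover, 10 % mutation, three restarts)."""

    n_generations: int = 40
    population: int = 80
    crossover_prob: float = 0.60
    mutation_prob: float = 0.10
    n_restarts: int = 3
    init_bit_prob: float = 0.05
    max_variables: int = 30
    covariance: str = "pooled"
    seed: int = 0

    def validate(self) -> None:
        for name in ("crossover_prob", "mutation_prob", "init_bit_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.population < 2:
            raise ConfigurationError("population must be >= 2")
        if self.population % 2:
            raise ConfigurationError("population must be even")
        if self.n_generations < 1:
            raise ConfigurationError("n_generations must be >= 1")
        if self.n_restarts < 1:
            raise ConfigurationError("n_restarts must be >= 1")
        if self.max_variables < 1:
            raise ConfigurationError("max_variables must be >= 1")


@dataclass
class GAResult:
    """Best chromosome over all restarts, as sorted variable indices."""

    selected: np.ndarray
    best_fitness: float
    fitness_history: list[list[float]] = field(default_factory=list)


def ga_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: GAConfig | None = None,
) -> GAResult:
    """Binary-chromosome GA minimizing :func:`fitness_G`.

    One bit per m/z column.  Tournament selection of size 2, single-point
    crossover with probability ``crossover_prob``, independent per-bit
    mutation with probability ``mutation_prob``, elitism of the single
    best chromosome.  Empty chromosomes are repaired by switching one
    random bit on; chromosomes above ``max_variables`` bits get infinite
    fitness.  Restart r uses the seeded generator ``seed + r``; the best
    chromosome over all restarts is returned, together with the
    best-so-far fitness trace of each restart (non-increasing by
    elitism).
    """
    config = config or GAConfig()
    config.validate()
    X_train = np.asarray(X_train, dtype=float)
    p = X_train.shape[1]

    cache: dict[bytes, float] = {}

    def evaluate(chrom: np.ndarray) -> float:
        key = np.packbits(chrom).tobytes()
        if key in cache:
            return cache[key]
        n_sel = int(chrom.sum())
        if n_sel == 0 or n_sel > config.max_variables:
            fit = np.inf
        else:
            try:
                fit = fitness_G(
                    X_train,
                    y_train,
                    X_val,
                    y_val,
                    np.where(chrom)[0],
                    covariance=config.covariance,
                )
            except NumericalError:
                fit = np.inf
        cache[key] = fit
        return fit

    best_overall: np.ndarray | None = None
    best_fit_overall = np.inf
    history: list[list[float]] = []

    for r in range(config.n_restarts):
        rng = np.random.default_rng(config.seed + r)
        pop = rng.random((config.population, p)) < config.init_bit_prob
        for chrom in pop:
            if not chrom.any():
                chrom[rng.integers(p)] = True
        fits = np.array([evaluate(c) for c in pop])

        ibest = int(np.argmin(fits))
        best, best_fit = pop[ibest].copy(), float(fits[ibest])
        trace: list[float] = []

        for _ in range(config.n_generations):
            new_pop = [best.copy()]  # elitism of one
            while len(new_pop) < config.population:
                parents = []
                for _ in range(2):
                    a, b = rng.integers(config.population, size=2)
                    if fits[b] < fits[a]:
                        a = b
                    parents.append(pop[a])
                c1, c2 = parents[0].copy(), parents[1].copy()
                if p > 1 and rng.random() < config.crossover_prob:
                    cut = int(rng.integers(1, p))
                    c1[cut:], c2[cut:] = parents[1][cut:], parents[0][cut:]
                for c in (c1, c2):
                    if config.mutation_prob > 0:
                        flip = rng.random(p) < config.mutation_prob
                        c[flip] = ~c[flip]
                    if not c.any():
                        c[rng.integers(p)] = True
                new_pop.append(c1)
                if len(new_pop) < config.population:
                    new_pop.append(c2)
            pop = np.array(new_pop)
            fits = np.array([evaluate(c) for c in pop])
            ibest = int(np.argmin(fits))
            if fits[ibest] < best_fit:
                best, best_fit = pop[ibest].copy(), float(fits[ibest])
            trace.append(best_fit)

        history.append(trace)
        if best_fit < best_fit_overall:
            best_overall, best_fit_overall = best, best_fit

    assert best_overall is not None
    return GAResult(
        selected=np.where(best_overall)[0],
        best_fitness=best_fit_overall,
        fitness_history=history,
    )


def ga_result_to_csv(result: GAResult, axis: np.ndarray, path: str | Path) -> None:
    """Selected variables with their m/z values, plus the best fitness."""
    with open(path, "w", newline="") as fh:
        fh.write("index,mz\n")
        for i in result.selected:
            fh.write(f"{int(i)},{axis[int(i)]:.17g}\n")
        fh.write(f"# best_fitness,{result.best_fitness:.17g}\n")
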