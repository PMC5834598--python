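"""PCA, Mahalanobis distance, GA fitness and GA selection — all against
explicit-loop/eigen-decomposition oracles."""

import numpy as np
import pytest

from lipoclass.errors import ConfigurationError, InputError
from lipoclass.reduction import (
    GAConfig,
    fit_class_stats,
    fitness_G,
    ga_select,
    mahalanobis_sq,
    pca_fit,
    pca_scores,
)
from lipoclass.synthetic import NILM, SIL


class TestPCA:
    def test_rank_one_data(self, rng):
        direction = rng.normal(size=5)
        X = np.outer(rng.normal(size=20), direction)
        model = pca_fit(X, k=2)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_reconstruction_completeness(self, rng):
        X = rng.normal(size=(12, 6))
        model = pca_fit(X, k=6)
        scores = pca_scores(model, X)
        recon = scores @ model.loadings.T + model.mean_vector
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_explained_variance_matches_eigendecomposition(self, rng):
        X = rng.normal(size=(30, 8))
        model = pca_fit(X, k=8)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(model.explained_variance, eigvals, atol=1e-10)
        np.testing.assert_allclose(
            model.explained_variance_fraction, eigvals / eigvals.sum(), atol=1e-10
        )

    def test_orthonormal_loadings_and_sign_convention(self, rng):
        X = rng.normal(size=(25, 10))
        model = pca_fit(X, k=4)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(4), atol=1e-8
        )
        for j in range(4):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_training_scores_centered_with_matching_variance(self, rng):
        X = rng.normal(size=(40, 7))
        model = pca_fit(X, k=5)
        scores = pca_scores(model, X)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(
            scores.var(axis=0, ddof=1), model.explained_variance, atol=1e-8
        )

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            pca_fit(rng.normal(size=(5, 10)), k=5)  # k > n - 1


class TestMahalanobis:
    def test_zero_at_mean_and_euclidean_identity(self, rng):
        m = rng.normal(size=4)
        assert mahalanobis_sq(m, m, np.eye(4)) == 0.0
        x = rng.normal(size=4)
        assert mahalanobis_sq(x, m, np.eye(4)) == pytest.approx(np.sum((x - m) ** 2))

    def test_diagonal_hand_case(self):
        # (1/1) + (4/4) + (9/9) = 3
        assert mahalanobis_sq(
            np.array([1.0, 2.0, 3.0]), np.zeros(3), np.diag([1.0, 4.0, 9.0])
        ) == pytest.approx(3.0)

    def test_dimension_mismatch(self):
        with pytest.raises(InputError):
            mahalanobis_sq(np.zeros(3), np.zeros(2), np.eye(2))


def brute_fitness_G(X_train, y_train, X_val, y_val, selected):
    """Explicit-loop recomputation with explicit matrix inverse."""
    Xt, Xv = X_train[:, selected], X_val[:, selected]
    classes = sorted(set(y_train))
    means = {c: Xt[y_train == c].mean(axis=0) for c in classes}
    p = len(selected)
    pooled = np.zeros((p, p))
    n = 0
    for c in classes:
        rows = Xt[y_train == c]
        d = rows - means[c]
        pooled += d.T @ d
        n += len(rows)
    pooled /= n - len(classes)
    inv = np.linalg.inv(pooled)
    total = 0.0
    for i in range(len(Xv)):
        r2 = {c: (Xv[i] - means[c]) @ inv @ (Xv[i] - means[c]) for c in classes}
        own = y_val[i]
        wrong = min(v for c, v in r2.items() if c != own)
        total += r2[own] / wrong
    return total / len(Xv)


class TestFitnessG:
    def test_scalar_oracle(self):
        """Training means 0 and 4 with pooled variance exactly 1;
        validation {1 (own class 0), 3 (own class 4)} -> g = 1/9 each."""
        a = np.sqrt(0.5)
        X_train = np.array([[-a], [a], [4 - a], [4 + a]])
        y_train = np.array([NILM, NILM, SIL, SIL])
        X_val = np.array([[1.0], [3.0]])
        y_val = np.array([NILM, SIL])
        g = fitness_G(X_train, y_train, X_val, y_val, np.array([0]))
        assert g == pytest.approx(1.0 / 9.0, abs=1e-12)

    def test_zero_when_validation_at_class_means(self):
        X_train = np.array([[0.0, 0.0], [0.2, -0.2], [5.0, 5.0], [5.2, 4.8]])
        y_train = np.array([NILM, NILM, SIL, SIL])
        X_val = np.array([[0.1, -0.1], [5.1, 4.9]])  # exactly the class means
        g = fitness_G(X_train, y_train, X_val, np.array([NILM, SIL]), [0, 1])
        assert g == pytest.approx(0.0, abs=1e-20)

    def test_equidistant_sample_scores_one(self):
        a = np.sqrt(0.5)
        X_train = np.array([[-a], [a], [4 - a], [4 + a]])
        y_train = np.array([NILM, NILM, SIL, SIL])
        g = fitness_G(X_train, y_train, np.array([[2.0]]), np.array([NILM]), [0])
        assert g == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            p = int(rng.integers(1, 5))
            X_train = rng.normal(size=(30, 8))
            y_train = np.array([NILM] * 16 + [SIL] * 14)
            X_val = rng.normal(size=(6, 8))
            y_val = np.array([NILM, SIL] * 3)
            sel = np.sort(rng.choice(8, size=p, replace=False))
            g = fitness_G(X_train, y_train, X_val, y_val, sel)
            assert g == pytest.approx(
                brute_fitness_G(X_train, y_train, X_val, y_val, sel), abs=1e-10
            )


def _replay_initial_population(cfg, p):
    """Reconstruct restart r's initial population from the documented
    init procedure (Bernoulli bits + single-bit repair)."""
    pops = []
    for r in range(cfg.n_restarts):
        rng = np.random.default_rng(cfg.seed + r)
        pop = rng.random((cfg.population, p)) < cfg.init_bit_prob
        for chrom in pop:
            if not chrom.any():
                chrom[rng.integers(p)] = True
        pops.append(pop)
    return pops


class TestGASelect:
    def test_degenerate_ga_returns_best_initial(self, rng):
        """With no mutation and no crossover, elitism means the result is
        the best chromosome of the initial populations."""
        X_train = rng.normal(size=(24, 12))
        y_train = np.array([NILM] * 12 + [SIL] * 12)
        X_train[y_train == SIL, 3] += 2.0
        X_val = rng.normal(size=(8, 12))
        y_val = np.array([NILM, SIL] * 4)
        X_val[y_val == SIL, 3] += 2.0
        cfg = GAConfig(
            n_generations=3, population=10, crossover_prob=0.0,
            mutation_prob=0.0, n_restarts=2, init_bit_prob=0.3, seed=5,
        )
        res = ga_select(X_train, y_train, X_val, y_val, cfg)

        def fit(chrom):
            sel = np.where(chrom)[0]
            if sel.size == 0 or sel.size > cfg.max_variables:
                return np.inf
            return fitness_G(X_train, y_train, X_val, y_val, sel)

        best = min(
            fit(c) for pop in _replay_initial_population(cfg, 12) for c in pop
        )
        assert res.best_fitness == pytest.approx(best, rel=1e-12)

    def test_fitness_history_non_increasing(self, planted_cohort_matrix):
        fm, split, _ = planted_cohort_matrix
        cfg = GAConfig(n_generations=8, population=20, n_restarts=2, seed=1)
        res = ga_select(
            fm.X[split.train], fm.labels[split.train],
            fm.X[split.validation], fm.labels[split.validation], cfg,
        )
        for trace in res.fitness_history:
            assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))

    def test_selection_respects_cap_and_finds_signal(self, planted_cohort_matrix):
        """On the planted cohort the GA returns a small subset (within the
        variable cap) that includes a planted marker column."""
        fm, split, marker_cols = planted_cohort_matrix
        cfg = GAConfig(seed=2)
        res = ga_select(
            fm.X[split.train], fm.labels[split.train],
            fm.X[split.validation], fm.labels[split.validation], cfg,
        )
        assert 1 <= res.selected.size <= cfg.max_variables
        assert set(res.selected.tolist()) & set(marker_cols)
        # reported fitness is the fitness of the reported subset
        assert res.best_fitness == pytest.approx(
            fitness_G(
                fm.X[split.train], fm.labels[split.train],
                fm.X[split.validation], fm.labels[split.validation],
                res.selected,
            ),
            rel=1e-12,
        )

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            GAConfig(population=1).validate()
        with pytest.raises(ConfigurationError):
            GAConfig(population=81).validate()
        with pytest.raises(ConfigurationError):
            GAConfig(crossover_prob=1.5).validate()


def test_class_stats_priors_and_pooled(rng):
    X = rng.normal(size=(10, 3))
    y = np.array([NILM] * 6 + [SIL] * 4)
    stats = fit_class_stats(X, y)
    np.testing.assert_allclose(stats.priors, [0.6, 0.4])
    pooled = (
        5 * np.cov(X[:6], rowvar=False) + 3 * np.cov(X[6:], rowvar=False)
    ) / 8
    np.testing.assert_allclose(stats.pooled_covariance, pooled, atol=1e-12)
    equal = fit_class_stats(X, y, equal_priors=True)
    np.testing.assert_allclose(equal.priors, [0.5, 0.5])
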