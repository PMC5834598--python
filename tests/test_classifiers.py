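"""LDA/QDA against explicit-formula oracles, kernel identities, SVM dual
feasibility and the max-margin toy geometry, KNN voting."""

import numpy as np
import pytest

from lipoclass.classifiers import (
    KernelSpec,
    discriminant_classify,
    fit_discriminant,
    kernel_eval,
    kernel_gram,
    knn_classify,
    knn_select_k,
    lda_score,
    qda_score,
    svm_classify,
    svm_decision,
    svm_train,
)
from lipoclass.errors import ConfigurationError, InputError
from lipoclass.reduction import ClassStats
from lipoclass.synthetic import NILM, SIL


def stats_1d(means, variances, priors, n=(10, 10)):
    """Hand-built 1-D two-class statistics (labels A < B in sort order)."""
    K = len(means)
    return ClassStats(
        classes=["A", "B"][:K],
        means=np.array(means, float).reshape(K, 1),
        pooled_covariance=np.array([[np.mean(variances)]]),
        class_covariances=np.array(variances, float).reshape(K, 1, 1),
        priors=np.array(priors, float),
        n_per_class=np.array(n),
    )


class TestDiscriminants:
    def test_lda_scalar_case(self):
        """Means 0 and 4, unit pooled variance, equal priors, x = 1:
        Mahalanobis parts 1 and 9, shifted equally by -2 ln(1/2)."""
        from lipoclass.classifiers import DiscriminantModel

        model = DiscriminantModel(
            "LDA", stats_1d([0.0, 4.0], [1.0, 1.0], [0.5, 0.5])
        )
        L = lda_score(model, np.array([[1.0]]))[0]
        shift = -2.0 * np.log(0.5)
        np.testing.assert_allclose(L, [1.0 + shift, 9.0 + shift], atol=1e-12)
        assert discriminant_classify(model, np.array([[1.0]]))[0] == "A"

    def test_lda_prior_tiebreak(self):
        from lipoclass.classifiers import DiscriminantModel

        model = DiscriminantModel(
            "LDA", stats_1d([0.0, 4.0], [1.0, 1.0], [0.9, 0.1])
        )
        # exactly midway: the -2 ln pi term decides for the 0.9-prior class
        assert discriminant_classify(model, np.array([[2.0]]))[0] == "A"

    def test_lda_reduces_to_nearest_centroid(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([NILM] * 20 + [SIL] * 20)
        X[y == SIL] += 1.5
        model = fit_discriminant("LDA", X, y, equal_priors=True)
        stats = model.class_stats
        # replace pooled covariance by identity -> nearest class mean
        stats.pooled_covariance = np.eye(3)
        Z = rng.normal(size=(15, 3))
        pred = discriminant_classify(model, Z)
        d0 = np.linalg.norm(Z - stats.means[0], axis=1)
        d1 = np.linalg.norm(Z - stats.means[1], axis=1)
        expected = np.where(d0 <= d1, stats.classes[0], stats.classes[1])
        assert pred.tolist() == expected.tolist()

    def test_qda_variance_effects(self):
        from lipoclass.classifiers import DiscriminantModel

        model = DiscriminantModel(
            "QDA", stats_1d([0.0, 0.0], [1.0, 9.0], [0.5, 0.5])
        )
        Q0 = qda_score(model, np.array([[0.0]]))[0]
        shift = -2.0 * np.log(0.5)
        np.testing.assert_allclose(
            Q0, [np.log(1.0) + shift, np.log(9.0) + shift], atol=1e-12
        )
        assert discriminant_classify(model, np.array([[0.0]]))[0] == "A"
        # far in the tail the heavy-variance class wins: Q = 36 vs 4 + ln 9
        assert discriminant_classify(model, np.array([[6.0]]))[0] == "B"

    def test_qda_degenerates_to_lda(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array([NILM] * 15 + [SIL] * 15)
        X[y == SIL, 0] += 2.0
        lda = fit_discriminant("LDA", X, y)
        qda = fit_discriminant("QDA", X, y)
        # force equal per-class covariances = pooled
        qda.class_stats.class_covariances = np.stack(
            [lda.class_stats.pooled_covariance] * 2
        )
        Z = rng.normal(size=(20, 4))
        assert discriminant_classify(qda, Z).tolist() == (
            discriminant_classify(lda, Z).tolist()
        )

    def test_scores_match_explicit_formulas(self, rng):
        """Brute-force evaluation with explicit inverse and log-determinant."""
        X = rng.normal(size=(60, 4))
        y = np.array([NILM] * 32 + [SIL] * 28)
        X[y == SIL] += rng.normal(size=4)
        lda = fit_discriminant("LDA", X, y)
        qda = fit_discriminant("QDA", X, y)
        stats = lda.class_stats
        Z = rng.normal(size=(10, 4))
        Sp_inv = np.linalg.inv(stats.pooled_covariance)
        for i, z in enumerate(Z):
            for k in range(2):
                d = z - stats.means[k]
                expect = d @ Sp_inv @ d - 2.0 * np.log(stats.priors[k])
                assert lda_score(lda, Z)[i, k] == pytest.approx(expect, abs=1e-8)
                Sk = qda.class_stats.class_covariances[k]
                expect_q = (
                    d @ np.linalg.inv(Sk) @ d
                    + np.log(np.linalg.det(Sk))
                    - 2.0 * np.log(stats.priors[k])
                )
                assert qda_score(qda, Z)[i, k] == pytest.approx(expect_q, abs=1e-8)


class TestKernels:
    def test_identities(self):
        x, z = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        assert kernel_eval(KernelSpec("linear"), x, z) == pytest.approx(11.0)
        assert kernel_eval(KernelSpec("quadratic", tau=0.0), x, z) == pytest.approx(121.0)
        assert kernel_eval(KernelSpec("poly3", tau=0.0), x, z) == pytest.approx(1331.0)
        assert kernel_eval(KernelSpec("rbf", gamma=0.7), x, x) == pytest.approx(1.0)
        ortho = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert kernel_eval(KernelSpec("mlp", k1=1.0, k2=0.0), *ortho) == pytest.approx(0.0)

    def test_parameter_validation(self):
        with pytest.raises(ConfigurationError):
            KernelSpec("rbf", gamma=-1.0).validate()
        with pytest.raises(ConfigurationError):
            KernelSpec("quadratic", tau=-0.5).validate()
        with pytest.raises(ConfigurationError):
            KernelSpec("mlp").validate()
        with pytest.raises(ConfigurationError):
            KernelSpec("sigmoid").validate()

    def test_rbf_gram_positive_semidefinite(self, rng):
        X = rng.normal(size=(25, 6))
        G = kernel_gram(KernelSpec("rbf", gamma=0.3), X, X)
        np.testing.assert_allclose(G, G.T, atol=1e-12)
        assert np.linalg.eigvalsh(G).min() >= -1e-8


TOY_X = np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 0.0], [2.0, 1.0]])
TOY_Y = np.array([-1.0, -1.0, 1.0, 1.0])


class TestSvm:
    def test_toy_max_margin_boundary(self):
        """Two columns of points at x1=0 and x1=2: the max-margin linear
        boundary is x1 = 1 with decision f(z) = z1 - 1."""
        model = svm_train(TOY_X, TOY_Y, KernelSpec("linear"), C=1e3, tol=1e-6)
        assert svm_decision(model, np.array([[1.0, 0.5]]))[0] == pytest.approx(0.0, abs=1e-3)
        assert svm_decision(model, np.array([[1.1, 0.5]]))[0] > 0
        assert svm_decision(model, np.array([[0.9, 0.5]]))[0] < 0
        # margin support vectors score ~ their label
        sv_scores = svm_decision(model, model.support_vectors)
        np.testing.assert_allclose(sv_scores, model.signed_labels, atol=1e-2)

    def test_separable_zero_training_error(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0, 1.0, -1.0)
        X[y > 0] += [1.0, 0.5]
        X[y < 0] -= [1.0, 0.5]
        model = svm_train(X, y, KernelSpec("linear"), C=1e3)
        assert np.array_equal(svm_classify(model, X), y)

    @pytest.mark.parametrize("kernel", [
        KernelSpec("linear"),
        KernelSpec("rbf", gamma=0.5),
        KernelSpec("quadratic", tau=1.0),
        KernelSpec("poly3", tau=1.0),
    ])
    def test_dual_feasibility_and_kkt(self, kernel, rng):
        X = rng.normal(size=(24, 3))
        y = np.where(rng.random(24) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]  # both classes present
        C = 2.0
        model = svm_train(X, y, kernel, C=C)
        assert np.all(model.alphas >= -1e-12)
        assert np.all(model.alphas <= C + 1e-12)
        assert abs(np.sum(model.alphas * model.signed_labels)) < 1e-8
        # KKT on the training set within the optimizer tolerance
        f = svm_decision(model, X)
        # recover full alpha vector (zeros off the support)
        sv_set = {tuple(v) for v in model.support_vectors}
        for i in range(24):
            yf = y[i] * f[i]
            if tuple(X[i]) not in sv_set:            # alpha == 0
                assert yf >= 1.0 - 2e-3
        margin = (model.alphas > 1e-8) & (model.alphas < C - 1e-8)
        mf = model.signed_labels * svm_decision(model, model.support_vectors)
        assert np.all(np.abs(mf[margin] - 1.0) < 2e-3)
        assert np.all(mf[~margin] <= 1.0 + 2e-3)     # alpha == C side

    def test_label_negation_negates_scores(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        Z = rng.normal(size=(8, 2))
        m1 = svm_train(X, y, KernelSpec("rbf", gamma=1.0), C=5.0, tol=1e-6)
        m2 = svm_train(X, -y, KernelSpec("rbf", gamma=1.0), C=5.0, tol=1e-6)
        np.testing.assert_allclose(
            svm_decision(m1, Z), -svm_decision(m2, Z), atol=5e-3
        )

    def test_requires_both_classes_and_positive_C(self):
        with pytest.raises(InputError):
            svm_train(TOY_X, np.ones(4), KernelSpec("linear"))
        with pytest.raises(ConfigurationError):
            svm_train(TOY_X, TOY_Y, KernelSpec("linear"), C=0.0)


class TestKnn:
    def test_exact_point_k1_and_majority(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([NILM, NILM, SIL])
        pred, _ = knn_classify(X, y, np.array([[2.0]]), k=1)
        assert pred[0] == SIL
        pred3, frac = knn_classify(X, y, np.array([[0.5]]), k=3)
        assert pred3[0] == NILM          # votes (NILM, NILM, SIL)
        assert frac[0] == pytest.approx(1.0 / 3.0)

    def test_even_k_rejected(self):
        X = np.zeros((4, 1))
        y = np.array([NILM, NILM, SIL, SIL])
        with pytest.raises(ConfigurationError):
            knn_classify(X, y, X, k=2)
        with pytest.raises(ConfigurationError):
            knn_classify(X, y, X, k=5)  # k > n_train

    def test_select_k_matches_exhaustive_grid(self, planted_cohort_matrix):
        fm, split, _ = planted_cohort_matrix
        Xt, yt = fm.X[split.train], fm.labels[split.train]
        Xv, yv = fm.X[split.validation], fm.labels[split.validation]
        grid = (1, 3, 5, 7)
        k_star = knn_select_k(Xt, yt, Xv, yv, grid)

        def balacc(k):
            pred, _ = knn_classify(Xt, yt, Xv, k)
            return np.mean([np.mean(pred[yv == c] == c) for c in sorted(set(yt))])

        best = max(balacc(k) for k in grid)
        assert balacc(k_star) == pytest.approx(best)
        assert all(balacc(k) < best or k >= k_star for k in grid)  # smallest tie
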