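"""PCA, NIPALS-PLS, LOOCV, PLS-DA and LDA against independent oracles."""

import numpy as np
import pytest

from uraman.core import Group
from uraman.chemometrics import (
    CVUnit,
    PLSModel,
    fit_pca,
    lda_classify,
    lda_fit,
    loocv_pls,
    pls_fit,
    pls_predict,
    plsda_classify,
    plsda_fit,
    select_latent_variables,
    variance_captured,
)


def random_problem(seed, n=30, p=20, informative=3, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:informative] = rng.normal(size=informative)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestPCA:
    def test_rank_one_data_has_one_component(self):
        rng = np.random.default_rng(0)
        shape = rng.normal(size=50)
        X = np.outer(rng.normal(size=10), shape) + 5.0
        p = fit_pca(X, 3)
        assert p.explained_variance_ratio[0] > 0.999

    def test_loadings_orthonormal_and_scores_centered(self):
        X = np.random.default_rng(1).normal(size=(12, 30))
        p = fit_pca(X, 6)
        np.testing.assert_allclose(
            p.loadings @ p.loadings.T, np.eye(6), atol=1e-8
        )
        np.testing.assert_allclose(p.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_explained_variance_matches_eigendecomposition(self):
        # independent oracle: eigenvalues of the sample covariance
        X = np.random.default_rng(2).normal(size=(8, 20))
        p = fit_pca(X, 7)
        Xc = X - X.mean(axis=0)
        evals = np.linalg.eigvalsh(Xc.T @ Xc)[::-1]
        expected = evals[:7] / evals.sum()
        np.testing.assert_allclose(p.explained_variance_ratio, expected, atol=1e-8)

    def test_full_reconstruction_is_lossless(self):
        X = np.random.default_rng(3).normal(size=(9, 15))
        p = fit_pca(X, 8)
        recon = p.scores @ p.loadings + p.mean_spectrum
        np.testing.assert_allclose(recon, X, atol=1e-6)

    def test_variance_captured_boundaries(self):
        X = np.random.default_rng(4).normal(size=(7, 10))
        p = fit_pca(X, 6)
        assert variance_captured(p, 0) == 0.0
        assert abs(variance_captured(p, 6) - 1.0) < 1e-9

    def test_component_count_validated(self):
        X = np.random.default_rng(5).normal(size=(5, 10))
        with pytest.raises(ValueError):
            fit_pca(X, 5)


class TestPLSFit:
    def test_rank_one_problem_fits_exactly_with_one_lv(self):
        rng = np.random.default_rng(6)
        w = rng.normal(size=25)
        t = rng.normal(size=15)
        X1 = np.outer(t, w)
        y1 = 3.0 * t * np.linalg.norm(w) ** 2
        m1 = pls_fit(X1, y1, 1)
        assert np.max(np.abs(pls_predict(m1, X1) - y1)) < 1e-6 * np.std(y1)

    def test_full_rank_pls_equals_least_squares(self):
        # oracle: minimum-norm least squares on the centered problem
        X, y = random_problem(7, n=40, p=8, informative=8, noise=0.2)
        m = pls_fit(X, y, 8)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        np.testing.assert_allclose(
            m.regression_vector, beta, rtol=1e-6, atol=1e-8 * np.abs(beta).max()
        )

    def test_row_permutation_invariance(self):
        X, y = random_problem(8)
        m = pls_fit(X, y, 4)
        perm = np.random.default_rng(9).permutation(len(y))
        m2 = pls_fit(X[perm], y[perm], 4)
        np.testing.assert_allclose(m.regression_vector, m2.regression_vector, atol=1e-10)

    def test_affine_prediction_identity(self):
        # sequential NIPALS prediction equals the collapsed affine form
        X, y = random_problem(10)
        m = pls_fit(X, y, 5)
        Xc = X - m.x_mean
        yhat_seq = np.full(len(y), m.y_mean)
        E = Xc.copy()
        for a in range(m.n_lv):
            t = E @ m.weights[a]
            yhat_seq += m.y_loadings[a] * t
            E -= np.outer(t, m.x_loadings[a])
        np.testing.assert_allclose(pls_predict(m, X), yhat_seq, atol=1e-8)

    def test_predicting_training_mean_returns_y_mean(self):
        X, y = random_problem(11)
        m = pls_fit(X, y, 3)
        assert abs(pls_predict(m, X.mean(axis=0)) [0] - m.y_mean) < 1e-10

    def test_zero_variance_target_rejected(self):
        X, _ = random_problem(12)
        with pytest.raises(ValueError, match="zero variance"):
            pls_fit(X, np.ones(X.shape[0]), 2)

    def test_agreement_with_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem(13, n=25, p=40, informative=5, noise=0.5)
        for n_lv in (1, 3, 6):
            m = pls_fit(X, y, n_lv)
            ref = sklearn.PLSRegression(n_components=n_lv, scale=False).fit(
                X, y.reshape(-1, 1)
            )
            np.testing.assert_allclose(
                pls_predict(m, X), ref.predict(X).ravel(), atol=1e-6 * np.std(y)
            )


class TestLOOCV:
    def test_perfect_model_limit(self):
        rng = np.random.default_rng(14)
        w = rng.normal(size=12)
        t = rng.normal(size=10)
        X = np.outer(t, w)
        y = 2.0 * t
        cv = loocv_pls(X, y, 2, CVUnit.SPECTRUM)
        assert cv.rmsecv_by_lv[0] < 1e-6 * np.std(y)
        assert cv.r_by_lv[0] > 0.9999

    def test_matches_brute_force_fold_loop(self):
        # oracle: explicit refit-and-predict loop over folds and LV counts
        rng = np.random.default_rng(15)
        X = rng.normal(size=(5, 6))
        y = rng.normal(size=5)
        max_lv = 3
        cv = loocv_pls(X, y, max_lv, CVUnit.SPECTRUM)
        for k in range(1, max_lv + 1):
            preds = np.zeros(5)
            for i in range(5):
                train = [j for j in range(5) if j != i]
                m = pls_fit(X[train], y[train], k)
                preds[i] = pls_predict(m, X[i])[0]
            expected = np.sqrt(np.mean((preds - y) ** 2))
            assert abs(cv.rmsecv_by_lv[k - 1] - expected) < 1e-10

    def test_sample_folds_hold_replicates_together(self):
        rng = np.random.default_rng(16)
        n_samples, reps, p = 6, 3, 10
        sample_ids = np.repeat([f"s{i}" for i in range(n_samples)], reps)
        truth = rng.normal(size=n_samples)
        X = rng.normal(size=(n_samples * reps, p))
        y = np.repeat(truth, reps)
        cv = loocv_pls(X, y, 2, CVUnit.SAMPLE, sample_ids)
        # brute force at the sample level
        for k in (1, 2):
            preds = np.zeros(len(y))
            for i in range(n_samples):
                test = np.flatnonzero(sample_ids == f"s{i}")
                train = np.flatnonzero(sample_ids != f"s{i}")
                m = pls_fit(X[train], y[train], k)
                preds[test] = pls_predict(m, X[test])
            expected = np.sqrt(np.mean((preds - y) ** 2))
            assert abs(cv.rmsecv_by_lv[k - 1] - expected) < 1e-10

    def test_null_response_scores_near_sd(self):
        # y independent of X: the best cross-validated RMSE stays near SD(y)
        for seed in range(20):
            X, _ = random_problem(100 + seed, n=40, p=10)
            y = np.random.default_rng(200 + seed).normal(size=40)
            cv = loocv_pls(X, y, 3, CVUnit.SPECTRUM)
            best = cv.rmsecv_by_lv.min()
            assert 0.8 * np.std(y) <= best <= 1.3 * np.std(y)

    def test_no_leakage_from_held_out_response(self):
        # corrupting y[i] must not change row i's own held-out prediction
        # max_lv=1 pins the selected LV count, so cv_predictions for the
        # two runs are comparable fold by fold
        rng = np.random.default_rng(17)
        X = rng.normal(size=(8, 10))
        y = rng.normal(size=8)
        cv = loocv_pls(X, y, 1, CVUnit.SPECTRUM)
        y2 = y.copy()
        y2[3] += 100.0
        cv2 = loocv_pls(X, y2, 1, CVUnit.SPECTRUM)
        assert abs(cv.cv_predictions[3] - cv2.cv_predictions[3]) < 1e-10
        others = [i for i in range(8) if i != 3]
        assert np.max(np.abs(cv.cv_predictions[others] - cv2.cv_predictions[others])) > 1e-3

    def test_too_few_units_rejected(self):
        X = np.random.default_rng(18).normal(size=(2, 5))
        with pytest.raises(ValueError):
            loocv_pls(X, np.array([1.0, 2.0]), 1, CVUnit.SPECTRUM)


class TestLVSelection:
    @pytest.mark.parametrize(
        "curve, expected",
        [([5.0, 3.0, 3.0, 4.0], 2), (list(range(8, 0, -1)), 8), ([2.5], 1)],
    )
    def test_argmin_with_ties_to_fewer(self, curve, expected):
        assert select_latent_variables(np.array(curve)) == expected


class TestPLSDA:
    def _separated(self, seed=19, n=20, p=10, gap=8.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        X[n // 2 :, 0] += gap
        labels = [Group.CT] * (n // 2) + [Group.DMHBP] * (n // 2)
        return X, labels

    def test_separable_training_accuracy(self):
        X, labels = self._separated()
        m = plsda_fit(X, labels, 2)
        assert plsda_classify(m, X) == labels

    def test_boundary_score_goes_to_disease_class(self):
        m = PLSModel(
            n_lv=1,
            x_mean=np.zeros(3),
            y_mean=1.5,
            weights=np.zeros((1, 3)),
            x_loadings=np.zeros((1, 3)),
            y_loadings=np.zeros(1),
            regression_vector=np.zeros(3),
        )
        assert plsda_classify(m, np.zeros((1, 3))) == [Group.DMHBP]

    def test_single_class_rejected(self):
        X = np.random.default_rng(20).normal(size=(6, 4))
        with pytest.raises(ValueError, match="both classes"):
            plsda_fit(X, [Group.CT] * 6, 1)


class TestLDA:
    def test_widely_separated_classes_classified_perfectly(self):
        rng = np.random.default_rng(21)
        n = 50
        a = rng.normal(0.0, 1.0, size=(n, 3))
        b = rng.normal(10.0, 1.0, size=(n, 3))
        X = np.vstack([a, b])
        labels = [Group.CT] * n + [Group.DMHBP] * n
        m = lda_fit(X[::2], labels[::2])
        held_out = lda_classify(m, X[1::2])
        assert held_out == labels[1::2]

    def test_identical_distributions_are_chance_level(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            X = rng.normal(size=(200, 4))
            labels = [Group.CT] * 100 + [Group.DMHBP] * 100
            m = lda_fit(X[::2], labels[::2])
            pred = lda_classify(m, X[1::2])
            accs.append(np.mean([p == t for p, t in zip(pred, labels[1::2])]))
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_boundary_matches_closed_form_discriminant(self):
        # two features, equal spherical covariance: the discriminant is
        # w = S^-1 (mu2 - mu1), threshold at the midpoint (equal priors)
        rng = np.random.default_rng(22)
        mu1, mu2 = np.array([0.0, 0.0]), np.array([2.0, 1.0])
        a = rng.normal(size=(40, 2)) + mu1
        b = rng.normal(size=(40, 2)) + mu2
        X = np.vstack([a, b])
        labels = [Group.CT] * 40 + [Group.DMHBP] * 40
        m = lda_fit(X, labels)
        Sinv = np.linalg.inv(m.pooled_covariance)
        w = Sinv @ (m.class_means[1] - m.class_means[0])
        c = 0.5 * (m.class_means[1] + m.class_means[0]) @ w
        grid_pts = rng.normal(loc=1.0, size=(200, 2))
        expected = [
            Group.DMHBP if g @ w - c > 0 else Group.CT for g in grid_pts
        ]
        got = lda_classify(m, grid_pts)
        mism = [i for i, (e, g) in enumerate(zip(expected, got)) if e != g]
        for i in mism:  # only points numerically on the boundary may differ
            assert abs(grid_pts[i] @ w - c) < 1e-8

    def test_small_class_rejected(self):
        X = np.random.default_rng(23).normal(size=(3, 2))
        with pytest.raises(ValueError):
            lda_fit(X, [Group.CT, Group.CT, Group.DMHBP])
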