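"""Cross-validated PCA + OLS decoder: folds, oracles, leakage guards."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import neurovoc as nv
from neurovoc.decoder import (
    FoldSpec,
    apply_pca,
    fit_linear,
    fit_pca,
    predict,
)
from neurovoc.neural_features import Normalizer


class TestFolds:
    @given(n=st.integers(10, 5000), k=st.integers(2, 10))
    def test_partition_properties(self, n, k):
        """Contiguous, disjoint, exhaustive blocks with sizes differing by <= 1."""
        folds = nv.make_folds(n, k)
        assert len(folds) == k
        all_test = np.concatenate([f.test_rows for f in folds])
        np.testing.assert_array_equal(np.sort(all_test), np.arange(n))
        sizes = [f.test_rows.size for f in folds]
        assert max(sizes) - min(sizes) <= 1
        for f in folds:
            np.testing.assert_array_equal(
                f.test_rows, np.arange(f.test_rows[0], f.test_rows[-1] + 1)
            )

    def test_examples(self):
        folds = nv.make_folds(100, 10)
        np.testing.assert_array_equal(folds[0].test_rows, np.arange(10))
        sizes = {f.test_rows.size for f in nv.make_folds(29956, 10)}
        assert sizes == {2995, 2996}
        assert all(f.test_rows.size == 1 for f in nv.make_folds(10, 10))

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            nv.make_folds(5, 10)


class TestPCA:
    def test_explained_variance_matches_direct_svd(self, rng):
        """PCA variance ratios agree with a from-scratch SVD to 1e-8."""
        x = rng.normal(size=(200, 30)) @ rng.normal(size=(30, 30))
        model = fit_pca(x, n_components=10)
        xc = x - x.mean(axis=0)
        s = np.linalg.svd(xc, compute_uv=False)
        ratios = s**2 / np.sum(s**2)
        np.testing.assert_allclose(
            model.explained_variance_ratio, ratios[:10], atol=1e-8
        )

    def test_rank_deficiency_capped_not_fatal(self, rng):
        basis = rng.normal(size=(3, 20))
        x = rng.normal(size=(100, 3)) @ basis
        model = fit_pca(x, n_components=50)
        assert model.n_components == 20  # capped at n_features
        assert np.all(model.explained_variance_ratio[3:] < 1e-12)

    def test_projection_decorrelated(self, rng):
        x = rng.normal(size=(300, 12))
        model = fit_pca(x, n_components=5)
        proj = apply_pca(model, x)
        cov = np.cov(proj.T)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) / np.max(np.diag(cov)) < 1e-8

    def test_components_orthonormal(self, rng):
        model = fit_pca(rng.normal(size=(100, 15)), n_components=8)
        np.testing.assert_allclose(
            model.components.T @ model.components, np.eye(8), atol=1e-10
        )


class TestLinearRegression:
    def test_realizable_target_perfect(self, rng):
        x = rng.normal(size=(500, 8))
        w = rng.normal(size=(8, 3))
        y = x @ w + 2.0
        dec = fit_linear(x[:400], y[:400])
        r_train = nv.pearson_per_bin(y[:400], predict(dec, x[:400]))
        r_test = nv.pearson_per_bin(y[400:], predict(dec, x[400:]))
        np.testing.assert_allclose(r_train, 1.0, atol=1e-9)
        assert np.all(r_test > 0.999)

    def test_noise_target_null_level(self, rng):
        """Held-out correlation on pure noise stays within the 2/sqrt(n) band."""
        x = rng.normal(size=(6000, 50))
        y = rng.normal(size=(6000, 4))
        dec = fit_linear(x[:3000], y[:3000])
        r = nv.pearson_per_bin(y[3000:], predict(dec, x[3000:]))
        assert np.all(np.abs(r) < 0.08)

    def test_intercept_only(self, rng):
        x = np.ones((100, 3))
        y = rng.normal(size=(100, 2))
        pred = predict(fit_linear(x, y), x)
        np.testing.assert_allclose(pred, y.mean(axis=0)[None, :].repeat(100, 0), atol=1e-9)

    def test_residual_orthogonality(self, rng):
        x = rng.normal(size=(400, 10))
        y = rng.normal(size=(400, 5))
        dec = fit_linear(x, y)
        resid = y - predict(dec, x)
        x1 = np.column_stack([np.ones(400), x])
        rel = np.max(np.abs(x1.T @ resid)) / (np.linalg.norm(x1) * np.linalg.norm(y))
        assert rel < 1e-6


class TestRunCV:
    def test_planted_session_recovery(self, small_fit):
        """Parameter-recovery oracle: planted coupling decodes well above chance."""
        _, results = small_fit
        assert results.mean_correlation > 0.5

    def test_shuffled_target_at_chance(self, small_fit, rng):
        model, _ = small_fit
        y = np.array(model.targets)
        shuffled = y[rng.permutation(y.shape[0])]
        res = nv.run_cv(model.features, shuffled)
        assert abs(res.mean_correlation) < 0.05

    def test_every_row_predicted_once(self, small_fit):
        model, results = small_fit
        assert results.predicted.shape == model.targets.shape
        assert np.all(np.isfinite(results.predicted))
        covered = np.concatenate([f.spec.test_rows for f in results.fold_fits])
        np.testing.assert_array_equal(np.sort(covered), np.arange(model.targets.shape[0]))

    def test_deterministic(self, small_fit):
        model, results = small_fit
        again = nv.run_cv(model.features, model.targets)
        np.testing.assert_array_equal(again.predicted, results.predicted)
        np.testing.assert_array_equal(again.fold_correlations, results.fold_correlations)

    def test_no_leakage_from_test_rows(self, small_fit):
        """Refit from train rows only (test rows NaN-corrupted) reproduces every
        fold's fitted normalizer, PCA and regression bit-for-bit."""
        model, results = small_fit
        X = np.array(model.features.values)
        Y = np.array(model.targets)
        for fold in results.fold_fits:
            Xc, Yc = X.copy(), Y.copy()
            Xc[fold.spec.test_rows] = np.nan
            Yc[fold.spec.test_rows] = np.nan
            norm = Normalizer().fit(Xc[fold.spec.train_rows])
            np.testing.assert_array_equal(norm.mean, fold.normalizer.mean)
            np.testing.assert_array_equal(norm.std, fold.normalizer.std)
            Xtr = norm.transform(Xc[fold.spec.train_rows])
            pca = fit_pca(Xtr, results.n_components)
            np.testing.assert_array_equal(pca.components, fold.pca.components)
            reg = fit_linear(apply_pca(pca, Xtr), Yc[fold.spec.train_rows])
            np.testing.assert_array_equal(reg.weights, fold.regression.weights)

    def test_summary_mentions_headline_numbers(self, small_fit):
        _, results = small_fit
        text = results.summary()
        assert f"{results.mean_correlation:.4f}" in text
        assert "folds: 10" in text

    def test_misaligned_rows_rejected(self, small_fit):
        model, _ = small_fit
        with pytest.raises(nv.errors.DimensionError):
            nv.run_cv(model.features, np.array(model.targets)[:-5])


class TestModelObject:
    def test_from_session_alignment(self, small_session):
        model = nv.SpectrogramDecoder.from_session(small_session)
        assert model.features.values.shape[0] == model.targets.shape[0]
        assert model.features.values.shape[1] == 9 * small_session.n_channels
        assert model.targets.shape[1] == 23
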