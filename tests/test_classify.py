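import numpy as np
import pytest

from lareims.classify import (FeatureMatrix, PCALDA, confusion_metrics,
                              cross_modality_eval, cross_validate, fit_pca,
                              fit_pca_lda, volcano)


def _gaussian_classes(n_per_class=20, n_features=30, separation=10.0,
                      seed=3, classes=("a", "b")):
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for i, cls in enumerate(classes):
        mean = np.zeros(n_features)
        mean[i] = separation
        blocks.append(np.abs(rng.normal(mean, 1.0,
                                        (n_per_class, n_features))))
        labels += [cls] * n_per_class
    return FeatureMatrix(X=np.vstack(blocks), labels=np.array(labels))


class TestPCA:
    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(0)
        direction = rng.random(20)
        X = np.outer(rng.random(15), direction)
        comps, ratios, scores = fit_pca(X, 3)
        assert ratios[0] == pytest.approx(1.0, abs=1e-10)

    def test_scores_are_centered(self):
        rng = np.random.default_rng(1)
        X = rng.random((12, 8))
        _c, _r, scores = fit_pca(X, 4)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-12)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, 6))
        comps, _r, scores = fit_pca(X, 6)
        recon = scores @ comps + X.mean(axis=0)
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        X = rng.random((15, 40))
        comps, _r, _s = fit_pca(X, 8)
        np.testing.assert_allclose(comps @ comps.T, np.eye(len(comps)),
                                   atol=1e-10)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.random.default_rng(0).random((5, 10)), 5)

    def test_matches_sklearn_oracle(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(4)
        X = rng.random((25, 12))
        comps, ratios, _ = fit_pca(X, 5)
        ref = PCA(n_components=5).fit(X)
        np.testing.assert_allclose(np.abs(comps), np.abs(ref.components_),
                                   atol=1e-8)
        np.testing.assert_allclose(ratios, ref.explained_variance_ratio_,
                                   atol=1e-8)


class TestPCALDA:
    def test_overwhelming_separation_trains_perfectly(self):
        fm = _gaussian_classes(separation=10.0, seed=3)
        model = fit_pca_lda(fm, k=10)
        assert np.mean(model.predict(fm.X) == fm.labels) == 1.0

    def test_deterministic_refit(self):
        fm = _gaussian_classes(seed=5)
        a = fit_pca_lda(fm, k=8)
        b = fit_pca_lda(fm, k=8)
        np.testing.assert_array_equal(a.components_, b.components_)
        np.testing.assert_array_equal(a.scalings_, b.scalings_)
        np.testing.assert_array_equal(a.centroids_, b.centroids_)

    def test_discriminant_count_bounded(self):
        fm = _gaussian_classes(classes=("a", "b", "c"), seed=6)
        model = fit_pca_lda(fm, k=10)
        assert model.scalings_.shape[1] <= 2

    def test_single_class_rejected(self):
        X = np.abs(np.random.default_rng(0).random((10, 5)))
        with pytest.raises(ValueError):
            PCALDA().fit(X, np.array(["a"] * 10))

    def test_label_permutation_null(self):
        """Randomly permuted labels (global null) give chance-level CV."""
        fm = _gaussian_classes(n_per_class=20, separation=10.0, seed=3)
        rng = np.random.default_rng(0)
        null = FeatureMatrix(X=fm.X, labels=rng.permutation(fm.labels))
        report = cross_validate(null, n_repeats=25, seed=1)
        accuracy = float(report.per_repeat_accuracy.mean()) * 100.0
        assert 30.0 <= accuracy <= 70.0

    def test_sklearn_pipeline_compatible(self):
        from sklearn.base import clone
        from sklearn.model_selection import cross_val_score

        fm = _gaussian_classes(separation=8.0)
        est = clone(PCALDA(n_components=5))
        scores = cross_val_score(est, fm.X, fm.labels, cv=3)
        assert scores.mean() > 0.9

    def test_agrees_with_sklearn_lda_reference(self):
        """Nearest-centroid PCA-LDA vs sklearn PCA->LDA: identical labels on
        random well-separated synthetic datasets."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.decomposition import PCA

        for seed in range(5):
            fm = _gaussian_classes(n_per_class=15, separation=6.0, seed=seed)
            ours = PCALDA(n_components=5).fit(fm.X, fm.labels)
            scores = PCA(n_components=5).fit_transform(fm.X)
            ref = LinearDiscriminantAnalysis().fit(scores, fm.labels)
            ref_pred = ref.predict(scores)
            np.testing.assert_array_equal(ours.predict(fm.X), ref_pred)


class TestCrossValidate:
    def test_split_sizes_stratified(self):
        fm = _gaussian_classes(n_per_class=20)
        from lareims.classify import _stratified_split

        rng = np.random.default_rng(0)
        train, test = _stratified_split(fm.labels, 0.2, rng)
        for cls in ("a", "b"):
            n_test = np.sum(fm.labels[test] == cls)
            assert abs(n_test - 4) <= 1

    def test_separable_classes_are_perfect(self):
        fm = _gaussian_classes(separation=12.0, seed=7)
        report = cross_validate(fm, n_repeats=10, seed=2, positive_class="a")
        assert report.sensitivity == 100.0
        assert report.specificity == 100.0

    def test_seeded_report_identical(self):
        fm = _gaussian_classes(seed=8)
        a = cross_validate(fm, n_repeats=5, seed=3)
        b = cross_validate(fm, n_repeats=5, seed=3)
        assert a.confusion.equals(b.confusion)
        np.testing.assert_array_equal(a.per_repeat_accuracy,
                                      b.per_repeat_accuracy)

    def test_group_aware_splitting(self):
        fm = _gaussian_classes(n_per_class=20, seed=9)
        groups = np.repeat(np.arange(8), 5)   # 4 specimens per class
        report = cross_validate(fm, n_repeats=5, seed=0, groups=groups)
        assert report.n_repeats == 5

    def test_tiny_class_rejected(self):
        X = np.abs(np.random.default_rng(0).random((5, 4)))
        labels = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError):
            cross_validate(FeatureMatrix(X=X, labels=labels))


class TestCrossModality:
    def test_identity_transfer_equals_training_performance(self):
        fm = _gaussian_classes(separation=10.0, seed=10)
        res = cross_modality_eval(fm, fm)
        model = fit_pca_lda(fm)
        train_acc = {cls: 100.0 * np.mean(
            model.predict(fm.X[fm.labels == cls]) == cls)
            for cls in np.unique(fm.labels)}
        assert res == train_acc

    def test_perturbed_copy_transfers_well(self):
        fm = _gaussian_classes(n_per_class=30, separation=8.0, seed=11)
        rng = np.random.default_rng(12)
        gain = rng.lognormal(0.0, 0.1, fm.X.shape[1])
        other = FeatureMatrix(X=fm.X * gain, labels=fm.labels)
        res = cross_modality_eval(fm, other)
        assert all(v >= 85.0 for v in res.values())

    def test_disjoint_bin_axes_rejected(self):
        a = _gaussian_classes(seed=13)
        b = FeatureMatrix(X=a.X[:, :10], labels=a.labels)
        with pytest.raises(ValueError, match="bin axes"):
            cross_modality_eval(a, b)


class TestConfusionMetrics:
    def test_arithmetic(self):
        truth = ["t"] * 10 + ["n"] * 20
        pred = ["t"] * 9 + ["n"] + ["n"] * 19 + ["t"]
        m = confusion_metrics(truth, pred, "t")
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(95.0)

    def test_all_correct(self):
        m = confusion_metrics(["t", "n"], ["t", "n"], "t")
        assert m["sensitivity"] == 100.0
        assert m["specificity"] == 100.0

    def test_undefined_flagged(self):
        m = confusion_metrics(["n", "n"], ["n", "n"], "t")
        assert np.isnan(m["sensitivity"])
        assert m["sensitivity_undefined"]


class TestVolcano:
    def _null_fm(self, n=20, bins=50, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(0.0, 0.3, (2 * n, bins))
        labels = np.array(["a"] * n + ["b"] * n)
        return FeatureMatrix(X=X, labels=labels)

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(1)
        half = rng.lognormal(0.0, 0.3, (10, 40))
        fm = FeatureMatrix(X=np.vstack([half, half]),
                           labels=np.array(["a"] * 10 + ["b"] * 10))
        res = volcano(fm)
        np.testing.assert_allclose(res.log2_fold_change, 0.0, atol=1e-12)
        assert res.n_significant == 0
        assert np.all(res.q_values >= res.p_values - 1e-15)

    def test_planted_tenfold_bin_recovered(self):
        fm = self._null_fm(n=20, seed=5)
        fm.X[fm.labels == "a", 7] *= 10.0
        res = volcano(fm)
        assert res.significant[7]
        assert res.log2_fold_change[7] > 1.0

    def test_fdr_controlled_under_global_null(self):
        """Mean significant fraction <= 0.06 at q = 0.05 over 100 global-null
        replicates (200 bins, 20 vs 20)."""
        fractions = []
        for rep in range(100):
            fm = self._null_fm(n=20, bins=200, seed=100 + rep)
            res = volcano(fm)
            fractions.append(res.n_significant / 200.0)
        assert np.mean(fractions) <= 0.06

    def test_small_group_rejected(self):
        fm = FeatureMatrix(X=np.abs(np.random.default_rng(0).random((5, 4))),
                           labels=np.array(["a", "a", "b", "b", "b"]))
        with pytest.raises(ValueError):
            volcano(fm)
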