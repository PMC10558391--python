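"""PLS-LDA: NIPALS fit, LDA eigenproblem, cross-validation, loadings."""

import dataclasses

import numpy as np
import pytest

from glycoscope import chemometrics as chem, spectra as sp, synthetic as syn


def make_separable(rng, n_per_class=20, n_features=40, classes=(0, 1, 2), gap=5.0):
    X = np.vstack([rng.normal(gap * i, 1.0, (n_per_class, n_features)) for i, _ in enumerate(classes)])
    y = np.repeat(classes, n_per_class)
    return X, y


class TestFitPLS:
    def test_rank_one_data_single_component_separates(self, rng):
        v = rng.normal(size=30)
        t_true = np.concatenate([rng.uniform(-2, -1, 15), rng.uniform(1, 2, 15)])
        X = np.outer(t_true, v)
        y = (t_true > 0).astype(int)
        Y = np.column_stack([1.0 - y, y])
        model = chem.fit_pls(X, Y, 1)
        scores = model.transform(X)[:, 0]
        assert (scores[y == 1].min() > scores[y == 0].max()) or (
            scores[y == 1].max() < scores[y == 0].min()
        )

    def test_duplicated_rows_get_identical_scores(self, rng):
        X, y = make_separable(rng)
        X2 = np.vstack([X, X[:3]])
        Y2 = chem._one_hot(np.concatenate([y, y[:3]]), np.unique(y))
        model = chem.fit_pls(X2, Y2, 3)
        T = model.transform(X2)
        np.testing.assert_allclose(T[:3], T[-3:], atol=1e-10)

    def test_matches_sklearn_nipals_up_to_sign(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = make_separable(rng, n_per_class=14, n_features=30)
        Y = chem._one_hot(y, np.unique(y))
        ours = chem.fit_pls(X, Y, 5).transform(X)
        theirs = sklearn.PLSRegression(
            n_components=5, scale=False, tol=1e-12, max_iter=5000
        ).fit(X, Y).transform(X)
        for j in range(5):
            c = np.corrcoef(ours[:, j], theirs[:, j])[0, 1]
            assert abs(c) > 1 - 1e-8
            np.testing.assert_allclose(np.abs(ours[:, j]), np.abs(theirs[:, j]), atol=1e-4)

    def test_invalid_inputs(self, rng):
        X, y = make_separable(rng, n_per_class=5)
        Y = chem._one_hot(y, np.unique(y))
        with pytest.raises(ValueError):
            chem.fit_pls(X, Y, X.shape[0])  # > n_samples - 1
        X[0] = 0.0
        with pytest.raises(ValueError):
            chem.fit_pls(X, Y, 2)


class TestFitLDA:
    def test_two_class_direction_equals_fisher_closed_form(self, rng):
        for _ in range(20):
            n0, n1 = rng.integers(5, 15, 2)
            k = int(rng.integers(2, 6))
            s0 = rng.normal(0, 1, (n0, k))
            s1 = rng.normal(rng.normal(0, 3, k), 1, (n1, k))
            scores = np.vstack([s0, s1])
            labels = np.array([0] * n0 + [1] * n1)
            model = chem.fit_lda(scores, labels)
            m0, m1 = s0.mean(axis=0), s1.mean(axis=0)
            Sw = (s0 - m0).T @ (s0 - m0) + (s1 - m1).T @ (s1 - m1)
            fisher = np.linalg.solve(Sw, m0 - m1)
            d = model.directions[:, 0]
            cos = abs(fisher @ d) / (np.linalg.norm(fisher) * np.linalg.norm(d))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_well_separated_classes_split_on_ld1(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])[:, None]
        labels = np.repeat([0, 1], 50)
        model = chem.fit_lda(scores, labels)
        proj = model.transform(scores)[:, 0]
        assert proj[labels == 0].max() < proj[labels == 1].min() or (
            proj[labels == 0].min() > proj[labels == 1].max()
        )

    def test_five_classes_give_four_discriminants(self, rng):
        X, y = make_separable(rng, classes=(0, 1, 2, 3, 4), n_features=10)
        model = chem.fit_lda(X, y)
        assert model.directions.shape[1] == 4
        assert np.all(np.diff(model.eigenvalues) <= 1e-9)  # sorted descending

    def test_preconditions(self, rng):
        with pytest.raises(ValueError):
            chem.fit_lda(rng.normal(size=(10, 3)), np.zeros(10))  # one class
        with pytest.raises(ValueError):
            chem.fit_lda(rng.normal(size=(3, 2)), np.array([0, 1, 1]))  # class of 1


class TestPLSLDA:
    def test_separable_resubstitution_is_perfect(self, rng):
        X, y = make_separable(rng, classes=(0, 1, 2, 3, 4))
        model = chem.fit_plslda(X, labels=y, n_components=6)
        assert (model.predict(X) == y).mean() == 1.0

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError):
            chem.fit_plslda(X, labels=np.zeros(10), n_components=2)

    def test_row_permutation_leaves_predictions_invariant(self, rng):
        X, y = make_separable(rng)
        perm = rng.permutation(len(y))
        m1 = chem.fit_plslda(X, labels=y, n_components=4)
        m2 = chem.fit_plslda(X[perm], labels=y[perm], n_components=4)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


class TestKFoldCV:
    def test_separable_dataset_is_perfectly_classified(self, rng):
        X, y = make_separable(rng, n_per_class=25, classes=(0, 1, 2, 3, 4))
        rep = chem.kfold_cv(X, labels=y, K=5, n_components=5, seed=0)
        assert rep.accuracy == 1.0
        assert np.allclose(rep.sensitivity, 1.0) and np.allclose(rep.specificity, 1.0)

    def test_seed_determinism(self, rng):
        X, y = make_separable(rng, gap=0.5)
        a = chem.kfold_cv(X, labels=y, K=5, n_components=3, seed=7)
        b = chem.kfold_cv(X, labels=y, K=5, n_components=3, seed=7)
        np.testing.assert_array_equal(a.confusion, b.confusion)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)

    def test_label_permutation_null_is_at_chance(self, rng):
        # shuffled labels: accuracy should sit near 1/n_classes
        X, _ = make_separable(rng, n_per_class=40, classes=(0, 1, 2, 3, 4), gap=3.0)
        y = rng.permutation(np.repeat([0, 1, 2, 3, 4], 40))
        rep = chem.kfold_cv(X, labels=y, K=5, n_components=5, seed=1)
        n = len(y)
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(rep.accuracy - 0.2) <= 3 * se + 1e-9

    def test_confusion_row_sums_equal_class_sizes(self, rng):
        X, y = make_separable(rng, n_per_class=13, gap=0.3)
        rep = chem.kfold_cv(X, labels=y, K=5, n_components=3, seed=0)
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), [13, 13, 13])
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / rep.confusion.sum())

    def test_class_smaller_than_k_rejected(self, rng):
        X = rng.normal(size=(7, 5))
        y = np.array([0, 0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="fewer than K"):
            chem.kfold_cv(X, labels=y, K=5, n_components=2, seed=0)

    def test_accuracy_monotone_in_glycation_effect(self):
        # stronger band changes -> better separability, within sampling error
        accs = {}
        for effect in (0.1, 0.4, 0.8):
            vals = []
            for seed in range(5):
                cfg = syn.RamanGenConfig(seed=seed)
                presets = [
                    syn.glycation_preset(0, 30),
                    syn.GlycationPreset(200, 30, effect, 0.2, 20.0),
                ]
                ds = syn.generate_raman_dataset(cfg, presets, 25)
                pre, _ = sp.preprocess_dataset(ds, syn.untreated_reference(cfg))
                vals.append(chem.kfold_cv(pre, K=5, n_components=5, seed=0).accuracy)
            accs[effect] = np.mean(vals)
        assert accs[0.1] <= accs[0.4] + 0.02
        assert accs[0.4] <= accs[0.8] + 0.02


class TestConfusionMetrics:
    def test_perfect_diagonal(self):
        sens, spec, acc = chem.confusion_metrics(np.diag([20] * 5))
        assert np.allclose(sens, 1.0) and np.allclose(spec, 1.0) and acc == 1.0

    def test_hand_computed_two_class(self):
        sens, spec, acc = chem.confusion_metrics(np.array([[8, 2], [4, 6]]))
        np.testing.assert_allclose(sens, [0.8, 0.6])
        np.testing.assert_allclose(spec, [0.6, 0.8])
        assert acc == pytest.approx(0.7)

    def test_degenerate_single_column(self):
        sens, spec, acc = chem.confusion_metrics(np.array([[5, 0], [7, 0]]))
        np.testing.assert_allclose(sens, [1.0, 0.0])
        assert acc == pytest.approx(5 / 12)

    def test_zero_row_warns_and_gives_nan(self):
        with pytest.warns(UserWarning, match="zero true members"):
            sens, _, _ = chem.confusion_metrics(np.array([[0, 0], [1, 9]]))
        assert np.isnan(sens[0])


class TestLDLoadings:
    def _dataset_differing_at_1372(self, rng, flip=False):
        w = np.arange(800.0, 1751.0, 2.0)
        base = syn.spectrum_from_bands(syn.make_collagen_bands(), w)
        extra = syn.spectrum_from_bands([syn.BandSpec(1372.0, 30.0, 0.25)], w)
        X = np.vstack(
            [base + rng.normal(0, 0.005, w.size) for _ in range(20)]
            + [base + extra + rng.normal(0, 0.005, w.size) for _ in range(20)]
        )
        if flip:
            X = -X
        return w, X, np.repeat([0, 1], 20)

    def test_ld1_loading_peaks_at_the_discriminating_band(self, rng):
        w, X, y = self._dataset_differing_at_1372(rng)
        model = chem.fit_plslda(sp.SpectralDataset(w, X), labels=y, n_components=3)
        load = chem.ld_loadings(model)
        peak = load.wavenumbers[np.argmax(np.abs(load.loadings[0]))]
        assert abs(peak - 1372.0) <= 10.0
        np.testing.assert_array_equal(load.wavenumbers, w)

    def test_sign_convention_is_flip_invariant(self, rng):
        w, X, y = self._dataset_differing_at_1372(rng)
        m_pos = chem.fit_plslda(sp.SpectralDataset(w, X), labels=y, n_components=3)
        m_neg = chem.fit_plslda(sp.SpectralDataset(w, -X), labels=y, n_components=3)
        l_pos = chem.ld_loadings(m_pos).loadings[0]
        l_neg = chem.ld_loadings(m_neg).loadings[0]
        # the convention (largest-magnitude element positive) makes both equal
        np.testing.assert_allclose(l_pos, l_neg, atol=1e-6)
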