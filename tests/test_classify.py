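"""Weighted logistic classification, group-wise LOOCV, RFE, ROC."""

import warnings

import numpy as np
import pytest

from msipipe import (LabelledSpectra, compare_models, fit_weighted_logreg,
                     loocv_groups, rfe)


def _separable_data(rng, n=120, n_feat=5, n_groups=6, gap=4.0):
    y = np.repeat(["neg", "pos"], n // 2)
    X = rng.normal(0, 1, (n, n_feat))
    X[y == "pos", 0] += gap
    groups = np.tile(np.arange(n_groups), n // n_groups)
    return LabelledSpectra(X, y, groups)


class TestFitWeightedLogreg:
    def test_separable_1d_training_accuracy_one(self, rng):
        X = np.concatenate([rng.uniform(0, 1, 20),
                            rng.uniform(2, 3, 20)])[:, None]
        y = np.repeat([0, 1], 20)
        model = fit_weighted_logreg(X, y, ridge=1e-4)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_balanced_classes_match_unweighted_fit(self, rng):
        X = rng.normal(0, 1, (80, 4))
        y = np.repeat([0, 1], 40)
        X[y == 1] += 0.8
        w = fit_weighted_logreg(X, y, class_weights="balanced")
        u = fit_weighted_logreg(X, y, class_weights=None)
        assert np.allclose(w.coef, u.coef, atol=1e-8)
        assert np.isclose(w.intercept, u.intercept, atol=1e-8)

    def test_inverse_frequency_weighting_shifts_intercept_to_minority(self, rng):
        """2:1 imbalance, positive minority: balancing raises the
        positive-class intercept relative to the unweighted fit."""
        n_neg, n_pos = 80, 40
        X = np.concatenate([rng.normal(0, 1, n_neg),
                            rng.normal(1.0, 1, n_pos)])[:, None]
        y = np.repeat([0, 1], [n_neg, n_pos])
        w = fit_weighted_logreg(X, y, class_weights="balanced")
        u = fit_weighted_logreg(X, y, class_weights=None)
        assert w.intercept > u.intercept

    def test_zero_variance_feature_dropped_with_warning(self, rng):
        X = np.column_stack([rng.normal(0, 1, 40), np.full(40, 2.0)])
        y = np.repeat([0, 1], 20)
        X[y == 1, 0] += 3
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_weighted_logreg(X, y)
        assert model.kept.tolist() == [0]

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            fit_weighted_logreg(rng.normal(0, 1, (10, 2)), np.zeros(10))


class TestLoocvGroups:
    def test_singleton_groups_reduce_to_classical_loo(self, rng):
        data = _separable_data(rng, n=24, n_groups=6)
        singleton = LabelledSpectra(data.X, data.y, np.arange(24))
        rep = loocv_groups(singleton)
        assert np.all(np.isfinite(rep.proba))
        assert rep.auc > 0.9

    def test_separable_classes_auc_near_one(self):
        rng = np.random.default_rng(3)
        data = _separable_data(rng, n=120, n_groups=6, gap=4.0)
        rep = loocv_groups(data)
        assert rep.auc >= 0.99

    def test_label_permutation_null_auc_half(self):
        """100 label permutations of separable data: mean held-out AUC
        in 0.5 +- 0.05."""
        rng = np.random.default_rng(17)
        data = _separable_data(rng, n=60, n_feat=3, n_groups=6)
        aucs = []
        for _ in range(100):
            y_perm = rng.permutation(data.y)
            if np.unique(y_perm).size < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = loocv_groups(LabelledSpectra(data.X, y_perm, data.groups))
            aucs.append(rep.auc)
        assert abs(np.nanmean(aucs) - 0.5) <= 0.05

    def test_fold_lacking_class_skipped_with_warning(self, rng):
        X = rng.normal(0, 1, (12, 2))
        y = np.array(["a"] * 6 + ["b"] * 6)
        groups = np.array([0] * 6 + [1] * 6)   # each fold trains one class
        with pytest.warns(UserWarning, match="lacks a class"):
            rep = loocv_groups(LabelledSpectra(X, y, groups))
        assert set(rep.skipped_groups) == {0, 1}

    def test_no_leakage_from_test_samples_into_their_fold(self, rng):
        """A fold's model is trained only on other groups: deleting one
        of group 0's samples leaves the held-out predictions of the rest
        of group 0 unchanged (its training set did not contain it)."""
        data = _separable_data(rng, n=60, n_groups=6)
        full = loocv_groups(data)
        drop = np.nonzero(data.groups == 0)[0][0]
        keep = np.ones(60, dtype=bool)
        keep[drop] = False
        reduced = loocv_groups(LabelledSpectra(
            data.X[keep], data.y[keep], data.groups[keep]))
        g0 = data.groups[keep] == 0
        assert np.allclose(reduced.proba[g0], full.proba[keep][g0])

    def test_auc_invariant_under_monotone_probability_transform(self, rng):
        from sklearn.metrics import auc as sk_auc
        from sklearn.metrics import roc_curve
        data = _separable_data(rng, n=60, n_groups=6, gap=1.0)
        rep = loocv_groups(data)
        y_bin = (data.y == rep.positive_class).astype(int)
        fpr, tpr, _ = roc_curve(y_bin, np.sqrt(rep.proba))
        assert sk_auc(fpr, tpr) == pytest.approx(rep.auc, abs=1e-12)


class TestRFE:
    def test_n_target_equal_n_is_identity(self, rng):
        data = _separable_data(rng, n=40, n_feat=4, n_groups=4)
        ranking, selected = rfe(data, n_target=4)
        assert selected.tolist() == [0, 1, 2, 3]
        assert np.all(ranking == ranking[0])

    def test_single_shot_elimination_equals_weight_sort(self, rng):
        """step = N - n_target: one elimination round must keep exactly
        the top-|weight| features of the initial fit."""
        data = _separable_data(rng, n=80, n_feat=6, n_groups=4)
        model = fit_weighted_logreg(data.X, data.y)
        order = np.argsort(np.abs(model.coef), kind="mergesort")
        expected = sorted(order[-2:].tolist())
        _, selected = rfe(data, step=4, n_target=2)
        assert sorted(selected.tolist()) == expected

    def test_planted_feature_recovered_across_seeds(self):
        """One informative feature among 49 nulls, 200 samples: survives
        to the final subset in >= 95% of 20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (200, 50))
            y = np.repeat([0, 1], 100)
            X[y == 1, 7] += 2.0
            groups = np.tile(np.arange(5), 40)
            _, selected = rfe(LabelledSpectra(X, y, groups),
                              step=0.1, n_target=5)
            hits += 7 in selected
        assert hits / 20 >= 0.95

    def test_n_target_beyond_n_raises(self, rng):
        data = _separable_data(rng, n=40, n_feat=4, n_groups=4)
        with pytest.raises(ValueError):
            rfe(data, n_target=5)

    def test_matches_sklearn_rfe_selection(self, rng):
        """Cross-check: single-feature-step elimination on standardized
        data selects the same subset as sklearn.feature_selection.RFE."""
        from sklearn.feature_selection import RFE as SkRFE
        from sklearn.linear_model import LogisticRegression
        X = rng.normal(0, 1, (100, 8))
        X = (X - X.mean(0)) / X.std(0)
        y = np.repeat([0, 1], 50)
        X[y == 1, 2] += 1.5
        X[y == 1, 5] += 1.0
        data = LabelledSpectra(X, y, np.tile(np.arange(5), 20))
        _, selected = rfe(data, step=1, n_target=2)
        sk = SkRFE(LogisticRegression(C=1.0, class_weight="balanced",
                                      solver="lbfgs", max_iter=5000,
                                      tol=1e-10),
                   n_features_to_select=2, step=1).fit(X, y)
        assert sorted(selected.tolist()) == sorted(
            np.nonzero(sk.support_)[0].tolist())


class TestCompareModels:
    def test_identical_subsets_identical_roc(self, rng):
        data = _separable_data(rng, n=60, n_groups=6)
        cmp = compare_models(data, np.arange(5), np.arange(5))
        assert cmp.delta_auc == 0.0
        assert np.array_equal(cmp.full.fpr, cmp.selected.fpr)
        assert np.array_equal(cmp.full.tpr, cmp.selected.tpr)

    def test_informative_subset_keeps_auc(self):
        rng = np.random.default_rng(5)
        data = _separable_data(rng, n=120, n_feat=10, n_groups=6, gap=3.0)
        cmp = compare_models(data, np.arange(10), np.array([0]))
        assert cmp.selected.auc >= cmp.full.auc - 0.05

    def test_null_subset_auc_near_half(self):
        rng = np.random.default_rng(6)
        data = _separable_data(rng, n=120, n_feat=10, n_groups=6, gap=3.0)
        cmp = compare_models(data, np.arange(10), np.array([4, 7, 9]))
        assert abs(cmp.selected.auc - 0.5) <= 0.1

    def test_empty_subset_raises(self, rng):
        data = _separable_data(rng)
        with pytest.raises(ValueError):
            compare_models(data, np.arange(5), np.array([], dtype=int))
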