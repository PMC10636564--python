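"""Class-weighted logistic model, nomogram, LOO validation, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression

from abnmap import (WeightedLogisticOutcome, build_nomogram,
                    fit_weighted_logistic, loo_auc, mann_whitney_auc_greater,
                    one_sample_t_greater, rank_auc)
from abnmap.metrics import FEATURE_COLUMNS


def frame(X, y):
    df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    df["ilae"] = np.where(np.asarray(y) == 1, 1, 2)
    df.index = pd.Index([f"s{i:03d}" for i in range(len(df))],
                        name="subject_id")
    return df


def synth_cohort(beta, intercept, n, seed):
    g = np.random.default_rng(seed)
    X = g.uniform(0, 1, size=(n, 3))
    p = 1 / (1 + np.exp(-(intercept + X @ np.asarray(beta))))
    y = (g.uniform(size=n) < p).astype(int)
    return X, y


class TestWeightedLogistic:
    def test_equalizing_weights(self):
        X, y = synth_cohort([1.0, -1.0, 0.5], 0.0, 32, 0)
        y[:12] = 1
        y[12:] = 0
        m = WeightedLogisticOutcome().fit(X, y)
        # the study's imbalance: 12 vs 20 -> weights 20/32 and 12/32
        assert m.class_weight_[1] == pytest.approx(20 / 32)
        assert m.class_weight_[0] == pytest.approx(12 / 32)

    def test_constant_features_give_weighted_balance_intercept(self):
        X = np.zeros((10, 3))
        y = np.r_[np.ones(3), np.zeros(7)]
        m = WeightedLogisticOutcome().fit(X, y)
        # equalizing weights make the weighted prevalence 1/2 -> logit 0
        np.testing.assert_allclose(m.coef_, 0.0, atol=1e-8)
        assert m.intercept_[0] == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery(self):
        # Monte-Carlo over replicate draws: every slope is recovered within
        # 25% relative error on average
        rels = []
        for seed in range(123, 133):
            X, y = synth_cohort([6.0, -4.0, -4.0], 1.0, 400, seed)
            m = WeightedLogisticOutcome().fit(X, y)
            rels.append(np.abs(m.coef_.ravel() - [6.0, -4.0, -4.0])
                        / [6.0, 4.0, 4.0])
        assert np.mean(rels, axis=0).max() < 0.25

    def test_separation_fallback(self):
        X = np.column_stack([np.r_[np.zeros(5), np.ones(5)],
                             np.zeros(10), np.zeros(10)])
        y = np.r_[np.zeros(5), np.ones(5)]
        m = WeightedLogisticOutcome().fit(X, y)
        assert m.fit_meta_["separation_fallback"]
        assert m.fit_meta_["penalty"] == pytest.approx(1e-6)
        scores = m.decision_function(X)
        assert rank_auc(scores[y == 1], scores[y == 0]) == 1.0

    def test_agrees_with_sklearn_reference(self):
        # independent cross-check: same weighted likelihood maximized by
        # sklearn's unpenalized solver on a non-separable cohort
        X, y = synth_cohort([2.0, -1.0, 0.5], -0.2, 300, 7)
        ours = WeightedLogisticOutcome().fit(X, y)
        n1 = y.sum()
        ref = LogisticRegression(
            C=np.inf, solver="newton-cholesky", tol=1e-10, max_iter=500,
            class_weight={1: (len(y) - n1) / len(y), 0: n1 / len(y)},
        ).fit(X, y)
        np.testing.assert_allclose(ours.coef_, ref.coef_, atol=1e-5)
        np.testing.assert_allclose(ours.intercept_, ref.intercept_, atol=1e-5)

    def test_sklearn_estimator_protocol(self):
        X, y = synth_cohort([1.0, 0.0, 0.0], 0.0, 50, 1)
        m = clone(WeightedLogisticOutcome(tol=1e-8)).fit(X, y)
        assert m.get_params()["tol"] == 1e-8
        proba = m.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert set(m.predict(X)) <= set(m.classes_)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            WeightedLogisticOutcome().fit(np.zeros((5, 3)), np.ones(5))

    def test_nonfinite_rejected(self):
        X = np.zeros((6, 3))
        X[0, 0] = np.inf
        with pytest.raises(ValueError):
            WeightedLogisticOutcome().fit(X, np.r_[np.ones(3), np.zeros(3)])

    def test_too_few_per_class_rejected(self):
        X, y = synth_cohort([1.0, 0.0, 0.0], 0.0, 6, 3)
        y[:] = 0
        y[0] = 1
        with pytest.raises(ValueError, match="two subjects per"):
            fit_weighted_logistic(frame(X, y))


class TestNomogram:
    def test_single_feature_spans_hundred_points(self):
        X = np.zeros((8, 3))
        X[:, 0] = np.linspace(0, 1, 8)
        m = WeightedLogisticOutcome().fit(X, np.r_[np.zeros(4), np.ones(4)])
        m.coef_ = np.array([[4.0, 0.0, 0.0]])
        m.intercept_ = np.array([-2.0])
        nomo = build_nomogram(m, frame(X, X[:, 0] > 0.5))
        pts = nomo.points(X)
        assert pts[:, 0].min() == pytest.approx(0.0)
        assert pts[:, 0].max() == pytest.approx(100.0)
        np.testing.assert_allclose(pts[:, 1:], 0.0)

    def test_negative_coefficient_points_decrease(self):
        g = np.random.default_rng(0)
        X = g.uniform(size=(20, 3))
        m = WeightedLogisticOutcome().fit(X, g.integers(0, 2, 20))
        m.coef_ = np.array([[1.0, -3.0, 0.5]])
        nomo = build_nomogram(m, frame(X, X[:, 0] > 0.5))
        tbl = nomo.breakpoint_table()
        drs_pts = tbl.loc[tbl["feature"] == "drs_meg", "points"].to_numpy()
        assert np.all(np.diff(drs_pts) < 0)
        assert (tbl["points"] >= -1e-9).all()

    def test_total_points_rank_equals_probability_rank(self, small_report):
        features = small_report["features"]
        model = small_report["model"]
        X = features[list(FEATURE_COLUMNS)].to_numpy()
        nomo = build_nomogram(model, features)
        total = nomo.total_points(X)
        proba = model.predict_proba(X)[:, 1]
        rho = stats.spearmanr(total, proba).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_threshold_classification_matches_probability(self, small_report):
        features = small_report["features"]
        model = small_report["model"]
        X = features[list(FEATURE_COLUMNS)].to_numpy()
        nomo = build_nomogram(model, features)
        np.testing.assert_array_equal(
            nomo.predict_seizure_free(X),
            model.predict_proba(X)[:, 1] > 0.5)

    def test_zero_range_everywhere_rejected(self):
        X = np.full((6, 3), 0.4)
        y = np.r_[np.ones(3), np.zeros(3)]
        m = WeightedLogisticOutcome().fit(X, y)
        with pytest.raises(ValueError, match="zero range"):
            build_nomogram(m, frame(X, y))


class TestLeaveOneOut:
    def test_separable_feature_gives_perfect_folds(self):
        X = np.zeros((12, 3))
        X[:, 0] = np.r_[np.linspace(0.6, 1.0, 6), np.linspace(0.0, 0.4, 6)]
        y = np.r_[np.ones(6), np.zeros(6)]
        res = loo_auc(frame(X, y))
        assert res.mean == res.min == res.max == 1.0
        assert res.n_folds == 12

    def test_permuted_labels_are_chance_with_optimism(self):
        # chance-level plus small-sample in-sample optimism, averaged over
        # replicate permutations of the 12/20 labels
        g = np.random.default_rng(5)
        means = []
        for _ in range(10):
            X = g.uniform(size=(32, 3))
            y = g.permutation(np.r_[np.ones(12), np.zeros(20)])
            means.append(loo_auc(frame(X, y)).mean)
        assert 0.4 <= np.mean(means) <= 0.75

    def test_duplicate_subject_removal_is_stable(self):
        # removing one copy of a duplicated subject leaves a cohort whose
        # refit (with identical recomputed weights) matches the fit on the
        # deduplicated cohort itself
        X, y = synth_cohort([2.0, -1.0, 1.0], 0.0, 40, 9)
        Xd = np.vstack([X, X[0]])
        yd = np.r_[y, y[0]]
        full = WeightedLogisticOutcome().fit(Xd, yd)
        mask = np.ones(41, dtype=bool)
        mask[40] = False
        # class weights recomputed on the 40-subject fold as in loo_auc
        refit = WeightedLogisticOutcome(
            class_weight=full.class_weight_).fit(Xd[mask], yd[mask])
        direct = WeightedLogisticOutcome(
            class_weight=full.class_weight_).fit(X, y)
        np.testing.assert_allclose(refit.coef_, direct.coef_, atol=1e-6)

    def test_heldout_mode_single_auc(self):
        X, y = synth_cohort([3.0, -2.0, 1.0], 0.0, 30, 2)
        res = loo_auc(frame(X, y), heldout=True)
        assert res.mode == "heldout"
        assert res.mean == res.min == res.max


class TestGroupStatistics:
    def test_t_closed_form(self):
        res = one_sample_t_greater([0.6, 0.7, 0.8], 0.5)
        # mean 0.7, sample SD 0.1, n 3 -> t = 0.2/(0.1/sqrt(3))
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-10)
        assert res.statistic == pytest.approx(3.4641016, abs=1e-6)
        assert res.one_tailed_p == pytest.approx(
            stats.t.sf(res.statistic, df=2))

    def test_t_null_symmetric(self):
        res = one_sample_t_greater([0.4, 0.45, 0.55, 0.6], 0.5)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.one_tailed_p == pytest.approx(0.5)

    def test_t_direction(self):
        res = one_sample_t_greater([0.1, 0.2, 0.3], 0.5)
        assert res.statistic < 0
        assert res.one_tailed_p > 0.5

    def test_t_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            one_sample_t_greater([0.5, 0.5, 0.5])

    @pytest.mark.parametrize("a, b, u, auc", [
        ([3.0, 4.0], [1.0, 2.0], 4.0, 1.0),
        ([1.0, 3.0], [2.0, 4.0], 1.0, 0.25),
        ([1.0, 2.0], [1.0, 2.0], 2.0, 0.5),
    ])
    def test_mwu_examples(self, a, b, u, auc):
        res = mann_whitney_auc_greater(a, b)
        assert res.statistic == pytest.approx(u)
        assert res.auc_effect_size == pytest.approx(auc)

    def test_mwu_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney_auc_greater([], [1.0])

    def test_mwu_auc_matches_rank_auc(self, rng):
        for _ in range(30):
            a = rng.normal(size=rng.integers(2, 15))
            b = rng.normal(size=rng.integers(2, 15))
            res = mann_whitney_auc_greater(a, b)
            assert res.auc_effect_size == pytest.approx(
                rank_auc(a, b), abs=1e-12)
            assert res.statistic == pytest.approx(
                rank_auc(a, b) * a.size * b.size, abs=1e-9)

    def test_mwu_p_matches_scipy(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=25)
        res = mann_whitney_auc_greater(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="greater")
        assert res.one_tailed_p == pytest.approx(ref.pvalue, rel=1e-6)
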