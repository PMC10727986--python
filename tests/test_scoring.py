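"""Feature selection, LOSO scoring, Youden threshold and metric formulas."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from mesovasc import scoring
from mesovasc.scoring import (ConfusionCounts, ForestConfig, bootstrap_eval,
                              classification_metrics, confusion_counts,
                              gini_importance, imbalance_check, loso_score,
                              metrics_from_counts, participant_score,
                              select_k_best, subgroup_report, youden_threshold)


class TestSelectKBest:
    def test_k_equals_p_identity(self, rng):
        X = rng.normal(size=(30, 6))
        y = np.array([0, 1] * 15)
        assert list(select_k_best(X, y, 6)) == list(range(6))

    def test_informative_feature_ranked_first(self):
        hits = 0
        for s in range(50):
            r = np.random.default_rng(s)
            X = r.normal(size=(40, 10))
            y = np.array([0] * 20 + [1] * 20)
            X[y == 1, 3] += 3.0
            hits += 3 in select_k_best(X, y, 1)
        assert hits >= 49

    def test_deterministic(self, rng):
        X = rng.normal(size=(24, 12))
        y = np.array([0, 1] * 12)
        assert np.array_equal(select_k_best(X, y, 5), select_k_best(X, y, 5))

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            select_k_best(rng.normal(size=(10, 4)), np.array([0, 1] * 5), 5)


class TestLoso:
    def _cohort(self, rng, n=30, shift=5.0, images_per=1):
        y = np.repeat([0, 1], n // 2)
        ids = np.array([f"p{i}" for i in range(n)])
        X = rng.normal(size=(n, 6))
        X[y == 1, 0] += shift
        if images_per > 1:
            X = np.repeat(X, images_per, axis=0) + rng.normal(
                0, 0.1, size=(n * images_per, 6))
            y = np.repeat(y, images_per)
            ids = np.repeat(ids, images_per)
        return X, y, ids

    def test_separable_cohort_auc_one(self, rng):
        X, y, ids = self._cohort(rng)
        part = participant_score(loso_score(X, y, ids,
                                            ForestConfig(n_estimators=50)))
        assert roc_auc_score(part["label"], part["score"]) == 1.0

    def test_probabilities_in_unit_interval(self, rng):
        X, y, ids = self._cohort(rng, shift=0.0)
        sc = loso_score(X, y, ids, ForestConfig(n_estimators=20))
        assert ((sc["probability"] >= 0) & (sc["probability"] <= 1)).all()
        assert (sc["tree_sd"] >= 0).all()

    def test_single_class_fold_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        y = np.array([0, 1, 1])
        ids = np.array(["a", "b", "c"])
        # leaving out either b or c leaves... still both classes; leaving a
        # out leaves a single class
        with pytest.raises(ValueError, match="single class"):
            loso_score(X, y, ids, ForestConfig(n_estimators=5))

    def test_participant_mean_and_bounds(self):
        df = pd.DataFrame({"participant_id": ["a", "a", "b"],
                           "probability": [0.6, 0.8, 0.3],
                           "tree_sd": [0.1, 0.1, 0.1],
                           "label": [1, 1, 0]})
        part = participant_score(df)
        assert part.loc["a", "score"] == pytest.approx(0.7)
        assert part.loc["b", "score"] == pytest.approx(0.3)
        grouped = df.groupby("participant_id")["probability"]
        assert (part["score"] >= grouped.min()).all()
        assert (part["score"] <= grouped.max()).all()


class TestYouden:
    def test_perfect_separation_midpoint(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert youden_threshold(scores, labels) == pytest.approx(0.5)

    def test_exhaustive_hand_case(self):
        scores = np.array([0.3, 0.6, 0.4, 0.9])
        labels = np.array([0, 0, 1, 1])
        t = youden_threshold(scores, labels)
        # brute force over the candidate cuts
        def J(th):
            sns = ((scores > th) & (labels == 1)).mean() * 2
            spc = ((scores <= th) & (labels == 0)).mean() * 2
            return sns + spc - 1
        assert J(t) == pytest.approx(max(J(c) for c in
                                         [0.2, 0.35, 0.5, 0.75, 1.0]))
        assert 0.3 < t < 0.4

    def test_matches_exhaustive_on_random_sets(self):
        for s in range(100):
            r = np.random.default_rng(s)
            n = int(r.integers(6, 200))
            scores = r.random(n)
            labels = r.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            t = youden_threshold(scores, labels)
            uniq = np.unique(scores)
            cands = np.concatenate([[uniq[0] - 1],
                                    (uniq[:-1] + uniq[1:]) / 2,
                                    [uniq[-1] + 1]])

            def J(th):
                sns = ((scores > th) & (labels == 1)).sum() / (labels == 1).sum()
                spc = ((scores <= th) & (labels == 0)).sum() / (labels == 0).sum()
                return sns + spc - 1

            assert J(t) == pytest.approx(max(J(c) for c in cands))

    def test_label_swap_antisymmetry(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        t = youden_threshold(scores, labels)

        def J(th, lab):
            sns = ((scores > th) & (lab == 1)).sum() / max((lab == 1).sum(), 1)
            spc = ((scores <= th) & (lab == 0)).sum() / max((lab == 0).sum(), 1)
            return sns + spc - 1

        assert J(t, labels) == pytest.approx(-J(t, 1 - labels))

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            youden_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestMetrics:
    def test_printed_formula_arithmetic(self):
        m = metrics_from_counts(ConfusionCounts(TP=40, TN=30, FP=10, FN=20))
        assert m.acc == pytest.approx(0.70)
        assert m.sns == pytest.approx(2 / 3, abs=1e-4)
        assert m.spc == pytest.approx(0.75)
        assert m.ppv == pytest.approx(0.80)
        assert m.npv == pytest.approx(0.60)

    def test_perfect_predictions(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        m = classification_metrics(scores, labels, 0.5)
        for v in (m.acc, m.sns, m.spc, m.ppv, m.npv, m.f1, m.mcc_normalized,
                  m.auc):
            assert v == 1.0

    def test_confusion_matches_bruteforce_recount(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        for thr in (0.2, 0.5, 0.8):
            c = confusion_counts(scores, labels, thr)
            tp = sum(1 for s, l in zip(scores, labels) if s > thr and l == 1)
            tn = sum(1 for s, l in zip(scores, labels) if s <= thr and l == 0)
            assert (c.TP, c.TN) == (tp, tn)
            assert c.total == 50

    def test_undefined_denominator_flagged(self):
        m = metrics_from_counts(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert m.ppv is None and "ppv" in m.undefined

    def test_sns_spc_monotone_in_threshold(self, rng):
        scores = rng.random(80)
        labels = rng.integers(0, 2, size=80)
        thresholds = np.linspace(0, 1, 21)
        sns, spc = [], []
        for t in thresholds:
            c = confusion_counts(scores, labels, t)
            sns.append(c.TP / max(c.TP + c.FN, 1))
            spc.append(c.TN / max(c.TN + c.FP, 1))
        assert np.all(np.diff(sns) <= 1e-12)
        assert np.all(np.diff(spc) >= -1e-12)

    def test_auc_equals_mannwhitney_bruteforce(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        m = classification_metrics(scores, labels, 0.5)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert m.auc == pytest.approx(wins / (len(pos) * len(neg)))


class TestBootstrapImbalanceImportance:
    def test_bootstrap_degenerate_test_set(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([0] * 15 + [1] * 15)
        clf = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        Xt = np.tile(X[y == 1][:1], (6, 1))
        out = bootstrap_eval(clf, Xt, np.ones(6, int), threshold=0.5, B=50)
        assert out["acc"]["value"] == 1.0
        assert out["acc"]["ci_low"] == out["acc"]["ci_high"] == 1.0

    def test_bootstrap_ci_contains_point(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + rng.normal(0, 1, 60) > 0).astype(int)
        clf = RandomForestClassifier(n_estimators=30, random_state=0).fit(
            X[:40], y[:40])
        out = bootstrap_eval(clf, X[40:], y[40:], threshold=0.5, B=200, seed=1)
        for v in out.values():
            assert 0 <= v["ci_low"] <= v["value"] <= v["ci_high"] <= 1

    def test_bootstrap_matches_binomial_interval(self, rng):
        # ACC of iid correct/incorrect draws: percentile bootstrap CI agrees
        # with the analytic binomial quantiles
        from scipy import stats

        n, p_correct = 120, 0.75
        correct = rng.random(n) < p_correct
        y = np.ones(n, int)
        prob = np.where(correct, 0.9, 0.1)

        class _Stub:
            classes_ = [0, 1]

            def predict_proba(self, X):
                return np.column_stack([1 - X[:, 0], X[:, 0]])

        out = bootstrap_eval(_Stub(), prob[:, None], y, threshold=0.5, B=2000,
                             seed=2)
        k = correct.sum()
        lo = stats.binom.ppf(0.025, n, k / n) / n
        hi = stats.binom.ppf(0.975, n, k / n) / n
        assert abs(out["acc"]["ci_low"] - lo) < 0.02
        assert abs(out["acc"]["ci_high"] - hi) < 0.02

    def test_imbalance_identical_scores(self):
        scores = np.concatenate([np.full(10, 0.4), np.full(50, 0.7)])
        labels = np.array([0] * 10 + [1] * 50)
        out = imbalance_check(scores, labels, subgroup_size=40, n_subsets=100,
                              seed=0)
        assert out["patient_median"] == 0.7
        assert out["patient_ci"] == (0.7, 0.7)

    def test_imbalance_planted_separation(self, rng):
        scores = np.concatenate([rng.normal(0.4, 0.05, 40),
                                 rng.normal(0.7, 0.05, 60)])
        labels = np.array([0] * 40 + [1] * 60)
        out = imbalance_check(scores, labels, subgroup_size=40, n_subsets=500,
                              seed=1)
        assert out["frac_patient_above_healthy"] == 1.0

    def test_imbalance_reproducible(self, rng):
        scores = rng.random(80)
        labels = np.array([0] * 30 + [1] * 50)
        a = imbalance_check(scores, labels, 40, 200, seed=5)
        b = imbalance_check(scores, labels, 40, 200, seed=5)
        assert np.array_equal(a["subset_medians"], b["subset_medians"])

    def test_imbalance_subgroup_too_large(self):
        with pytest.raises(ValueError):
            imbalance_check(np.ones(10), np.array([0] * 5 + [1] * 5), 40, 10)

    def test_gini_importance_properties(self, rng):
        X = rng.normal(size=(80, 6))
        y = (X[:, 2] > 0).astype(int)
        X[:, 5] = 1.0  # zero-variance feature
        clf = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        imp = gini_importance(clf)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(imp >= 0)
        assert imp[2] == imp.max()
        assert imp[5] == 0.0

    def test_gini_unfitted_error(self):
        with pytest.raises(ValueError):
            gini_importance(RandomForestClassifier())


class TestSubgroupReport:
    def test_all_correct_single_subgroup(self):
        meta = pd.DataFrame({"diabetes_type": ["I", "I", "I"]})
        out = subgroup_report([True, True, True], meta)
        assert len(out) == 1
        assert out.iloc[0]["prop_correct"] == 1.0
        assert out.iloc[0]["prop_incorrect"] == 0.0

    def test_proportions_sum_to_one(self, rng):
        meta = pd.DataFrame({"age_band": rng.choice(["<45", "45-64", ">65"], 60),
                             "hba1c_ge_6_5": rng.integers(0, 2, 60)})
        out = subgroup_report(rng.random(60) > 0.3, meta)
        assert np.allclose(out["prop_correct"] + out["prop_incorrect"], 1.0)

    def test_independent_errors_match_overall_rate(self, rng):
        n = 4000
        correct = rng.random(n) < 0.8
        meta = pd.DataFrame({"duration_band": rng.choice(list("abcd"), n)})
        out = subgroup_report(correct, meta)
        assert np.all(np.abs(out["prop_correct"] - correct.mean()) < 0.05)


class TestNestedCV:
    def test_separable_cohort_and_reporting_contract(self, rng):
        n = 24
        X = rng.normal(size=(n, 12))
        y = np.repeat([0, 1], n // 2)
        X[y == 1, 0] += 5.0
        ids = np.array([f"p{i}" for i in range(n)])
        res = scoring.nested_cv(X, y, ids, n_trials=2, k_grid=[10, 12],
                                estimator_grid=(25,),
                                max_features_grid=("sqrt",),
                                inner_folds=4, seed=0)
        mean_auc, sd_auc = res.auc
        assert mean_auc >= 0.95
        assert sd_auc >= 0.0
        k_mean, k_sd = res.k_star          # reported as mean +/- sd
        assert 10 <= k_mean <= 12 and k_sd >= 0.0
        assert len(res.per_trial) == 2

    def test_cohort_too_small_for_inner_folds(self, rng):
        X = rng.normal(size=(4, 3))
        y = np.array([0, 0, 1, 1])
        ids = np.array(list("abcd"))
        with pytest.raises(ValueError, match="inner"):
            scoring.nested_cv(X, y, ids, n_trials=1, inner_folds=4)


class TestAucConfidenceInterval:
    def test_separable_interval_is_high_and_ordered(self, rng):
        n = 40
        X = rng.normal(size=(n, 5))
        y = np.repeat([0, 1], n // 2)
        X[y == 1, 0] += 4.0
        ids = np.array([f"p{i}" for i in range(n)])
        lo, hi = scoring.auc_confidence_interval(
            X, y, ids, scoring.ForestConfig(n_estimators=20),
            n_iterations=20, seed=0)
        assert 0 <= lo <= hi <= 1
        assert lo > 0.8
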