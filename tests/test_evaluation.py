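"""ROC/Youden/fold machinery against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

import cogconv as cc
from cogconv.evaluation import (EvalConfig, aggregate_folds, clopper_pearson,
                                confusion_metrics, delong_auc_ci, roc_auc,
                                stratified_folds, youden_cutoff)


def auc_pairwise_oracle(scores, labels):
    """Concordance-probability count, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestStratifiedFolds:
    def test_cohort_of_224_gives_45x4_plus_44(self):
        labels = np.array([1] * 85 + [0] * 139)  # published class split
        folds = stratified_folds(labels, EvalConfig(k=5, seed=0))
        sizes = sorted(np.bincount(folds), reverse=True)
        assert sizes == [45, 45, 45, 45, 44]
        # class proportions off by at most one member per fold
        for f in range(5):
            pos = labels[folds == f].sum()
            assert pos in (17,)

    def test_tiny_balanced_cohort(self):
        labels = np.array([0, 1] * 5)
        folds = stratified_folds(labels, EvalConfig(k=5, seed=1))
        for f in range(5):
            sel = labels[folds == f]
            assert len(sel) == 2 and sel.sum() == 1

    def test_seeded_and_deterministic(self):
        labels = np.array([0] * 30 + [1] * 20)
        a = stratified_folds(labels, EvalConfig(k=5, seed=9))
        b = stratified_folds(labels, EvalConfig(k=5, seed=9))
        np.testing.assert_array_equal(a, b)

    def test_too_few_class_members_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array([0] * 20 + [1] * 3), EvalConfig(k=5))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_equals_pairwise_oracle(self, rng):
        for _ in range(10):
            n = rng.integers(10, 200)
            scores = rng.choice(np.round(rng.normal(size=50), 2), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_random_scores_near_half(self, rng):
        # 3-sigma U-statistic bound for n=2000 balanced: ~0.033
        scores = rng.normal(size=2000)
        labels = np.array([0, 1] * 1000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.033


class TestYouden:
    def test_separated_classes_j_one(self):
        res = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.j == 1.0

    def test_uninformative_scores_j_zero(self):
        res = youden_cutoff([0.5] * 8, [0, 1] * 4)
        assert res.j == 0.0

    def test_equals_exhaustive_search(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            res = youden_cutoff(scores, labels)
            # brute force over the same candidate set
            uniq = np.unique(scores)
            cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2,
                                    [np.inf]])
            best_j, best_t = -2.0, None
            for t in cands:
                pred = scores >= t
                sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
                spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
                if sens + spec - 1 > best_j:
                    best_j, best_t = sens + spec - 1, t
            assert res.j == pytest.approx(best_j, abs=1e-12)
            assert res.threshold == best_t  # ties -> lowest threshold


class TestConfusionMetrics:
    def test_sensitivity_14_of_16_exact_ci(self):
        """Published fold: sensitivity 0.875 (0.617-0.984) from 14/16."""
        lo, hi = clopper_pearson(14, 16)
        sm_lo, sm_hi = proportion_confint(14, 16, method="beta")
        assert lo == pytest.approx(sm_lo, abs=1e-12)
        assert hi == pytest.approx(sm_hi, abs=1e-12)
        assert lo == pytest.approx(0.617, abs=1e-3)
        assert hi == pytest.approx(0.984, abs=1e-3)

    def test_perfect_predictions(self):
        m = confusion_metrics([0.1, 0.1, 0.9, 0.9], [0, 0, 1, 1], 0.5)
        for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv",
                  "f_score", "auc", "auprc"):
            assert m[k] == 1.0

    def test_all_positive_predictions(self):
        m = confusion_metrics([0.9, 0.8, 0.9, 0.8], [0, 0, 1, 1], 0.5)
        assert m["specificity"] == 0.0
        assert m["ppv"] == 0.5  # prevalence

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([0.5], [1], np.inf)

    def test_published_fold0_counts_internally_consistent(self, rng):
        """Accuracy 0.711, sensitivity 0.875, specificity 0.621 arise from
        32/45, 14/16 and 18/29 with 16 + 29 = 45; the metrics op reproduces
        all three from scores realizing those confusion counts."""
        labels = np.array([1] * 16 + [0] * 29)
        scores = np.concatenate([
            np.full(14, 0.9), np.full(2, 0.1),    # 14 TP, 2 FN
            np.full(11, 0.9), np.full(18, 0.1),   # 11 FP, 18 TN
        ])
        m = confusion_metrics(scores, labels, 0.5)
        assert m["n"] == 45
        assert m["accuracy"] == pytest.approx(32 / 45, abs=1e-12)
        assert m["accuracy"] == pytest.approx(0.711, abs=5e-4)
        assert m["sensitivity"] == pytest.approx(0.875, abs=1e-12)
        assert m["specificity"] == pytest.approx(18 / 29, abs=1e-12)
        assert m["specificity"] == pytest.approx(0.621, abs=5e-4)

    def test_cis_contain_point_and_respect_unit_interval(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        m = confusion_metrics(scores, labels, 0.5)
        for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            if np.isfinite(m[k]):
                assert 0.0 <= m[f"{k}_lo"] <= m[k] <= m[f"{k}_hi"] <= 1.0


class TestDeLong:
    def test_matches_auc(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        auc, lo, hi = delong_auc_ci(scores, labels)
        assert auc == pytest.approx(roc_auc(scores, labels), abs=1e-12)
        assert 0.0 <= lo <= auc <= hi <= 1.0


class TestAggregateFolds:
    def test_identical_folds_zero_width(self):
        mean, lo, hi = aggregate_folds([0.8, 0.8, 0.8])
        assert (mean, lo, hi) == pytest.approx((0.8, 0.8, 0.8))
        assert hi - lo == pytest.approx(0.0, abs=1e-15)

    def test_two_folds_closed_form(self):
        mean, lo, hi = aggregate_folds([0.6, 0.8])
        se = np.std([0.6, 0.8], ddof=1) / np.sqrt(2)
        assert mean == pytest.approx(0.7)
        assert hi - mean == pytest.approx(1.959964 * se, abs=1e-5)

    def test_published_3_month_fold_aucs(self):
        """Printed per-fold values reproduce the pooled 0.735 (0.701-0.769)
        to rounding of unprinted digits."""
        mean, lo, hi = aggregate_folds([0.737, 0.754, 0.761, 0.758, 0.670])
        assert mean == pytest.approx(0.736, abs=1e-3)
        assert lo == pytest.approx(0.7027, abs=1e-3)
        assert hi == pytest.approx(0.7693, abs=1e-3)


class TestWithdrawal:
    def test_ignored_step_gives_zero_auc_difference(self, planted):
        """Surgery: no recurrence, no state memory, and step inputs that the
        gates cannot distinguish => identical scores with and without the
        mid-point, so the paired AUC difference is exactly zero."""
        X, seq, y6 = planted["X"][:80], planted["seq"][:80], planted["y6"][:80]
        net = cc.ConversionNet(X.shape[1], seq.shape[2], hidden_size=8, seed=2)
        w = net.get_weights()
        H = 8
        w["lstm_W"][:, :] = 0.0
        step_in = seq.shape[2] + 2
        rng = np.random.default_rng(0)
        w["lstm_W"][seq.shape[2], :] = rng.normal(size=4 * H)  # static score row
        w["lstm_b"][0, H:2 * H] = -20.0  # forget gate shut: no state memory
        net.set_weights(w)
        p_full = net.predict(X, seq)[:, -1]
        p_withdrawn = net.predict(X, seq[:, :1, :])[:, -1]
        np.testing.assert_allclose(p_full, p_withdrawn, atol=1e-9)
        assert (cc.roc_auc(p_full, y6) - cc.roc_auc(p_withdrawn, y6)) == 0.0

    def test_withdrawn_sequence_length_one(self, planted, planted_model):
        seq1 = planted["seq"][:, :1, :]
        assert seq1.shape[1] == 1
        p = planted_model.net.predict(planted["X"], seq1)
        assert p.shape == (len(planted["X"]), 1)

    def test_full_beats_withdrawn_on_planted_signal(self, planted, planted_model):
        """The 3-month visit carries AR(1) information about 6 months."""
        X, seq, y6 = planted["X"], planted["seq"], planted["y6"]
        p_full = planted_model.net.predict(X, seq)[:, -1]
        p_with = planted_model.net.predict(X, seq[:, :1, :])[:, -1]
        assert cc.roc_auc(p_full, y6) >= cc.roc_auc(p_with, y6) - 0.02
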