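"""Reassignment rule and 2x2 contingency machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import cogconv as cc
from cogconv.decision import compare_rates, expected_counts, flag_reassignment


def chi2_oracle(a, n1, b, n2):
    """Cell-wise sum of (O-E)^2/E."""
    obs = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / total
            stat += (obs[i, j] - e) ** 2 / e
    return stat


def fisher_oracle(a, n1, b, n2):
    """Two-sided exact p by full hypergeometric enumeration."""
    k = a + b  # flagged margin
    rv = hypergeom(n1 + n2, k, n1)
    p_obs = rv.pmf(a)
    support = range(max(0, k - n2), min(k, n1) + 1)
    return sum(rv.pmf(x) for x in support if rv.pmf(x) <= p_obs * (1 + 1e-9))


PRINTED_TABLES = [
    # (a, n1, b, n2, chi2) — actual vs predicted reassignment counts
    (139, 224, 104, 224, 11.017),  # overall, 3 months
    (140, 224, 121, 224, 3.314),   # overall, 6 months
    (46, 93, 20, 93, 15.876),      # monotherapy, 3 months
    (25, 47, 11, 47, 8.824),       # combination, 3 months
    (88, 137, 64, 137, 8.511),     # female, 3 months
    (76, 135, 56, 135, 5.929),     # AD, 3 months
]


class TestPearson:
    @pytest.mark.parametrize("a,n1,b,n2,expected", PRINTED_TABLES)
    def test_reproduces_published_statistics(self, a, n1, b, n2, expected):
        t = cc.pearson_chi2_2x2(a, n1, b, n2)
        assert round(t.statistic, 3) == expected

    def test_equal_proportions_zero(self):
        assert cc.pearson_chi2_2x2(10, 20, 10, 20).statistic == 0.0

    def test_matches_cellwise_oracle(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(5, 80, size=2)
            a, b = rng.integers(1, n1), rng.integers(1, n2)
            if a == n1 or b == n2:
                continue
            t = cc.pearson_chi2_2x2(int(a), int(n1), int(b), int(n2))
            assert t.statistic == pytest.approx(
                chi2_oracle(a, n1, b, n2), abs=1e-9)

    def test_group_swap_and_relabel_invariance(self):
        t = cc.pearson_chi2_2x2(17, 40, 9, 35)
        swapped = cc.pearson_chi2_2x2(9, 35, 17, 40)
        relabeled = cc.pearson_chi2_2x2(40 - 17, 40, 35 - 9, 35)
        assert t.statistic == pytest.approx(swapped.statistic, abs=1e-12)
        assert t.statistic == pytest.approx(relabeled.statistic, abs=1e-12)

    def test_count_bounds_enforced(self):
        with pytest.raises(ValueError):
            cc.pearson_chi2_2x2(11, 10, 2, 10)
        with pytest.raises(ValueError):
            cc.pearson_chi2_2x2(1, 0, 2, 10)


class TestExact:
    def test_all_cells_equal_p_one(self):
        assert cc.exact_test_2x2(5, 10, 5, 10).p_value == 1.0

    def test_matches_enumeration_oracle(self, rng):
        cases = [(0, 5, 5, 5), (2, 8, 7, 9), (1, 12, 6, 10), (3, 7, 3, 7)]
        for _ in range(20):
            n1, n2 = rng.integers(3, 25, size=2)
            cases.append((int(rng.integers(0, n1 + 1)), int(n1),
                          int(rng.integers(0, n2 + 1)), int(n2)))
        for a, n1, b, n2 in cases:
            t = cc.exact_test_2x2(a, n1, b, n2)
            assert t.p_value == pytest.approx(
                fisher_oracle(a, n1, b, n2), abs=1e-9)

    def test_small_expected_count_routes_to_exact(self):
        # unflagged margin 9 of 44: min expected cell 9*22/44 = 4.5 < 5
        assert expected_counts(15, 22, 20, 22).min() == pytest.approx(4.5)
        assert compare_rates(15, 22, 20, 22).method == "exact"
        assert compare_rates(15, 22, 20, 22, adjustment="yates").method == "yates"

    def test_large_expected_counts_stay_pearson(self):
        assert compare_rates(139, 224, 104, 224).method == "pearson"


class TestFlagsAndRates:
    def make_labels(self):
        return pd.DataFrame({
            "id": ["a", "b", "c", "a", "b", "c"],
            "month": [3, 3, 3, 6, 6, 6],
            "label": ["CI", "CNI", "CI", "CNI", "CNI", "CI"],
        })

    def test_flagged_iff_cni(self):
        flags = flag_reassignment(self.make_labels(), 3).set_index("id")["flagged"]
        assert not flags["a"] and flags["b"] and not flags["c"]
        flags6 = flag_reassignment(self.make_labels(), 6).set_index("id")["flagged"]
        assert flags6["a"] and flags6["b"] and not flags6["c"]

    def test_cumulative_reading(self):
        flags = flag_reassignment(self.make_labels(), 6, cumulative=True)
        flags = flags.set_index("id")["flagged"]
        assert flags["a"] and flags["b"] and not flags["c"]
        # 'b' CNI at 3 months only would still be flagged at 6 cumulatively
        labels = self.make_labels()
        labels.loc[(labels["id"] == "b") & (labels["month"] == 6), "label"] = "CI"
        f6 = flag_reassignment(labels, 6, cumulative=True).set_index("id")["flagged"]
        assert f6["b"]
        f6_point = flag_reassignment(labels, 6).set_index("id")["flagged"]
        assert not f6_point["b"]

    def test_published_rate(self):
        flags = np.array([True] * 139 + [False] * 85)
        assert cc.reassignment_rate(flags) * 100 == pytest.approx(62.05, abs=5e-3)

    def test_rate_extremes(self):
        assert cc.reassignment_rate(np.array([False] * 5)) == 0.0
        assert cc.reassignment_rate(np.array([True] * 5)) == 1.0

    def test_rate_complements_ci_prevalence(self, small_cohort):
        from cogconv.preprocess import label_conversion
        labels = label_conversion(small_cohort)
        flags = flag_reassignment(labels, 3)
        ci_prev = (labels[labels["month"] == 3]["label"] == "CI").mean()
        assert cc.reassignment_rate(flags) == pytest.approx(1 - ci_prev)


class TestMcNemar:
    def test_paired_alternative_labeled(self):
        actual = np.array([True] * 30 + [False] * 20)
        pred = np.array([True] * 25 + [False] * 25)
        t = cc.mcnemar_test(actual, pred)
        assert t.method == "mcnemar-exact"
        assert 0 <= t.p_value <= 1


class TestReport:
    @pytest.fixture()
    def cohort_pieces(self):
        n = 60
        rng = np.random.default_rng(0)
        static = pd.DataFrame({
            "id": [f"p{i}" for i in range(n)],
            "age": rng.integers(50, 90, n).astype(float),
            "gender": rng.integers(0, 2, n).astype(float),
            "diagnosis": rng.choice(["AD", "MCI"], n),
            "arm": rng.choice(["observation", "exercise", "donepezil",
                               "gbe", "donepezil_gbe"], n),
        })
        labels = pd.concat([
            pd.DataFrame({"id": static["id"], "month": m,
                          "label": rng.choice(["CI", "CNI"], n)})
            for m in (3, 6)], ignore_index=True)
        return static, labels

    def test_identical_predictions_all_null(self, cohort_pieces):
        static, labels = cohort_pieces
        rep = cc.reassignment_report(static, labels, labels)
        filled = rep[rep["n"] > 0]
        assert (filled["actual"] == filled["predicted"]).all()
        pearson_rows = filled[filled["method"] == "pearson"]
        assert (pearson_rows["statistic"] == 0.0).all()

    def test_counts_match_hand_tabulation(self, cohort_pieces):
        static, labels = cohort_pieces
        rng = np.random.default_rng(1)
        pred = labels.copy()
        pred["label"] = rng.choice(["CI", "CNI"], len(pred))
        rep = cc.reassignment_report(static, labels, pred).set_index(
            ["stratum", "month"])
        lab3 = labels[labels["month"] == 3].set_index("id")["label"]
        female_ids = static.loc[static["gender"] == 1, "id"]
        assert rep.loc[("gender:female", 3), "actual"] == \
            (lab3[female_ids] == "CNI").sum()
        mono = static.loc[static["arm"].isin(["donepezil", "gbe"]), "id"]
        p3 = pred[pred["month"] == 3].set_index("id")["label"]
        assert rep.loc[("arm:monotherapy", 3), "predicted"] == \
            (p3[mono] == "CNI").sum()

    def test_stratum_sizes_partition_cohort(self, cohort_pieces):
        static, labels = cohort_pieces
        rep = cc.reassignment_report(static, labels, labels)
        rep3 = rep[rep["month"] == 3]
        overall = rep3.loc[rep3["stratum"] == "overall", "n"].item()
        for prefix in ("arm:", "gender:", "diagnosis:", "age:"):
            top = rep3[rep3["stratum"].str.startswith(prefix)
                       & ~rep3["stratum"].str.contains("/")]
            assert top["n"].sum() == overall

    def test_empty_stratum_dash(self, cohort_pieces):
        static, labels = cohort_pieces
        static = static[static["arm"] != "exercise"].reset_index(drop=True)
        labels = labels[labels["id"].isin(static["id"])]
        rep = cc.reassignment_report(static, labels, labels).set_index(
            ["stratum", "month"])
        assert rep.loc[("arm:exercise", 3), "method"] == "-"
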