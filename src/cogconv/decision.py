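"""Treatment-reassignment decision rule and contingency analysis.

Decision rule: a patient whose conversion label at a follow-up visit is
CNI (ADAS-cog decline < 4 points, or any increase, from baseline) is
flagged — the treatment recommended at diagnosis is considered
insufficient and an upgrade/redirection is recommended.  The rule is
applied identically to actual labels and to model-predicted labels, and
the two flag rates are compared with an (unpaired) chi-square test per
stratum, falling back to Fisher's exact test when any expected cell
count is below 5.

The unpaired comparison mirrors the original analysis even though actual
and predicted flags describe the same patients; :func:`mcnemar_test` is
provided as the statistically appropriate paired alternative and is
labeled as such in reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar

from .preprocess import CNI

__all__ = [
    "ContingencyTest",
    "flag_reassignment",
    "reassignment_rate",
    "pearson_chi2_2x2",
    "yates_chi2_2x2",
    "exact_test_2x2",
    "compare_rates",
    "mcnemar_test",
    "reassignment_report",
    "AGE_BANDS",
]

#: Age bands used for stratified reporting.
AGE_BANDS = ((50, 59), (60, 69), (70, 79), (80, 89))


@dataclass(frozen=True)
class ContingencyTest:
    a: int
    n1: int
    b: int
    n2: int
    statistic: float | None  # None for exact tests (no statistic printed)
    p_value: float
    method: str  # 'pearson' | 'yates' | 'exact'


def _check_counts(a: int, n1: int, b: int, n2: int) -> None:
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("flagged counts must lie within their group totals")


def flag_reassignment(labels: pd.DataFrame, month: int,
                      cumulative: bool = False) -> pd.DataFrame:
    """Per-patient reassignment flags at one follow-up month.

    ``labels`` is a conversion-label frame (columns id, month, label).
    Default reading: flagged is True exactly when the label is CNI at that
    month (this reproduces the published overall counts).  The
    ``cumulative`` reading flags a patient who is CNI at *any* follow-up
    up to and including that month.
    """
    sub = labels[labels["month"] == month]
    if sub.empty:
        raise ValueError(f"no labels at month {month}")
    flagged = (sub["label"] == CNI).to_numpy()
    if cumulative:
        earlier = labels[labels["month"] <= month]
        cni_ever = set(earlier.loc[earlier["label"] == CNI, "id"])
        flagged = np.array([pid in cni_ever for pid in sub["id"]])
    return pd.DataFrame({
        "id": sub["id"].to_numpy(),
        "month": month,
        "flagged": flagged,
    })


def reassignment_rate(flags: pd.DataFrame | np.ndarray) -> float:
    """Fraction of patients flagged for treatment reassignment."""
    arr = flags["flagged"].to_numpy() if isinstance(flags, pd.DataFrame) else np.asarray(flags)
    if arr.size == 0:
        raise ValueError("no flags to summarize")
    return float(arr.mean())


def pearson_chi2_2x2(a: int, n1: int, b: int, n2: int) -> ContingencyTest:
    """Uncorrected Pearson chi-square on [[a, n1−a], [b, n2−b]], 1 df."""
    _check_counts(a, n1, b, n2)
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    if table.sum(axis=0).min() == 0:  # empty column: identical degenerate rates
        return ContingencyTest(a, n1, b, n2, 0.0, 1.0, "pearson")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ContingencyTest(a, n1, b, n2, float(stat), float(p), "pearson")


def yates_chi2_2x2(a: int, n1: int, b: int, n2: int) -> ContingencyTest:
    """Continuity-corrected chi-square, the adjustment some software applies."""
    _check_counts(a, n1, b, n2)
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    if table.sum(axis=0).min() == 0:
        return ContingencyTest(a, n1, b, n2, 0.0, 1.0, "yates")
    stat, p, _, _ = stats.chi2_contingency(table, correction=True)
    return ContingencyTest(a, n1, b, n2, float(stat), float(p), "yates")


def exact_test_2x2(a: int, n1: int, b: int, n2: int) -> ContingencyTest:
    """Two-sided Fisher exact test (hypergeometric point-probability sum)."""
    _check_counts(a, n1, b, n2)
    _, p = stats.fisher_exact([[a, n1 - a], [b, n2 - b]], alternative="two-sided")
    return ContingencyTest(a, n1, b, n2, None, float(p), "exact")


def expected_counts(a: int, n1: int, b: int, n2: int) -> np.ndarray:
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    return rows @ cols / table.sum()


def compare_rates(a: int, n1: int, b: int, n2: int,
                  adjustment: str = "exact") -> ContingencyTest:
    """Chi-square comparison, adjusted when expected counts are small.

    Uses the uncorrected Pearson statistic unless any expected cell count
    is below 5, in which case the test routes to the ``adjustment`` method
    ('exact' for Fisher, 'yates' for the continuity correction).
    """
    _check_counts(a, n1, b, n2)
    if expected_counts(a, n1, b, n2).min() < 5:
        if adjustment == "exact":
            return exact_test_2x2(a, n1, b, n2)
        if adjustment == "yates":
            return yates_chi2_2x2(a, n1, b, n2)
        raise ValueError("adjustment must be 'exact' or 'yates'")
    return pearson_chi2_2x2(a, n1, b, n2)


def mcnemar_test(actual_flags: np.ndarray, predicted_flags: np.ndarray,
                 exact: bool = True) -> ContingencyTest:
    """Paired comparison of the same patients' actual vs predicted flags."""
    actual = np.asarray(actual_flags, dtype=bool)
    pred = np.asarray(predicted_flags, dtype=bool)
    if actual.shape != pred.shape:
        raise ValueError("flag vectors must be aligned")
    n = len(actual)
    table = [[int((actual & pred).sum()), int((actual & ~pred).sum())],
             [int((~actual & pred).sum()), int((~actual & ~pred).sum())]]
    res = mcnemar(table, exact=exact)
    return ContingencyTest(int(actual.sum()), n, int(pred.sum()), n,
                           None if exact else float(res.statistic),
                           float(res.pvalue),
                           "mcnemar-exact" if exact else "mcnemar-chi2")


# ---------------------------------------------------------------------------
# Stratified reporting (actual vs predicted, per subgroup and horizon)
# ---------------------------------------------------------------------------

def _arm4(arm: str) -> str:
    if arm in ("donepezil", "gbe"):
        return "monotherapy"
    if arm == "donepezil_gbe":
        return "combination"
    return arm


def _age_band(age: float) -> str:
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return "other"


def _row(name: str, sub: pd.DataFrame, month: int,
         adjustment: str) -> dict:
    n = len(sub)
    a = int(sub["actual_flag"].sum())
    b = int(sub["pred_flag"].sum())
    if n == 0:
        return dict(stratum=name, month=month, n=0, actual=0, predicted=0,
                    actual_pct=np.nan, predicted_pct=np.nan,
                    statistic=np.nan, p_value=np.nan, method="-")
    test = compare_rates(a, n, b, n, adjustment=adjustment)
    return dict(
        stratum=name, month=month, n=n, actual=a, predicted=b,
        actual_pct=round(100.0 * a / n, 2),
        predicted_pct=round(100.0 * b / n, 2),
        statistic=(np.nan if test.statistic is None
                   else round(test.statistic, 3)),
        p_value=round(test.p_value, 3),
        method=test.method,
    )


def reassignment_report(
    static: pd.DataFrame,
    actual_labels: pd.DataFrame,
    predicted_labels: pd.DataFrame,
    months: tuple[int, ...] = (3, 6),
    adjustment: str = "exact",
    cumulative: bool = False,
) -> pd.DataFrame:
    """Actual vs predicted reassignment per stratum and follow-up month.

    ``static`` needs columns id, age, gender, diagnosis, arm (one row per
    patient); the label frames are conversion labels from the actual data
    and from the model.  Strata: overall, intervention (4 groups, the two
    monotherapies pooled), age bands, gender, diagnosis class, and
    intervention nested inside each demographic stratum.  Strata with no
    members are reported with the '-' method marker.
    """
    rows = []
    for month in months:
        act = flag_reassignment(actual_labels, month,
                                cumulative).set_index("id")["flagged"]
        prd = flag_reassignment(predicted_labels, month,
                                cumulative).set_index("id")["flagged"]
        ids = act.index.intersection(prd.index)
        base = static[static["id"].isin(ids)].copy()
        if set(base["id"]) != set(ids):
            raise ValueError("static table does not cover all labeled patients")
        base["actual_flag"] = act.loc[base["id"]].to_numpy()
        base["pred_flag"] = prd.loc[base["id"]].to_numpy()
        base["arm4"] = base["arm"].map(_arm4)
        base["age_band"] = base["age"].map(_age_band)
        base["sex"] = np.where(base["gender"] == 1, "female", "male")

        rows.append(_row("overall", base, month, adjustment))
        for arm in ("observation", "exercise", "monotherapy", "combination"):
            rows.append(_row(f"arm:{arm}", base[base["arm4"] == arm],
                             month, adjustment))
        for lo, hi in AGE_BANDS:
            band = f"{lo}-{hi}"
            sel = base[base["age_band"] == band]
            rows.append(_row(f"age:{band}", sel, month, adjustment))
            for arm in ("observation", "exercise", "monotherapy", "combination"):
                rows.append(_row(f"age:{band}/arm:{arm}",
                                 sel[sel["arm4"] == arm], month, adjustment))
        for sex in ("male", "female"):
            sel = base[base["sex"] == sex]
            rows.append(_row(f"gender:{sex}", sel, month, adjustment))
            for arm in ("observation", "exercise", "monotherapy", "combination"):
                rows.append(_row(f"gender:{sex}/arm:{arm}",
                                 sel[sel["arm4"] == arm], month, adjustment))
        for dx in ("AD", "MCI"):
            sel = base[base["diagnosis"] == dx]
            rows.append(_row(f"diagnosis:{dx}", sel, month, adjustment))
            for arm in ("observation", "exercise", "monotherapy", "combination"):
                rows.append(_row(f"diagnosis:{dx}/arm:{arm}",
                                 sel[sel["arm4"] == arm], month, adjustment))
    return pd.DataFrame(rows)
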