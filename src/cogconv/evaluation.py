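"""Cross-validated performance measurement and the withdrawal experiment.

Five-fold stratified cross-validation produces per-fold accuracy,
sensitivity, specificity, PPV, NPV, F-score, AUC and AUPRC at the
Youden-optimal cutoff (J = sensitivity + specificity − 1), with exact
Clopper–Pearson intervals for the proportions and DeLong intervals for
the AUCs.  The withdrawal experiment re-scores the trained models with
the mid-point (3-month) visit removed from the input sequence, measuring
how much the 6-month prediction depends on the intermediate follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .model import TrainedModel, TrainingConfig, aligned_labels, design_matrices, train_model
from .preprocess import standardize
from .synthetic import CohortTable

__all__ = [
    "EvalConfig",
    "CutoffResult",
    "stratified_folds",
    "roc_auc",
    "youden_cutoff",
    "confusion_metrics",
    "clopper_pearson",
    "delong_auc_ci",
    "aggregate_folds",
    "cross_validate",
    "withdrawal_experiment",
    "CVResult",
]


@dataclass(frozen=True)
class EvalConfig:
    k: int = 5
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need at least 2 folds")


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float
    j: float


def stratified_folds(labels: np.ndarray, cfg: EvalConfig = EvalConfig()) -> np.ndarray:
    """Fold index per sample; sizes differ by at most one, label-stratified."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < cfg.k:
        raise ValueError(f"every class needs >= {cfg.k} members")
    skf = StratifiedKFold(n_splits=cfg.k, shuffle=True, random_state=cfg.seed % (2**31))
    assign = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assign[test_idx] = fold
    return assign


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = Mann–Whitney concordance probability, ties counted 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> CutoffResult:
    """Threshold maximizing J over midpoints of unique scores plus ±∞.

    A score is called positive when it is >= the threshold.  Ties in J are
    broken toward the lowest threshold, favoring sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Youden cutoff undefined: only one class present")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    best = None
    for thr in candidates:  # ascending, so strict '>' keeps the lowest tie
        called = scores >= thr
        sens = (called & pos).sum() / n_pos
        spec = (~called & ~pos).sum() / n_neg
        j = sens + spec - 1.0
        if best is None or j > best.j:
            best = CutoffResult(float(thr), float(sens), float(spec), float(j))
    return best


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if n == 0:
        return (np.nan, np.nan)
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_ci(scores: np.ndarray, labels: np.ndarray,
                  level: float = 0.95) -> tuple[float, float, float]:
    """AUC with DeLong variance-based confidence interval.

    Returns ``(auc, lo, hi)``, the interval clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: only one class present")
    rx = _midrank(np.concatenate([x, y]))[:m]
    v10 = (rx - _midrank(x)) / n          # placement of positives among negatives
    ry = _midrank(np.concatenate([y, x]))[:n]
    v01 = 1.0 - (ry - _midrank(y)) / m    # placement of negatives among positives
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def confusion_metrics(scores: np.ndarray, labels: np.ndarray,
                      threshold: float, level: float = 0.95) -> dict:
    """One metrics row at a fixed cutoff (score >= threshold ⇒ positive).

    Proportions carry exact Clopper–Pearson intervals; the F-score is the
    harmonic mean of PPV and sensitivity; AUPRC is the step-wise
    (non-interpolated) precision–recall summation; the AUC interval is
    DeLong's.  Ratios with zero denominator are NaN.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    called = scores >= threshold
    pos = labels == 1
    tp = int((called & pos).sum())
    fp = int((called & ~pos).sum())
    fn = int((~called & pos).sum())
    tn = int((~called & ~pos).sum())
    n = tp + fp + fn + tn

    def prop(k, d):
        p = k / d if d else np.nan
        lo, hi = clopper_pearson(k, d, level)
        return p, lo, hi

    acc, acc_lo, acc_hi = prop(tp + tn, n)
    sens, sens_lo, sens_hi = prop(tp, tp + fn)
    spec, spec_lo, spec_hi = prop(tn, tn + fp)
    ppv, ppv_lo, ppv_hi = prop(tp, tp + fp)
    npv, npv_lo, npv_hi = prop(tn, tn + fn)
    f_score = (2 * ppv * sens / (ppv + sens)
               if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
               else np.nan)
    auc, auc_lo, auc_hi = delong_auc_ci(scores, labels, level)
    auprc = float(average_precision_score(labels, scores))
    return dict(
        n=n, tp=tp, fp=fp, tn=tn, fn=fn, threshold=float(threshold),
        accuracy=acc, accuracy_lo=acc_lo, accuracy_hi=acc_hi,
        sensitivity=sens, sensitivity_lo=sens_lo, sensitivity_hi=sens_hi,
        specificity=spec, specificity_lo=spec_lo, specificity_hi=spec_hi,
        ppv=ppv, ppv_lo=ppv_lo, ppv_hi=ppv_hi,
        npv=npv, npv_lo=npv_lo, npv_hi=npv_hi,
        f_score=f_score, auc=auc, auc_lo=auc_lo, auc_hi=auc_hi, auprc=auprc,
    )


def aggregate_folds(fold_aucs: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean AUC across folds with a normal-approximation interval.

    mean ± z · sd/√k with the sample (ddof=1) standard deviation, the
    convention under which the published per-fold values reproduce the
    reported pooled AUC intervals to rounding.
    """
    a = np.asarray(fold_aucs, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    z = stats.norm.ppf(0.5 + level / 2)
    se = a.std(ddof=1) / np.sqrt(len(a))
    return float(a.mean()), float(a.mean() - z * se), float(a.mean() + z * se)


# ---------------------------------------------------------------------------
# Cross-validated training and the withdrawal experiment
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    metrics: pd.DataFrame            # one row per fold per horizon
    oof: pd.DataFrame                # id, month, score, pred_label, fold
    models: list = field(default_factory=list)
    fold_assignment: pd.Series | None = None


def cross_validate(
    table: CohortTable,
    labels: pd.DataFrame,
    train_cfg: TrainingConfig = TrainingConfig(),
    eval_cfg: EvalConfig = EvalConfig(),
    pooled_scaling: bool = False,
) -> CVResult:
    """Stratified k-fold train/evaluate loop over a filtered, imputed cohort.

    Scalers are fit on each training fold only; the
    ``pooled_scaling`` switch restores whole-dataset fitting, the
    convention the original analysis used.  Patients lacking either
    follow-up label are excluded from modeling.  The per-fold cutoff is the
    Youden-optimal threshold on that fold's held-out scores.
    """
    ids_all, _, _, _ = design_matrices(table)
    y3_all = aligned_labels(labels, ids_all, table.schema.months[1])
    y6_all = aligned_labels(labels, ids_all, table.schema.months[2])
    ok = ~np.isnan(y3_all) & ~np.isnan(y6_all)
    keep_ids = set(ids_all[ok])

    strat = y6_all[ok]
    folds = stratified_folds(strat, eval_cfg)

    df = table.data[table.data["id"].isin(keep_ids)].reset_index(drop=True)
    sub = CohortTable(df, table.schema)

    if pooled_scaling:
        scaled_all, _ = standardize(sub)

    rows, oof_rows, models = [], [], []
    kept_ids = ids_all[ok]
    for fold in range(eval_cfg.k):
        test_ids = set(kept_ids[folds == fold])
        train_ids = set(kept_ids[folds != fold])
        if pooled_scaling:
            scaled = scaled_all
        else:
            scaled, _ = standardize(sub, fit_ids=train_ids)
        ids, X, seq, names = design_matrices(scaled)
        y3 = aligned_labels(labels, ids, table.schema.months[1])
        y6 = aligned_labels(labels, ids, table.schema.months[2])
        tr = np.array([i in train_ids for i in ids])
        te = ~tr

        cfg = TrainingConfig(**{**train_cfg.__dict__,
                                "seed": train_cfg.seed + fold})
        model = train_model(X[tr], seq[tr], y3[tr], y6[tr], cfg,
                            feature_names=names)
        models.append(model)

        p = model.net.predict(X[te], seq[te])
        for col, month in ((0, table.schema.months[1]), (1, table.schema.months[2])):
            y = y3[te] if col == 0 else y6[te]
            cut = youden_cutoff(p[:, col], y)
            thr = cut.threshold
            if not np.isfinite(thr):  # degenerate fold: all-positive/-negative
                thr = p[:, col].min() - 1.0 if thr < 0 else p[:, col].max() + 1.0
            m = confusion_metrics(p[:, col], y, thr, eval_cfg.ci_level)
            m.update(fold=fold, month=month, youden_j=cut.j)
            rows.append(m)
            for pid, sc in zip(ids[te], p[:, col]):
                oof_rows.append((pid, month, float(sc),
                                 "CI" if sc >= cut.threshold else "CNI", fold))

    metrics = pd.DataFrame(rows)
    front = ["fold", "month", "n"]
    metrics = metrics[front + [c for c in metrics.columns if c not in front]]
    oof = pd.DataFrame(oof_rows, columns=["id", "month", "score", "pred_label", "fold"])
    return CVResult(metrics=metrics, oof=oof, models=models,
                    fold_assignment=pd.Series(folds, index=kept_ids))


def withdrawal_experiment(
    cv: CVResult,
    table: CohortTable,
    labels: pd.DataFrame,
    pooled_scaling: bool = False,
    zero_fill: bool = False,
) -> pd.DataFrame:
    """Paired 6-month AUC report: full sequence vs mid-point withdrawn.

    The already-trained fold models are re-scored (no retraining) on their
    held-out patients with the 3-month step removed, so each withdrawn
    input sequence has length 1.  ``zero_fill`` keeps the step but zeroes
    its visit features instead, for comparison.
    """
    month6 = table.schema.months[2]
    kept_ids = cv.fold_assignment.index.to_numpy()
    folds = cv.fold_assignment.to_numpy()
    df = table.data[table.data["id"].isin(set(kept_ids))].reset_index(drop=True)
    sub = CohortTable(df, table.schema)
    if pooled_scaling:
        scaled_all, _ = standardize(sub)

    rows = []
    for fold, model in enumerate(cv.models):
        test_ids = set(kept_ids[folds == fold])
        train_ids = set(kept_ids[folds != fold])
        if pooled_scaling:
            scaled = scaled_all
        else:
            scaled, _ = standardize(sub, fit_ids=train_ids)
        ids, X, seq, _ = design_matrices(scaled)
        y6 = aligned_labels(labels, ids, month6)
        te = np.array([i in test_ids for i in ids])

        p_full = model.net.predict(X[te], seq[te])[:, -1]
        if zero_fill:
            seq_w = seq[te].copy()
            seq_w[:, 1, :] = 0.0
        else:
            seq_w = seq[te][:, :1, :]
        p_with = model.net.predict(X[te], seq_w)[:, -1]
        auc_full = roc_auc(p_full, y6[te])
        auc_with = roc_auc(p_with, y6[te])
        rows.append(dict(fold=fold, auc_full=auc_full, auc_withdrawn=auc_with,
                         auc_drop=auc_full - auc_with, n=int(te.sum())))
    return pd.DataFrame(rows)
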