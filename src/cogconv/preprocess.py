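"""Exclusion, imputation, normalization, and conversion labeling.

The preprocessing contract is deliberately small and auditable: every
change applied to a cohort table is traceable to an entry in the returned
:class:`PreprocessReport`.

Conversion outcome
------------------
A patient converts ("cognition improved", CI) at follow-up month *t* when
their ADAS-cog score declined by at least 4 points from baseline,

    CI at t  ⇔  ADAS(0) − ADAS(t) ≥ 4,

the clinically-important-change threshold for the scale; otherwise the
label is CNI ("cognition not improved").  Both the 3- and 6-month labels
are referenced to baseline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CohortTable, FeatureSchema

__all__ = [
    "ConversionRule",
    "PreprocessReport",
    "filter_missing",
    "impute",
    "standardize",
    "label_conversion",
]

CI, CNI = "CI", "CNI"


@dataclass(frozen=True)
class ConversionRule:
    threshold_points: float = 4.0
    reference_month: int = 0

    def __post_init__(self):
        if self.threshold_points <= 0:
            raise ValueError("threshold_points must be > 0")


@dataclass
class PreprocessReport:
    excluded_patients: dict = field(default_factory=dict)  # id -> missing frac
    dropped_features: list = field(default_factory=list)
    imputation_values: dict = field(default_factory=dict)  # col key -> value
    normalization: dict = field(default_factory=dict)      # col key -> (mean, sd)
    degenerate_features: list = field(default_factory=list)  # sd == 0 on fit set
    omitted_labels: list = field(default_factory=list)     # (id, month)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)


def _cell_frame(table: CohortTable) -> pd.DataFrame:
    """One row per patient, one column per distinct feature cell.

    Static features contribute one cell each; time-dependent features one
    cell per scheduled visit (``feat@month``).
    """
    stat = table.static_frame().set_index("id")[table.schema.static_names]
    parts = [stat]
    for feat in table.schema.time_names:
        wide = table.visit_values(feat)
        wide.columns = [f"{feat}@{m}" for m in wide.columns]
        parts.append(wide)
    return pd.concat(parts, axis=1)


def filter_missing(
    table: CohortTable,
    patient_threshold: float = 0.5,
    feature_threshold: float = 0.5,
) -> tuple[CohortTable, PreprocessReport]:
    """Drop under-observed features, then under-observed patients.

    A feature cell column observed in fewer than ``feature_threshold`` of
    patients is dropped (all visits of a time-dependent feature are dropped
    together); then any patient whose fraction of missing cells among the
    remaining features strictly exceeds ``patient_threshold`` is excluded.
    """
    if not 0.0 < patient_threshold <= 1.0:
        raise ValueError("patient_threshold must be in (0, 1]")
    report = PreprocessReport()
    if table.data.empty:
        return table.copy(), report

    cells = _cell_frame(table)
    observed = cells.notna().mean(axis=0)
    schema = table.schema
    drop_feats: list[str] = []
    for f in schema.static_names:
        if observed[f] < feature_threshold:
            drop_feats.append(f)
    for f in schema.time_names:
        cols = [c for c in cells.columns if c.startswith(f + "@")]
        if observed[cols].mean() < feature_threshold:
            drop_feats.append(f)
    report.dropped_features = drop_feats

    keep_cells = cells.drop(columns=[
        c for c in cells.columns
        if c in drop_feats or c.split("@")[0] in drop_feats])
    frac_missing = keep_cells.isna().mean(axis=1)
    excluded = frac_missing[frac_missing > patient_threshold]
    report.excluded_patients = {pid: float(fr) for pid, fr in excluded.items()}

    new_schema = FeatureSchema(
        static=tuple(f for f in schema.static if f.name not in drop_feats),
        time=tuple(f for f in schema.time if f.name not in drop_feats),
        months=schema.months,
    )
    df = table.data[~table.data["id"].isin(excluded.index)]
    df = df[new_schema.columns].reset_index(drop=True)
    return CohortTable(df, new_schema), report


def impute(table: CohortTable) -> tuple[CohortTable, PreprocessReport]:
    """Fill missing cells: mean for continuous, mode for binary/categorical.

    Time-dependent features are imputed per visit month (each ``feat@month``
    cell column has its own mean).  Mode ties break to the first value in
    sorted order, making the fill deterministic.  Observed values are never
    touched; a feature with no observed value at all is an error.
    """
    report = PreprocessReport()
    df = table.data.copy()
    for f in table.schema.static:
        col = df[f.name]
        if col.isna().all():
            raise ValueError(f"feature {f.name!r} has no observed values")
        if f.kind == "continuous":
            fill = float(col.mean())
        else:
            counts = col.dropna().value_counts()
            top = counts[counts == counts.max()].index
            fill = sorted(top)[0]
        if col.isna().any():
            report.imputation_values[f.name] = fill
            df[f.name] = col.fillna(fill)
    for f in table.schema.time:
        for m in table.schema.months:
            sel = df["month"] == m
            col = df.loc[sel, f.name]
            if col.isna().all():
                raise ValueError(
                    f"feature {f.name!r} has no observed values at month {m}")
            if col.isna().any():
                fill = float(col.mean())
                report.imputation_values[f"{f.name}@{m}"] = fill
                df.loc[sel, f.name] = col.fillna(fill)
    return CohortTable(df, table.schema), report


def standardize(
    table: CohortTable,
    fit_ids: set | None = None,
    ddof: int = 0,
) -> tuple[CohortTable, PreprocessReport]:
    """Z-score continuous features using statistics from ``fit_ids`` only.

    Population standard deviation (``ddof=0``) by default, so the fit set
    itself ends up with exactly unit variance.  Zero-variance features map
    to 0 and are flagged.  Binary and categorical features pass through.
    Imputation must already have been applied.
    """
    report = PreprocessReport()
    all_ids = set(table.patient_ids)
    if fit_ids is None:
        fit_ids = all_ids
    fit_ids = set(fit_ids)
    if not fit_ids:
        raise ValueError("fit_ids must be non-empty")
    if not fit_ids <= all_ids:
        raise ValueError("fit_ids must be a subset of the table's patient ids")

    df = table.data.copy()
    fit_rows = df["id"].isin(fit_ids)

    def transform(sel: pd.Series, name: str, key: str) -> None:
        vals = df.loc[sel, name].to_numpy(dtype=float)
        fit_vals = df.loc[sel & fit_rows, name].to_numpy(dtype=float)
        mean = float(fit_vals.mean())
        sd = float(fit_vals.std(ddof=ddof))
        report.normalization[key] = (mean, sd)
        if sd == 0.0:
            report.degenerate_features.append(key)
            df.loc[sel, name] = 0.0
        else:
            df.loc[sel, name] = (vals - mean) / sd

    everywhere = pd.Series(True, index=df.index)
    for f in table.schema.static:
        if f.kind == "continuous":
            transform(everywhere, f.name, f.name)
    for f in table.schema.time:
        for m in table.schema.months:
            transform(df["month"] == m, f.name, f"{f.name}@{m}")
    return CohortTable(df, table.schema), report


def label_conversion(
    table: CohortTable,
    rule: ConversionRule = ConversionRule(),
) -> pd.DataFrame:
    """Baseline-referenced conversion labels at every follow-up month.

    Returns a frame with columns ``id, month, label`` (label in {CI, CNI}).
    Pairs whose baseline or follow-up ADAS-cog is missing are omitted and
    listed in ``result.attrs['omitted']``.
    """
    wide = table.visit_values("adas_cog")
    ref = rule.reference_month
    if ref not in wide.columns:
        raise ValueError(f"reference month {ref} absent from table")
    follow_ups = [m for m in table.schema.months if m > ref]
    rows, omitted = [], []
    base = wide[ref]
    for m in follow_ups:
        decline = base - wide[m]
        for pid, d in decline.items():
            if np.isnan(d):
                omitted.append((pid, int(m)))
            else:
                rows.append((pid, int(m),
                             CI if d >= rule.threshold_points else CNI))
    out = pd.DataFrame(rows, columns=["id", "month", "label"])
    out.attrs["omitted"] = omitted
    return out
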