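"""Dichotomization and cohort restriction.

Raw candidate variables are collapsed to binary deprivation indicators in
which 1 always codes the deprivation-associated level (income below
$1500/month, education at most high school, unemployed, non-GBMSM,
Indigenous, any injection drug use, recent injection drug use, ever
incarcerated, past psychiatric hospitalization, ...). Monotone
deprivation-direction coding is what lets the item response model constrain
every discrimination positive. Provinces too small to support
province-level item parameters are dropped, and the model is fitted to
complete cases only (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .containers import ExclusionReport, ItemResponseMatrix

__all__ = [
    "DichotomizationRule",
    "dichotomize",
    "filter_small_provinces",
    "complete_cases",
    "default_rules",
    "DEFAULT_MIN_PROVINCE_N",
]

#: Default minimum province size; reproduces the exclusion of provinces with
#: 13 and 47 participants while keeping those with ~200+.
DEFAULT_MIN_PROVINCE_N = 100


@dataclass(frozen=True)
class DichotomizationRule:
    """Maps one raw variable to a 0/1 deprivation indicator.

    ``kind`` selects the predicate:

    - ``"less_than"``: numeric value strictly below ``threshold`` codes 1
      (boundary value belongs to the non-deprived 0 level);
    - ``"in_set"``: membership of ``categories`` codes 1;
    - ``"binary"``: values already 0/1 pass through (sanity-checked).

    Missing raw values propagate to missing output cells.
    """

    variable: str
    kind: str = "binary"
    threshold: float | None = None
    categories: frozenset = frozenset()
    output: str | None = None

    @property
    def item_name(self) -> str:
        return self.output or self.variable

    def apply(self, col: pd.Series) -> pd.Series:
        missing = col.isna() | (col.astype(str).str.strip() == "")
        if self.kind == "less_than":
            if self.threshold is None:
                raise ValueError(f"rule for {self.variable!r} needs a threshold")
            vals = pd.to_numeric(col, errors="coerce")
            out = (vals < self.threshold).astype(float)
            missing = missing | vals.isna()
        elif self.kind == "in_set":
            out = col.astype(str).str.strip().isin(self.categories).astype(float)
        elif self.kind == "binary":
            vals = pd.to_numeric(col, errors="coerce")
            observed = vals[~missing]
            if not observed.isin([0, 1]).all():
                raise ValueError(
                    f"rule for {self.variable!r}: values not binary after application"
                )
            out = vals.astype(float)
        else:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        out[missing] = np.nan
        return out


def default_rules() -> list[DichotomizationRule]:
    """Deprivation-direction rules for the raw cohort schema.

    Raw-form variables (numeric income, labelled education/orientation) get
    explicit predicates; indicators collected as yes/no pass through as
    binary.
    """
    rules = [
        DichotomizationRule(
            "income_monthly", kind="less_than", threshold=1500, output="income_lt_1500"
        ),
        DichotomizationRule(
            "education",
            kind="in_set",
            categories=frozenset({"High school diploma or less"}),
            output="education_hs_or_less",
        ),
        DichotomizationRule(
            "sexual_identity",
            kind="in_set",
            categories=frozenset({"Identifying as heterosexual"}),
            output="non_gbmsm",
        ),
    ]
    passthrough = [
        "vulnerably_housed",
        "living_alone",
        "not_married",
        "unemployed",
        "indigenous",
        "incarceration",
        "idu_ever",
        "idu_6mo",
        "snorted_6mo",
        "sex_client_ever",
        "sex_work_ever",
        "sex_work_6mo",
        "depression",
        "psych_hospital",
        "schizophrenia",
        "std_6mo",
    ]
    rules.extend(DichotomizationRule(v) for v in passthrough)
    return rules


def dichotomize(
    records: pd.DataFrame, rules: list[DichotomizationRule]
) -> ItemResponseMatrix:
    """Apply rules to a raw table, yielding the binary item matrix."""
    if "province" not in records.columns:
        raise ValueError("records must carry a 'province' column")
    unknown = [r.variable for r in rules if r.variable not in records.columns]
    if unknown:
        raise KeyError(f"rules reference unknown variables: {unknown}")
    if "id" in records.columns:
        if records["id"].duplicated().any():
            dup = records.loc[records["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate id {dup!r}")
        idx = pd.Index(records["id"], name="id")
    else:
        idx = pd.RangeIndex(len(records), name="id")
    out = pd.DataFrame(index=idx)
    for rule in rules:
        out[rule.item_name] = rule.apply(records[rule.variable]).to_numpy()
    province = pd.Series(records["province"].to_numpy(), index=idx)
    return ItemResponseMatrix(out, province)


def filter_small_provinces(
    X: ItemResponseMatrix, min_n: int = DEFAULT_MIN_PROVINCE_N
) -> tuple[ItemResponseMatrix, ExclusionReport]:
    """Drop provinces with fewer than ``min_n`` participants."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts = X.province.value_counts()
    keep_labels = [p for p in X.provinces if counts[p] >= min_n]
    excluded = [(p, int(counts[p])) for p in X.provinces if counts[p] < min_n]
    if not keep_labels:
        raise ValueError("all provinces excluded by the size filter")
    keep = X.province.isin(keep_labels)
    filtered = ItemResponseMatrix(X.responses.loc[keep].copy(), X.province.loc[keep].copy())
    report = ExclusionReport(
        n_input=X.n,
        n_after_province_filter=filtered.n,
        n_complete=filtered.n,
        excluded_provinces=excluded,
        per_item_missing={c: int(m) for c, m in filtered.missing_mask.sum().items()},
    )
    return filtered, report


def complete_cases(
    X: ItemResponseMatrix, items: list[str] | None = None
) -> tuple[ItemResponseMatrix, ExclusionReport]:
    """Keep rows fully observed on ``items`` (default: all columns)."""
    items = list(items) if items is not None else X.items
    unknown = [c for c in items if c not in X.responses.columns]
    if unknown:
        raise KeyError(f"unknown items: {unknown}")
    sub = X.responses[items]
    keep = ~sub.isna().any(axis=1)
    if not keep.any():
        raise ValueError("no complete cases remain")
    kept = ItemResponseMatrix(
        X.responses.loc[keep, items].copy(), X.province.loc[keep].copy()
    )
    report = ExclusionReport(
        n_input=X.n,
        n_after_province_filter=X.n,
        n_complete=kept.n,
        per_item_missing={c: int(m) for c, m in sub.isna().sum().items()},
    )
    return kept, report
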