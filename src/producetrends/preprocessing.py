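"""Inclusion/exclusion and classification rules producing the analysis cohort.

Raw loyalty-card extracts contain everything sold in the stores: food,
pharmacy and general-merchandise items, bulk-department non-foods (candy
moulds, pet food), coupons, and party-catering items not bought for
everyday consumption.  This module applies the study's filters, collapses
the raw demographic strata, enforces complete-case inclusion, and
classifies retained items as fresh produce or other food.

Fresh produce is defined by department *and* category: an item counts as
produce only when it sits in the produce department under one of the 13
fresh raw categories; frozen, dried, canned and juice items in the produce
department remain in the food denominator but are not produce.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import (
    AGE_COLLAPSE_MAP,
    INCOME_COLLAPSE_MAP,
    RAW_AGE_LABELS,
)

__all__ = [
    "PRODUCE_CATEGORIES",
    "ExclusionRules",
    "classify_produce",
    "classify_items",
    "apply_exclusions",
    "collapse_age",
    "collapse_income",
    "complete_case_filter",
    "prepare_cohort",
    "month_index",
    "MappingError",
]

#: The 13 fresh raw produce categories counted in the numerator.
PRODUCE_CATEGORIES: frozenset[str] = frozenset(
    {
        "summer fruit",
        "berries",
        "grapes",
        "seasonal/specialty",
        "apples and pears",
        "salad vegetables",
        "citrus",
        "tropical fruit",
        "bananas",
        "melons",
        "potatoes and onions",
        "cooking vegetables",
        "salad leaf",
    }
)

PRODUCE_DEPARTMENT = "produce"


class MappingError(KeyError):
    """Raised when a raw stratum label is outside the documented domain."""


@dataclass(frozen=True)
class ExclusionRules:
    """Configurable basket- and household-level exclusion rules.

    Weight thresholds are inclusive: a produce party tray weighing exactly
    ``produce_tray_max_lb`` is removed.  ``max_head_age_label`` is the
    oldest admissible raw head-of-household age label; households with a
    raw label outside the admissible set (e.g. heads aged 90+) are removed
    entirely.
    """

    non_food_departments: frozenset[str] = frozenset(
        {"pharmacy", "general merchandise", "floral", "health and beauty"}
    )
    non_food_item_patterns: tuple[str, ...] = (
        "candy mold", "candy making", "pet food", "coupon",
    )
    produce_tray_max_lb: float = 1.0
    deli_tray_max_lb: float = 2.0
    keg_patterns: tuple[str, ...] = ("keg",)
    max_head_age_label: str = RAW_AGE_LABELS[-1]

    def __post_init__(self) -> None:
        if self.produce_tray_max_lb <= 0 or self.deli_tray_max_lb <= 0:
            raise ValueError("tray weight thresholds must be positive")
        if self.max_head_age_label not in RAW_AGE_LABELS:
            raise ValueError(
                f"max_head_age_label {self.max_head_age_label!r} is not a raw age label"
            )

    @property
    def admissible_age_labels(self) -> frozenset[str]:
        idx = RAW_AGE_LABELS.index(self.max_head_age_label)
        return frozenset(RAW_AGE_LABELS[: idx + 1])


def classify_produce(department: str, category: str) -> bool:
    """True iff the item is fresh produce (produce department, fresh category).

    Matching is case-insensitive; unknown categories are simply not produce.
    """
    return (
        str(department).strip().lower() == PRODUCE_DEPARTMENT
        and str(category).strip().lower() in PRODUCE_CATEGORIES
    )


def classify_items(items: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification; adds ``is_produce`` to a filtered item table.

    Expects a table that has already passed :func:`apply_exclusions`, so
    every row is food.
    """
    out = items.copy()
    dept = out["department"].astype(str).str.strip().str.lower()
    cat = out["category"].astype(str).str.strip().str.lower()
    out["is_food"] = True
    out["is_produce"] = (dept == PRODUCE_DEPARTMENT) & cat.isin(PRODUCE_CATEGORIES)
    return out


def _pattern_mask(series: pd.Series, patterns: tuple[str, ...]) -> np.ndarray:
    if not patterns:
        return np.zeros(len(series), dtype=bool)
    rx = "|".join(re.escape(p) for p in patterns)
    return series.astype(str).str.contains(rx, case=False, regex=True).to_numpy()


def apply_exclusions(
    items: pd.DataFrame,
    households: pd.DataFrame,
    rules: ExclusionRules | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove non-food and non-everyday items plus over-age households.

    Each removed item is attributed to exactly the first matching rule, so
    the removal log partitions the removals:

    ``non_food_department`` -> ``non_food_pattern`` -> ``produce_tray``
    -> ``deli_tray`` -> ``keg`` -> ``head_age``.

    Returns the retained items and the removal log (one count per rule).
    """
    rules = rules or ExclusionRules()
    if "household_id" not in items.columns or "household_id" not in households.columns:
        raise KeyError("items and households must share a household_id column")

    dept = items["department"].astype(str).str.strip().str.lower()
    cat = items["category"].astype(str).str.strip().str.lower()
    desc = items["item_description"]
    weight = pd.to_numeric(items.get("unit_weight_lb"), errors="coerce")

    is_tray = cat.str.contains("party tray", case=False)
    produce_tray = (
        is_tray
        & (dept == PRODUCE_DEPARTMENT)
        & (weight >= rules.produce_tray_max_lb)
    ).to_numpy()
    deli_tray = (
        is_tray
        & (dept != PRODUCE_DEPARTMENT)
        & (weight >= rules.deli_tray_max_lb)
    ).to_numpy()

    over_age_ids = set(
        households.loc[
            households["age_group_raw"].astype(str).ne("")
            & households["age_group_raw"].notna()
            & ~households["age_group_raw"].isin(rules.admissible_age_labels),
            "household_id",
        ]
    )

    masks = {
        "non_food_department": dept.isin(
            {d.lower() for d in rules.non_food_departments}
        ).to_numpy(),
        "non_food_pattern": _pattern_mask(desc, rules.non_food_item_patterns),
        "produce_tray": produce_tray,
        "deli_tray": deli_tray,
        "keg": _pattern_mask(desc, rules.keg_patterns),
        "head_age": items["household_id"].isin(over_age_ids).to_numpy(),
    }

    removed = np.zeros(len(items), dtype=bool)
    log: dict[str, int] = {}
    for rule, mask in masks.items():
        hit = mask & ~removed
        log[rule] = int(hit.sum())
        removed |= hit
    return items.loc[~removed].copy(), log


def collapse_age(raw: str) -> str:
    """Collapse a six-level raw head-of-household age label to five levels."""
    try:
        return AGE_COLLAPSE_MAP[raw]
    except KeyError:
        raise MappingError(f"unknown raw age label {raw!r}") from None


def collapse_income(raw: str) -> str:
    """Collapse a nine-level raw household income label to six levels."""
    try:
        return INCOME_COLLAPSE_MAP[raw]
    except KeyError:
        raise MappingError(f"unknown raw income label {raw!r}") from None


def _missing(series: pd.Series) -> pd.Series:
    return series.isna() | series.astype(str).str.strip().eq("")


def complete_case_filter(
    households: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain households with observed age, income and household size.

    Family status (yes/no) is descriptive only and a missing value there
    does not exclude a household from the trend models; the three tables'
    differing totals reflect exactly this.
    """
    miss = {
        "age_group_raw": _missing(households["age_group_raw"]),
        "income_group_raw": _missing(households["income_group_raw"]),
        "household_size": _missing(households["household_size"]),
    }
    dropped = {k: int(v.sum()) for k, v in miss.items()}
    keep = ~(miss["age_group_raw"] | miss["income_group_raw"] | miss["household_size"])
    return households.loc[keep].copy(), dropped


def prepare_cohort(
    households: pd.DataFrame, rules: ExclusionRules | None = None
) -> pd.DataFrame:
    """Build the analysis cohort: under-age-cutoff, complete-case, collapsed.

    Adds collapsed ``age_group`` / ``income_group`` columns.
    """
    rules = rules or ExclusionRules()
    hh = households.loc[
        _missing(households["age_group_raw"])
        | households["age_group_raw"].isin(rules.admissible_age_labels)
    ]
    hh, _ = complete_case_filter(hh)
    hh = hh.copy()
    hh["age_group"] = hh["age_group_raw"].map(AGE_COLLAPSE_MAP)
    hh["income_group"] = hh["income_group_raw"].map(INCOME_COLLAPSE_MAP)
    return hh


def month_index(date: str | pd.Timestamp, window_start: str, n_months: int = 33) -> int:
    """Integer study month, 1 for the start month, per calendar month.

    ``window_start`` is a year-month string such as ``"2016-01"``.  Dates
    outside months 1..n_months raise ``ValueError``.
    """
    ts = pd.Timestamp(date)
    start = pd.Period(window_start, freq="M")
    t = (ts.year - start.year) * 12 + (ts.month - start.month) + 1
    if not 1 <= t <= n_months:
        raise ValueError(f"date {ts.date()} outside the {n_months}-month study window")
    return int(t)


def month_index_series(
    dates: pd.Series, window_start: str, n_months: int = 33
) -> pd.Series:
    """Vectorised :func:`month_index` for an item table's date column."""
    ts = pd.to_datetime(dates)
    start = pd.Period(window_start, freq="M")
    t = (ts.dt.year - start.year) * 12 + (ts.dt.month - start.month) + 1
    bad = (t < 1) | (t > n_months)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} dates fall outside the {n_months}-month study window"
        )
    return t.astype(int)
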