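"""Household-month binomial panel and weighted monthly descriptive series.

The analysis unit is the household-month: Y produce items out of n food
items.  Items are counted once per unique (transaction, description,
class) line, regardless of quantity, so the outcome is a purchase
frequency, not a quantity.  Monthly descriptive curves are item-weighted
means of household proportions — algebraically the pooled proportion
sum(Y)/sum(n) — with a design-based between-household variance for the
95% interval, respecting the household as the sampling unit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .preprocessing import classify_items, month_index_series

__all__ = ["build_panel", "weighted_monthly_series", "grand_mean"]

_DEDUP_KEY = ["transaction_id", "item_description", "class"]


def build_panel(
    items_clean: pd.DataFrame,
    cohort: pd.DataFrame,
    window_start: str = "2016-01",
    n_months: int = 33,
) -> pd.DataFrame:
    """Count produce and total food items per household-month.

    ``items_clean`` must already have passed the exclusion filters.  Lines
    duplicated within a transaction are counted once.  Items from
    households outside the cohort are dropped (with a warning giving the
    count); household-months with no food purchases have no row.
    """
    items = items_clean.drop_duplicates(_DEDUP_KEY)
    if "is_produce" not in items.columns:
        items = classify_items(items)
    in_cohort = items["household_id"].isin(set(cohort["household_id"]))
    n_dropped = int((~in_cohort).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} items from households outside the cohort",
            stacklevel=2,
        )
        items = items.loc[in_cohort]
    items = items.copy()
    items["month"] = month_index_series(items["date"], window_start, n_months)

    panel = (
        items.groupby(["household_id", "month"], sort=True)
        .agg(produce=("is_produce", "sum"), total=("is_produce", "size"))
        .reset_index()
    )
    demo = cohort.set_index("household_id")[["age_group", "income_group"]]
    panel = panel.join(demo, on="household_id")
    panel["produce"] = panel["produce"].astype(int)
    panel["total"] = panel["total"].astype(int)
    return panel


def weighted_monthly_series(
    panel: pd.DataFrame, grouping: str = "none"
) -> pd.DataFrame:
    """Item-weighted monthly mean produce proportion with a 95% CI.

    Weights are the household's food-item counts, so the weighted mean
    equals the pooled proportion sum(Y)/sum(n) per month (and group).  The
    variance is design-based across households:
    Var = sum_i w_i^2 (p_i - pbar)^2 / (sum_i w_i)^2.
    """
    keys = {"none": ["month"], "age": ["age_group", "month"], "income": ["income_group", "month"]}
    if grouping not in keys:
        raise ValueError(f"grouping must be one of {sorted(keys)}, got {grouping!r}")

    def _one(g: pd.DataFrame) -> pd.Series:
        w = g["total"].to_numpy(float)
        p = g["produce"].to_numpy(float) / w
        wm = float(np.sum(w * p) / np.sum(w))
        var = float(np.sum(w**2 * (p - wm) ** 2) / np.sum(w) ** 2)
        half = 1.959964 * np.sqrt(var)
        return pd.Series(
            {
                "weighted_mean": wm,
                "ci_low": wm - half,
                "ci_high": wm + half,
                "total_items": int(np.sum(w)),
                "n_households": len(g),
            }
        )

    out = (
        panel.groupby(keys[grouping], sort=True)
        .apply(_one, include_groups=False)
        .reset_index()
    )
    return out


def grand_mean(panel: pd.DataFrame) -> float:
    """Item-weighted overall produce proportion across all rows."""
    if panel.empty:
        raise ValueError("panel is empty")
    return float(panel["produce"].sum() / panel["total"].sum())
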