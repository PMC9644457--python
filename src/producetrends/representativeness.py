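"""Descriptive-table arithmetic and the loyalty-vs-census comparison.

Reproduces the study's descriptive percentage tables from marginal counts
and compares loyalty-card household margins with American Community
Survey (ACS) county margins by Pearson chi-square.  The chi-square treats
the two sources as independent samples — an approximation, since loyalty
households are in fact a subset of county households.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .labels import ACS_INCOME_COLLAPSE_MAP, ACS_INCOME_LABELS, INCOME_LABELS

__all__ = [
    "MarginalTable",
    "round_half_away",
    "table_percentages",
    "collapse_for_acs",
    "chi_square_comparison",
]


@dataclass(frozen=True)
class MarginalTable:
    """Category counts from one source (internal loyalty data or external census)."""

    labels: tuple[str, ...]
    counts: tuple[int, ...]
    source: str = "internal"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts must align")
        if len(self.labels) < 2:
            raise ValueError("need at least two categories")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def round_half_away(x, decimals: int = 1):
    """Round half away from zero, as the study tables print percentages.

    numpy's default rounds half to even; printed tables use the
    conventional half-up (away from zero for negatives).
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out if out.ndim else float(out)


def table_percentages(
    counts: pd.DataFrame, axis: str = "column", decimals: int = 1
) -> pd.DataFrame:
    """Percentage table normalised along rows or columns.

    ``axis='column'`` divides each cell by its column total (each column
    sums to 100), ``axis='row'`` by its row total.  Zero totals raise.
    """
    if axis not in ("row", "column"):
        raise ValueError("axis must be 'row' or 'column'")
    totals = counts.sum(axis=1 if axis == "row" else 0)
    if (totals == 0).any():
        raise ZeroDivisionError("zero marginal total; percentages undefined")
    pct = 100 * counts.div(totals, axis=0 if axis == "row" else 1)
    return pct.apply(lambda col: round_half_away(col, decimals))


def collapse_for_acs(loyalty_income: MarginalTable) -> MarginalTable:
    """Collapse six-level income counts to the five ACS comparison levels."""
    if tuple(loyalty_income.labels) != INCOME_LABELS:
        raise KeyError(
            f"expected the six collapsed income labels {INCOME_LABELS}, "
            f"got {loyalty_income.labels}"
        )
    sums = dict.fromkeys(ACS_INCOME_LABELS, 0)
    for lab, c in zip(loyalty_income.labels, loyalty_income.counts):
        sums[ACS_INCOME_COLLAPSE_MAP[lab]] += int(c)
    return MarginalTable(
        labels=ACS_INCOME_LABELS,
        counts=tuple(sums[lab] for lab in ACS_INCOME_LABELS),
        source=loyalty_income.source,
    )


def chi_square_comparison(
    internal: MarginalTable, external: MarginalTable
) -> dict:
    """Pearson chi-square on the 2 x k source-by-category contingency.

    Returns statistic, df = k - 1, the two-sided p-value, and a
    ``small_expected`` flag when any expected cell is below 5.
    """
    if internal.labels != external.labels:
        raise ValueError("marginal tables must share labels in the same order")
    table = np.array([internal.counts, external.counts], dtype=float)
    res = stats.chi2_contingency(table, correction=False)
    return {
        "statistic": float(res.statistic),
        "df": int(res.dof),
        "p_value": float(res.pvalue),
        "small_expected": bool((res.expected_freq < 5).any()),
    }
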