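"""Demographic stratum labels and the collapsing maps between them.

The loyalty-card demographics table carries nine raw annual-income groups
and six raw head-of-household age groups.  Exploratory overlap in produce
purchasing motivates collapsing to six income and five age groups for the
trend models; a further income collapse to five groups aligns the table
with the American Community Survey (ACS) county margins.
"""

from __future__ import annotations

RAW_AGE_LABELS: tuple[str, ...] = (
    "18-24.9", "25-34.9", "35-44.9", "45-54.9", "55-74.9", "75-89",
)
#: Raw label for heads of household aged 90+, excluded from the cohort.
OVER_AGE_LABEL = "90-99"

AGE_LABELS: tuple[str, ...] = ("18-24", "25-34", "35-54", "55-74", "75-89")

RAW_INCOME_LABELS: tuple[str, ...] = (
    "0-14.9K", "15-19.9K", "20-29.9K", "30-39.9K", "40-49.9K",
    "50-74.9K", "75-99.9K", "100-124.9K", ">=125K",
)

INCOME_LABELS: tuple[str, ...] = (
    "0-14.9K", "15-29.9K", "30-49.9K", "50-74.9K", "75-99.9K", ">=100K",
)

#: Five-level income labels matching the ACS county household table.
ACS_INCOME_LABELS: tuple[str, ...] = (
    "0-14.9K", "15-49.9K", "50-74.9K", "75-99.9K", ">=100K",
)

HOUSEHOLD_SIZE_LABELS: tuple[str, ...] = ("1", "2", "3", "4", "5", ">=6")

AGE_COLLAPSE_MAP: dict[str, str] = {
    "18-24.9": "18-24",
    "25-34.9": "25-34",
    "35-44.9": "35-54",
    "45-54.9": "35-54",
    "55-74.9": "55-74",
    "75-89": "75-89",
}

INCOME_COLLAPSE_MAP: dict[str, str] = {
    "0-14.9K": "0-14.9K",
    "15-19.9K": "15-29.9K",
    "20-29.9K": "15-29.9K",
    "30-39.9K": "30-49.9K",
    "40-49.9K": "30-49.9K",
    "50-74.9K": "50-74.9K",
    "75-99.9K": "75-99.9K",
    "100-124.9K": ">=100K",
    ">=125K": ">=100K",
}

ACS_INCOME_COLLAPSE_MAP: dict[str, str] = {
    "0-14.9K": "0-14.9K",
    "15-29.9K": "15-49.9K",
    "30-49.9K": "15-49.9K",
    "50-74.9K": "50-74.9K",
    "75-99.9K": "75-99.9K",
    ">=100K": ">=100K",
}

#: All 30 collapsed age x income cells, age-major order.
CELLS: tuple[tuple[str, str], ...] = tuple(
    (a, i) for a in AGE_LABELS for i in INCOME_LABELS
)
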