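"""Synthetic loyalty-card transaction and household generator.

The study's real data are proprietary, so this module generates household
demographics and transaction-level purchase records with the statistical
structure the analysis assumes: stratified demographics with field-level
missingness, monthly store visits, per-visit baskets, and a produce share
following a logit-linear mean model

    logit p_c(t) = b0_c + bS1 sin(2*pi*t/12) + bS2 cos(2*pi*t/12) + bL_c * t

per collapsed age x income cell ``c`` and study month ``t``.  The default
calibration reflects the study county: per-cell January-2016 baselines of
roughly 12-19% rising with income and (non-monotonically) with age, a
seasonal swing of about 2.5 percentage points peaking in May, and annual
trends from about 1.4%/yr in the youngest households down to almost zero
in the oldest.

Two output granularities share the same mean model:

* :func:`generate_transactions` — item-level records that exercise every
  preprocessing filter (non-food departments, candy moulds, pet food,
  coupons, party trays, kegs, over-age households, duplicated lines);
* :func:`generate_panel` — household-month binomial counts drawn directly,
  for simulation studies where item-level detail is irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .labels import (
    AGE_COLLAPSE_MAP,
    AGE_LABELS,
    CELLS,
    HOUSEHOLD_SIZE_LABELS,
    INCOME_COLLAPSE_MAP,
    INCOME_LABELS,
    OVER_AGE_LABEL,
    RAW_AGE_LABELS,
    RAW_INCOME_LABELS,
)
from .preprocessing import PRODUCE_CATEGORIES

__all__ = [
    "ConfigError",
    "TrueModelParams",
    "GeneratorConfig",
    "default_truth",
    "true_percent",
    "generate_households",
    "generate_transactions",
    "generate_panel",
    "write_tables",
]


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


# ---------------------------------------------------------------------------
# True model parameters

_AGE_MAIN_PCT = {"18-24": 13.5, "25-34": 15.6, "35-54": 15.0, "55-74": 16.3, "75-89": 16.8}
_INCOME_MAIN_PCT = {
    "0-14.9K": 13.9, "15-29.9K": 14.5, "30-49.9K": 15.2,
    "50-74.9K": 15.9, "75-99.9K": 16.5, ">=100K": 17.1,
}
_GRID_CENTER_PCT = 15.5
# Annual change targets in percentage points of produce share per year.
_ANNUAL_CHANGE_PCT = {
    "18-24": [1.42, 1.30, 1.15, 1.00, 0.85, 0.69],
    "25-34": [0.45] * 6,
    "35-54": [0.35] * 6,
    "55-74": [0.25] * 6,
    "75-89": [0.03] * 6,
}
_SEASONAL_AMPLITUDE = 0.09  # logit scale; ~2.5 pct points peak-to-trough at p=0.17
_PEAK_MONTH = 5  # May; the curve peaks within the April-July window


@dataclass(frozen=True)
class TrueModelParams:
    """Generating coefficients of the logit mean model, per age x income cell.

    ``dispersion`` >= 1 selects beta-binomial item-level draws whose
    variance is about ``dispersion`` times binomial at the mean monthly
    item count; 1 is exact binomial.
    """

    intercept_by_cell: dict[tuple[str, str], float]
    seasonal_sin: float
    seasonal_cos: float
    slope_by_cell: dict[tuple[str, str], float]
    dispersion: float = 1.0
    period: int = 12

    def __post_init__(self) -> None:
        for d in (self.intercept_by_cell, self.slope_by_cell):
            for cell, v in d.items():
                if not math.isfinite(v):
                    raise ConfigError(f"non-finite coefficient for cell {cell}")
        if not (
            math.isfinite(self.seasonal_sin) and math.isfinite(self.seasonal_cos)
        ):
            raise ConfigError("non-finite seasonal coefficients")
        if self.dispersion < 1:
            raise ConfigError("dispersion must be >= 1")

    def seasonal(self, t: float | np.ndarray) -> float | np.ndarray:
        w = 2 * np.pi * np.asarray(t, dtype=float) / self.period
        return self.seasonal_sin * np.sin(w) + self.seasonal_cos * np.cos(w)

    def linear_predictor(
        self, cell: tuple[str, str], t: float | np.ndarray
    ) -> float | np.ndarray:
        if cell not in self.intercept_by_cell:
            raise KeyError(f"unknown age x income cell {cell!r}")
        t = np.asarray(t, dtype=float)
        return (
            self.intercept_by_cell[cell]
            + self.seasonal(t)
            + self.slope_by_cell[cell] * t
        )

    def true_annual_change_percent(
        self, cell: tuple[str, str], t_mid: float
    ) -> float:
        """Generating-truth annual change on the percent scale.

        Defined exactly as the model's annual-change contrast: the
        12-month difference of seasonal-free percents anchored at the
        window midpoint.
        """
        b0 = self.intercept_by_cell[cell]
        m = self.slope_by_cell[cell]
        eta0 = b0 + m * t_mid
        return 100.0 * (expit(eta0 + 12 * m) - expit(eta0))


def default_truth(dispersion: float = 1.0) -> TrueModelParams:
    """Default calibration of the generating model (see module docstring).

    Baseline percents come from an additive age x income grid with the two
    extreme cells pinned at 12.2% (youngest, lowest income) and 19.3%
    (oldest, highest income); annual-change targets are converted to
    per-month logit slopes at the cell baseline.
    """
    w = 2 * np.pi * _PEAK_MONTH / 12
    s1 = _SEASONAL_AMPLITUDE * math.sin(w)
    s2 = _SEASONAL_AMPLITUDE * math.cos(w)

    baseline_pct = {
        (a, i): _AGE_MAIN_PCT[a] + _INCOME_MAIN_PCT[i] - _GRID_CENTER_PCT
        for a, i in CELLS
    }
    baseline_pct[("18-24", "0-14.9K")] = 12.2
    baseline_pct[("75-89", ">=100K")] = 19.3

    intercepts: dict[tuple[str, str], float] = {}
    slopes: dict[tuple[str, str], float] = {}
    s_at_1 = s1 * math.sin(2 * np.pi / 12) + s2 * math.cos(2 * np.pi / 12)
    t_mid = 17.0  # midpoint of the default 33-month window
    for a, i in CELLS:
        p = baseline_pct[(a, i)] / 100.0
        target = _ANNUAL_CHANGE_PCT[a][INCOME_LABELS.index(i)] / 100.0
        # solve for the per-month logit slope whose midpoint-anchored
        # 12-month percent difference equals the target, holding the
        # January-2016 percent anchored at the cell baseline
        m = target / (12 * p * (1 - p))
        for _ in range(100):
            b0 = float(logit(p)) - s_at_1 - m
            eta0 = b0 + m * t_mid
            implied = float(expit(eta0 + 12 * m) - expit(eta0))
            if abs(implied - target) < 1e-12:
                break
            m *= target / implied
        slopes[(a, i)] = m
        # anchor: percent at t=1 (January 2016, seasonal included) = baseline
        intercepts[(a, i)] = float(logit(p)) - s_at_1 - m
    return TrueModelParams(
        intercept_by_cell=intercepts,
        seasonal_sin=s1,
        seasonal_cos=s2,
        slope_by_cell=slopes,
        dispersion=dispersion,
    )


def true_percent(
    params: TrueModelParams, cell: tuple[str, str], month: int | np.ndarray
) -> float | np.ndarray:
    """Generating produce proportion for a cell at study month ``t`` >= 1."""
    if np.any(np.asarray(month) < 1):
        raise ValueError("study month must be >= 1")
    out = expit(params.linear_predictor(cell, month))
    return float(out) if np.isscalar(month) or np.ndim(month) == 0 else out


# ---------------------------------------------------------------------------
# Generator configuration

# Raw shares chosen so collapsed margins match the published county tables.
_DEFAULT_AGE_SHARES = (0.028, 0.142, 0.175, 0.176, 0.368, 0.111)
_DEFAULT_INCOME_SHARES = (
    0.059, 0.039, 0.060, 0.093, 0.100, 0.279, 0.163, 0.120, 0.087,
)
_DEFAULT_SIZE_SHARES = (0.183, 0.237, 0.239, 0.156, 0.097, 0.088)
_FAMILY_YES_SHARE = 0.496
_ZIP_CODES = ("14604", "14605", "14607", "14609", "14611", "14619", "14620", "14621")
_N_STORES = 17


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition configuration for the synthetic generator.

    Defaults are the study conditions: 33 study months from January 2016,
    demographic shares matching the county tables, missingness of 4% (age),
    9% (income) and 15% (family status and size, jointly), about five store
    visits per household-month, and 1.6% of households headed by someone
    aged 90+ (excluded downstream).
    """

    n_households: int = 1000
    study_months: int = 33
    start_month: str = "2016-01"
    income_shares: tuple[float, ...] = _DEFAULT_INCOME_SHARES
    age_shares: tuple[float, ...] = _DEFAULT_AGE_SHARES
    over_age_share: float = 0.016
    missing_rate_age: float = 0.04
    missing_rate_income: float = 0.09
    missing_rate_family: float = 0.15
    visits_per_month: float = 5.0
    items_per_visit: float = 20.0
    filter_target_share: float = 0.05
    duplicate_line_share: float = 0.01
    model_truth: TrueModelParams = field(default_factory=default_truth)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_households < 1:
            raise ConfigError("n_households must be >= 1")
        if self.study_months < 1:
            raise ConfigError("study_months must be >= 1")
        for name, vec, k in (
            ("income_shares", self.income_shares, len(RAW_INCOME_LABELS)),
            ("age_shares", self.age_shares, len(RAW_AGE_LABELS)),
        ):
            if len(vec) != k:
                raise ConfigError(f"{name} must have length {k}")
            if any(p < 0 for p in vec) or abs(sum(vec) - 1.0) > 1e-12:
                raise ConfigError(f"{name} must be a probability vector summing to 1")
        for name, r in (
            ("missing_rate_age", self.missing_rate_age),
            ("missing_rate_income", self.missing_rate_income),
            ("missing_rate_family", self.missing_rate_family),
            ("over_age_share", self.over_age_share),
            ("filter_target_share", self.filter_target_share),
            ("duplicate_line_share", self.duplicate_line_share),
        ):
            if not 0 <= r < 1:
                raise ConfigError(f"{name} must be in [0, 1)")
        if self.visits_per_month <= 0 or self.items_per_visit <= 0:
            raise ConfigError("visit and basket rates must be positive")

    def rng_streams(self) -> tuple[np.random.Generator, np.random.Generator]:
        """One independent stream per output table, split from the seed.

        The household and transaction tables consume separate streams, so
        regenerating households does not perturb the transaction draws.
        """
        hh_ss, tx_ss = np.random.SeedSequence(self.seed).spawn(2)
        return np.random.default_rng(hh_ss), np.random.default_rng(tx_ss)


# ---------------------------------------------------------------------------
# Households

def generate_households(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the household demographics table.

    Missingness (encoded as empty strings) is applied independently per
    field family: age, income, and family-status-with-size (the latter two
    share one mask, as in the source data where both stem from the same
    commercial enrichment).
    """
    rng, _ = config.rng_streams()
    n = config.n_households

    age = rng.choice(RAW_AGE_LABELS, size=n, p=config.age_shares).astype(object)
    over = rng.random(n) < config.over_age_share
    age[over] = OVER_AGE_LABEL
    income = rng.choice(RAW_INCOME_LABELS, size=n, p=config.income_shares).astype(object)
    family = rng.choice(
        ["yes", "no"], size=n, p=[_FAMILY_YES_SHARE, 1 - _FAMILY_YES_SHARE]
    ).astype(object)
    size = rng.choice(HOUSEHOLD_SIZE_LABELS, size=n, p=_DEFAULT_SIZE_SHARES).astype(object)
    zips = rng.choice(_ZIP_CODES, size=n)

    age[rng.random(n) < config.missing_rate_age] = ""
    income[rng.random(n) < config.missing_rate_income] = ""
    fam_missing = rng.random(n) < config.missing_rate_family
    family[fam_missing] = ""
    size[fam_missing] = ""

    return pd.DataFrame(
        {
            "household_id": [f"H{i:07d}" for i in range(n)],
            "age_group_raw": age,
            "income_group_raw": income,
            "family": family,
            "household_size": size,
            "zip": zips,
        }
    )


def _household_cells(households: pd.DataFrame) -> list[tuple[str, str]]:
    """Collapsed cell per household; incomplete or over-age households get
    a typical mid-distribution cell (they are dropped downstream anyway)."""
    fallback = ("35-54", "50-74.9K")
    cells = []
    for a, i in zip(households["age_group_raw"], households["income_group_raw"]):
        ca = AGE_COLLAPSE_MAP.get(str(a))
        ci = INCOME_COLLAPSE_MAP.get(str(i))
        cells.append((ca, ci) if ca and ci else fallback)
    return cells


def _cell_month_probs(
    cells: list[tuple[str, str]], truth: TrueModelParams, T: int
) -> np.ndarray:
    """(n_households, T) matrix of generating produce probabilities."""
    months = np.arange(1, T + 1)
    unique = sorted(set(cells))
    lookup = {c: expit(truth.linear_predictor(c, months)) for c in unique}
    return np.vstack([lookup[c] for c in cells])


def _betabinomial_probs(
    p: np.ndarray, truth: TrueModelParams, mean_items: float, rng: np.random.Generator
) -> np.ndarray:
    """Household-month success probabilities under overdispersion.

    With dispersion d > 1, p is replaced by a Beta draw with mean p and
    concentration kappa = (m - d)/(d - 1) at mean monthly item count m,
    inflating Var(Y) by about d relative to binomial.
    """
    if truth.dispersion == 1.0:
        return p
    kappa = max((mean_items - truth.dispersion) / (truth.dispersion - 1.0), 1e-6)
    return rng.beta(p * kappa, (1 - p) * kappa)


# ---------------------------------------------------------------------------
# Transactions

_NONPRODUCE_FOOD_CATALOG: tuple[tuple[str, str, str, str, float], ...] = (
    ("Dairy", "yogurt", "greek yogurt", "GREEK YOGURT PLAIN", 1.1),
    ("Dairy", "milk", "whole milk", "WHOLE MILK GAL", 8.6),
    ("Dairy", "cheese", "cheddar", "CHEDDAR BLOCK", 0.5),
    ("Bakery", "bread", "sandwich bread", "WHEAT BREAD LOAF", 1.5),
    ("Bakery", "rolls", "dinner rolls", "DINNER ROLLS 12CT", 1.0),
    ("Meat", "chicken", "breast", "CHICKEN BREAST", 2.0),
    ("Meat", "ground beef", "85/15", "GROUND BEEF 85", 1.0),
    ("Seafood", "fish", "salmon", "ATLANTIC SALMON FILLET", 1.0),
    ("Grocery", "cereal", "oats", "ROLLED OATS", 2.0),
    ("Grocery", "pasta", "spaghetti", "SPAGHETTI 1LB", 1.0),
    ("Grocery", "canned goods", "soup", "TOMATO SOUP CAN", 0.8),
    ("Frozen", "pizza", "cheese pizza", "FROZEN CHEESE PIZZA", 1.8),
    ("Frozen", "desserts", "ice cream", "VANILLA ICE CREAM", 1.5),
    ("Deli", "sliced meats", "turkey", "SLICED TURKEY HALF LB", 0.5),
    ("Beverages", "juice", "orange juice", "ORANGE JUICE 64OZ", 4.3),
    # produce-department items outside the 13 fresh categories: food, not produce
    ("Produce", "frozen vegetables", "mixed", "FROZEN MIXED VEGETABLES", 1.0),
    ("Produce", "dried fruit", "raisins", "RAISINS CANISTER", 1.3),
    ("Produce", "canned vegetables", "corn", "CANNED SWEET CORN", 0.9),
    ("Produce", "juice", "apple juice", "FRESH PRESSED APPLE JUICE", 4.2),
)

_PRODUCE_DESCRIPTIONS: dict[str, str] = {
    "summer fruit": "PEACHES YELLOW",
    "berries": "STRAWBERRIES 1LB",
    "grapes": "GRAPES RED SEEDLESS",
    "seasonal/specialty": "POMEGRANATE",
    "apples and pears": "GALA APPLES",
    "salad vegetables": "CUCUMBER",
    "citrus": "NAVEL ORANGES",
    "tropical fruit": "MANGO",
    "bananas": "BANANAS YELLOW",
    "melons": "CANTALOUPE",
    "potatoes and onions": "RUSSET POTATOES 5LB",
    "cooking vegetables": "BROCCOLI CROWNS",
    "salad leaf": "ROMAINE HEARTS",
}

# (department, category, class, description, weight_low, weight_high)
_FILTER_TARGET_CATALOG: tuple[tuple[str, str, str, str, float, float], ...] = (
    ("Pharmacy", "medicine", "pain relief", "IBUPROFEN 200MG 100CT", 0.1, 0.1),
    ("General Merchandise", "paper goods", "towels", "PAPER TOWELS 6PK", 2.0, 2.0),
    ("Floral", "bouquets", "roses", "ROSE BOUQUET DOZEN", 1.0, 1.0),
    ("Bulk Foods", "candy making", "molds", "CANDY MAKING MOLD", 0.2, 0.2),
    ("Bulk Foods", "pet food", "dog food", "BULK PET FOOD SCOOP", 3.0, 6.0),
    ("Grocery", "promotions", "coupon", "STORE COUPON", 0.0, 0.0),
    ("Produce", "produce party tray", "tray", "PRODUCE PARTY TRAY LARGE", 1.0, 3.0),
    ("Produce", "produce party tray", "tray", "PRODUCE SNACK TRAY SMALL", 0.4, 0.99),
    ("Deli", "deli party tray", "cold cuts", "CHEESE COLD CUT PARTY TRAY", 2.0, 4.0),
    ("Deli", "deli party tray", "cold cuts", "DELI SNACK TRAY SMALL", 0.8, 1.99),
    ("Beverages", "beer", "keg", "BEER KEG 15.5GAL", 160.0, 160.0),
)

_FRESH_CATEGORIES = sorted(PRODUCE_CATEGORIES)


def generate_transactions(
    households: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Draw the item-level transaction table for every household.

    Per household-month, the visit count is Poisson(``visits_per_month``);
    each visit's basket holds 1 + Poisson(``items_per_visit`` - 1) items.
    Each item is, with probability ``filter_target_share``, one of the
    filter-target products the preprocessing rules must handle; otherwise
    it is a food item, fresh produce with the cell's true probability.
    Item descriptions carry a within-transaction slot suffix so distinct
    items never collide; a ``duplicate_line_share`` fraction of lines is
    then emitted twice verbatim to exercise the unique-item counting rule.
    """
    if households.empty:
        raise ValueError("households table is empty")
    _, rng = config.rng_streams()
    T = config.study_months
    n_h = len(households)
    truth = config.model_truth

    cells = _household_cells(households)
    probs = _cell_month_probs(cells, truth, T)  # (n_h, T)
    mean_items = config.visits_per_month * config.items_per_visit
    probs = _betabinomial_probs(probs, truth, mean_items, rng)

    visits = rng.poisson(config.visits_per_month, size=(n_h, T))
    hh_idx_m, month_m = np.nonzero(visits)
    v = visits[hh_idx_m, month_m]
    # per-transaction arrays
    tx_hh = np.repeat(hh_idx_m, v)
    tx_month = np.repeat(month_m, v) + 1
    n_tx = tx_hh.size
    tx_items = 1 + rng.poisson(config.items_per_visit - 1.0, size=n_tx)
    tx_day = rng.integers(1, 29, size=n_tx)
    tx_store = rng.integers(1, _N_STORES + 1, size=n_tx)

    # per-item arrays
    it_tx = np.repeat(np.arange(n_tx), tx_items)
    n_items = it_tx.size
    it_hh = tx_hh[it_tx]
    it_month = tx_month[it_tx]
    it_p = probs[it_hh, it_month - 1]
    is_target = rng.random(n_items) < config.filter_target_share
    is_produce = (~is_target) & (rng.random(n_items) < it_p)

    dept = np.empty(n_items, dtype=object)
    cat = np.empty(n_items, dtype=object)
    klass = np.empty(n_items, dtype=object)
    desc = np.empty(n_items, dtype=object)
    weight = np.empty(n_items, dtype=float)

    # fresh produce items
    pi = np.flatnonzero(is_produce)
    pick = rng.integers(0, len(_FRESH_CATEGORIES), size=pi.size)
    dept[pi] = "Produce"
    for k, c in enumerate(_FRESH_CATEGORIES):
        sel = pi[pick == k]
        cat[sel] = c
        klass[sel] = c
        desc[sel] = _PRODUCE_DESCRIPTIONS[c]
    weight[pi] = np.round(rng.uniform(0.3, 3.0, size=pi.size), 2)

    # other food items
    fi = np.flatnonzero(~is_target & ~is_produce)
    pick = rng.integers(0, len(_NONPRODUCE_FOOD_CATALOG), size=fi.size)
    for k, (d, c, cl, de, w) in enumerate(_NONPRODUCE_FOOD_CATALOG):
        sel = fi[pick == k]
        dept[sel] = d
        cat[sel] = c
        klass[sel] = cl
        desc[sel] = de
        weight[sel] = w

    # filter-target items
    ti = np.flatnonzero(is_target)
    pick = rng.integers(0, len(_FILTER_TARGET_CATALOG), size=ti.size)
    for k, (d, c, cl, de, lo, hi) in enumerate(_FILTER_TARGET_CATALOG):
        sel = ti[pick == k]
        dept[sel] = d
        cat[sel] = c
        klass[sel] = cl
        desc[sel] = de
        weight[sel] = np.round(rng.uniform(lo, hi, size=sel.size), 2) if hi > lo else lo

    # unique descriptions within a transaction via slot suffix
    slot = np.arange(n_items) - np.repeat(np.cumsum(tx_items) - tx_items, tx_items)
    desc = np.array(
        [f"{d} #{s:02d}" for d, s in zip(desc, slot)], dtype=object
    )

    start = pd.Period(config.start_month, freq="M")
    month0 = start.year * 12 + (start.month - 1) + (tx_month - 1)
    years = month0 // 12
    months = month0 % 12 + 1
    tx_date = np.array(
        [f"{y:04d}-{m:02d}-{d:02d}" for y, m, d in zip(years, months, tx_day)]
    )
    hh_ids = households["household_id"].to_numpy()

    out = pd.DataFrame(
        {
            "household_id": hh_ids[it_hh],
            "transaction_id": np.array([f"T{t:08d}" for t in it_tx]),
            "date": tx_date[it_tx],
            "store_id": tx_store[it_tx],
            "department": dept,
            "category": cat,
            "class": klass,
            "item_description": desc,
            "unit_weight_lb": weight,
        }
    )
    if config.duplicate_line_share > 0:
        dup = np.flatnonzero(rng.random(n_items) < config.duplicate_line_share)
        out = pd.concat([out, out.iloc[dup]], ignore_index=True)
        out = out.sort_values(
            ["transaction_id", "item_description"], kind="stable"
        ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Direct panel generation

def generate_panel(
    households: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Draw the household-month binomial panel directly from the mean model.

    Restricted to the analysis cohort (complete demographics, head under
    the age cutoff), mirroring what preprocessing + aggregation produce
    from the transaction path but without item-level detail.  Months with
    zero store visits yield no row.
    """
    from .preprocessing import prepare_cohort

    _, rng = config.rng_streams()
    cohort = prepare_cohort(households)
    if cohort.empty:
        raise ValueError("no cohort households with complete demographics")
    T = config.study_months
    truth = config.model_truth
    n_h = len(cohort)

    cells = list(zip(cohort["age_group"], cohort["income_group"]))
    probs = _cell_month_probs(cells, truth, T)
    mean_items = config.visits_per_month * config.items_per_visit
    probs = _betabinomial_probs(probs, truth, mean_items, rng)

    visits = rng.poisson(config.visits_per_month, size=(n_h, T))
    extra = rng.poisson(visits * (config.items_per_visit - 1.0))
    totals = visits + extra
    hh_idx, month_idx = np.nonzero(visits)
    n_ij = totals[hh_idx, month_idx]
    y_ij = rng.binomial(n_ij, probs[hh_idx, month_idx])

    return pd.DataFrame(
        {
            "household_id": cohort["household_id"].to_numpy()[hh_idx],
            "month": month_idx + 1,
            "produce": y_ij,
            "total": n_ij,
            "age_group": cohort["age_group"].to_numpy()[hh_idx],
            "income_group": cohort["income_group"].to_numpy()[hh_idx],
        }
    )


def write_tables(
    config: GeneratorConfig, out_dir
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate and write households.csv and transactions.csv."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hh = generate_households(config)
    tx = generate_transactions(hh, config)
    hh.to_csv(out / "households.csv", index=False)
    tx.to_csv(out / "transactions.csv", index=False)
    return hh, tx
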