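import numpy as np
import pandas as pd
import pytest

from producetrends import (
    GeneratorConfig,
    apply_exclusions,
    build_panel,
    classify_items,
    generate_households,
    generate_panel,
    generate_transactions,
    prepare_cohort,
)


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured study configuration."""
    return GeneratorConfig(
        n_households=150, visits_per_month=3.0, items_per_visit=12.0, seed=11
    )


@pytest.fixture(scope="session")
def households(small_config):
    return generate_households(small_config)


@pytest.fixture(scope="session")
def transactions(small_config, households):
    return generate_transactions(households, small_config)


@pytest.fixture(scope="session")
def clean_items(small_config, households, transactions):
    items, _ = apply_exclusions(transactions, households)
    return classify_items(items)


@pytest.fixture(scope="session")
def cohort(households):
    return prepare_cohort(households)


@pytest.fixture(scope="session")
def panel(small_config, clean_items, cohort):
    with pytest.warns(UserWarning, match="outside the cohort"):
        return build_panel(
            clean_items, cohort, small_config.start_month, small_config.study_months
        )


@pytest.fixture(scope="session")
def medium_panel():
    """Direct household-month panel, larger than the transaction-path one."""
    cfg = GeneratorConfig(n_households=500, seed=42)
    return generate_panel(generate_households(cfg), cfg)


@pytest.fixture
def filter_fixture():
    """20 crafted items + 3 households covering every exclusion rule."""
    hh = pd.DataFrame(
        {
            "household_id": ["H1", "H2", "H9"],
            "age_group_raw": ["25-34.9", "55-74.9", "90-99"],
            "income_group_raw": ["30-39.9K", "75-99.9K", "50-74.9K"],
            "family": ["yes", "no", "no"],
            "household_size": ["3", "2", "1"],
            "zip": ["14604"] * 3,
        }
    )
    rows = [
        # (household, dept, category, class, description, weight, expected_rule or None)
        ("H1", "Produce", "bananas", "bananas", "BANANAS YELLOW", 1.1, None),
        ("H1", "Produce", "salad leaf", "salad leaf", "ROMAINE HEARTS", 0.7, None),
        ("H1", "Produce", "frozen vegetables", "mixed", "FROZEN MIXED VEGETABLES", 1.0, None),
        ("H1", "Produce", "dried fruit", "raisins", "RAISINS CANISTER", 1.3, None),
        ("H1", "Produce", "canned vegetables", "corn", "CANNED SWEET CORN", 0.9, None),
        ("H1", "Produce", "juice", "apple juice", "FRESH PRESSED APPLE JUICE", 4.2, None),
        ("H1", "Dairy", "yogurt", "greek yogurt", "GREEK YOGURT PLAIN", 1.1, None),
        ("H1", "Pharmacy", "medicine", "pain relief", "IBUPROFEN 200MG", 0.1, "non_food_department"),
        ("H1", "General Merchandise", "paper goods", "towels", "PAPER TOWELS", 2.0, "non_food_department"),
        ("H1", "Bulk Foods", "candy making", "molds", "CANDY MAKING MOLD", 0.2, "non_food_pattern"),
        ("H1", "Bulk Foods", "pet food", "dog food", "BULK PET FOOD", 4.0, "non_food_pattern"),
        ("H1", "Grocery", "promotions", "coupon", "STORE COUPON", 0.0, "non_food_pattern"),
        ("H2", "Produce", "produce party tray", "tray", "PRODUCE PARTY TRAY", 1.0, "produce_tray"),
        ("H2", "Produce", "produce party tray", "tray", "PRODUCE SNACK TRAY", 0.9, None),
        ("H2", "Deli", "deli party tray", "cold cuts", "CHEESE COLD CUT PARTY TRAY", 2.0, "deli_tray"),
        ("H2", "Deli", "deli party tray", "cold cuts", "DELI SNACK TRAY", 1.9, None),
        ("H2", "Beverages", "beer", "keg", "BEER KEG 15.5GAL", 160.0, "keg"),
        ("H2", "Grocery", "pasta", "spaghetti", "SPAGHETTI 1LB", 1.0, None),
        ("H9", "Produce", "berries", "berries", "STRAWBERRIES 1LB", 1.0, "head_age"),
        ("H9", "Meat", "chicken", "breast", "CHICKEN BREAST", 2.0, "head_age"),
    ]
    items = pd.DataFrame(
        rows,
        columns=[
            "household_id", "department", "category", "class",
            "item_description", "unit_weight_lb", "expected_rule",
        ],
    )
    items.insert(1, "transaction_id", [f"T{i}" for i in range(len(items))])
    items.insert(2, "date", "2016-05-10")
    items.insert(3, "store_id", 1)
    return hh, items
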