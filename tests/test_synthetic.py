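"""Generator determinism, marginal calibration and mean-model fidelity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from producetrends import (
    GeneratorConfig,
    TrueModelParams,
    default_truth,
    generate_households,
    generate_panel,
    generate_transactions,
    true_percent,
)
from producetrends.labels import CELLS, RAW_INCOME_LABELS
from producetrends.synthetic import ConfigError


def _flat_truth(p=0.2, s1=0.0, s2=0.0, slope=0.0, dispersion=1.0):
    b0 = float(logit(p))
    return TrueModelParams(
        intercept_by_cell={c: b0 for c in CELLS},
        seasonal_sin=s1,
        seasonal_cos=s2,
        slope_by_cell={c: slope for c in CELLS},
        dispersion=dispersion,
    )


class TestTruePercent:
    def test_all_zero_coefficients_give_half(self):
        params = _flat_truth(0.5)
        assert true_percent(params, CELLS[0], 1) == pytest.approx(0.5)

    def test_flat_intercept_is_inverse_logit_identity(self):
        params = _flat_truth(0.17)
        for t in (1, 7, 33):
            assert true_percent(params, ("35-54", ">=100K"), t) == pytest.approx(0.17)

    def test_hand_evaluated_harmonic(self):
        # direct evaluation of expit(b0 + 0.1 sin(2pi t/12) - 0.05 cos(2pi t/12) + m t) at t=6
        b0, m = logit(0.17), 0.001
        params = TrueModelParams(
            intercept_by_cell={c: float(b0) for c in CELLS},
            seasonal_sin=0.1,
            seasonal_cos=-0.05,
            slope_by_cell={c: m for c in CELLS},
        )
        t = 6
        expected = expit(
            b0 + 0.1 * math.sin(2 * math.pi * t / 12)
            - 0.05 * math.cos(2 * math.pi * t / 12) + m * t
        )
        assert true_percent(params, CELLS[0], t) == pytest.approx(float(expected), abs=1e-12)

    def test_unknown_cell_raises(self):
        with pytest.raises(KeyError):
            true_percent(default_truth(), ("18-24", "no-such-income"), 1)

    def test_month_below_one_rejected(self):
        with pytest.raises(ValueError):
            true_percent(default_truth(), CELLS[0], 0)


class TestConfigValidation:
    def test_bad_probability_vector(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(age_shares=(0.5, 0.1, 0.1, 0.1, 0.1, 0.2))

    def test_nonpositive_rates(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(visits_per_month=0.0)

    def test_dispersion_below_one(self):
        with pytest.raises(ConfigError):
            default_truth(dispersion=0.5)


class TestHouseholds:
    def test_determinism_same_seed(self):
        cfg = GeneratorConfig(n_households=200, seed=5)
        a, b = generate_households(cfg), generate_households(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_missing_rates_give_complete_table(self):
        cfg = GeneratorConfig(
            n_households=300,
            missing_rate_age=0.0,
            missing_rate_income=0.0,
            missing_rate_family=0.0,
            seed=3,
        )
        hh = generate_households(cfg)
        for col in ("age_group_raw", "income_group_raw", "family", "household_size"):
            assert (hh[col].astype(str) != "").all()

    def test_missingness_and_marginals_calibrated_at_large_n(self):
        cfg = GeneratorConfig(n_households=100_000, seed=17)
        hh = generate_households(cfg)
        n = len(hh)
        # binomial 3-sigma bounds
        miss_inc = (hh["income_group_raw"] == "").mean()
        assert abs(miss_inc - 0.09) < 3 * math.sqrt(0.09 * 0.91 / n)
        miss_age = (hh["age_group_raw"] == "").mean()
        assert abs(miss_age - 0.04) < 3 * math.sqrt(0.04 * 0.96 / n)
        fam = hh["family"] == ""
        size = hh["household_size"] == ""
        assert (fam == size).all()  # joint missingness of the family fields
        assert abs(fam.mean() - 0.15) < 3 * math.sqrt(0.15 * 0.85 / n)
        # demographic share calibration (observed, scaled by non-missing share)
        obs = hh.loc[hh["income_group_raw"] != "", "income_group_raw"].value_counts(
            normalize=True
        )
        for lab, share in zip(RAW_INCOME_LABELS, cfg.income_shares):
            assert abs(obs.get(lab, 0.0) - share) < 3 * math.sqrt(
                share * (1 - share) / n
            ) + 1e-3

    def test_over_age_households_present_at_configured_share(self):
        cfg = GeneratorConfig(n_households=50_000, seed=9)
        hh = generate_households(cfg)
        share = (hh["age_group_raw"] == "90-99").mean()
        assert abs(share - 0.016) < 3 * math.sqrt(0.016 * 0.984 / len(hh))


class TestTransactions:
    def test_determinism(self):
        cfg = GeneratorConfig(
            n_households=40, visits_per_month=2, items_per_visit=6, seed=2
        )
        hh = generate_households(cfg)
        pd.testing.assert_frame_equal(
            generate_transactions(hh, cfg), generate_transactions(hh, cfg)
        )

    def test_pooled_share_matches_flat_truth(self):
        cfg = GeneratorConfig(
            n_households=300,
            model_truth=_flat_truth(0.2),
            filter_target_share=0.0,
            duplicate_line_share=0.0,
            missing_rate_age=0.0,
            missing_rate_income=0.0,
            missing_rate_family=0.0,
            over_age_share=0.0,
            seed=8,
        )
        hh = generate_households(cfg)
        tx = generate_transactions(hh, cfg)
        from producetrends import classify_items

        items = classify_items(tx)
        share = items["is_produce"].mean()
        n = len(items)
        assert abs(share - 0.2) < 3 * math.sqrt(0.2 * 0.8 / n)

    def test_dates_within_study_window(self, transactions, small_config):
        d = pd.to_datetime(transactions["date"])
        start = pd.Timestamp(small_config.start_month + "-01")
        months = (d.dt.year - start.year) * 12 + d.dt.month - start.month + 1
        assert months.between(1, small_config.study_months).all()

    def test_zero_filter_share_emits_only_catalog_food(self):
        cfg = GeneratorConfig(
            n_households=50, filter_target_share=0.0, seed=4,
            visits_per_month=2, items_per_visit=8,
        )
        hh = generate_households(cfg)
        tx = generate_transactions(hh, cfg)
        assert not tx["department"].str.lower().isin(
            {"pharmacy", "general merchandise", "floral"}
        ).any()
        assert not tx["item_description"].str.contains("KEG|COUPON|PET FOOD").any()


class TestPanelGenerator:
    def test_zero_visit_months_have_no_row(self):
        cfg = GeneratorConfig(n_households=80, visits_per_month=0.3, seed=6)
        hh = generate_households(cfg)
        panel = generate_panel(hh, cfg)
        # With rate 0.3 most household-months are silent: far fewer rows than n*T
        assert len(panel) < 0.5 * 80 * cfg.study_months
        assert (panel["total"] >= 1).all()
        assert (panel["produce"] <= panel["total"]).all()

    def test_mean_model_fidelity_per_cell_month(self):
        truth = default_truth()
        cfg = GeneratorConfig(n_households=4000, model_truth=truth, seed=13)
        hh = generate_households(cfg)
        panel = generate_panel(hh, cfg)
        g = panel.groupby(["age_group", "income_group", "month"]).agg(
            y=("produce", "sum"), n=("total", "sum")
        )
        g = g[g["n"] > 5000]  # well-populated cells only
        for (a, i, t), row in g.iterrows():
            p = true_percent(truth, (a, i), int(t))
            se = math.sqrt(p * (1 - p) / row["n"])
            assert abs(row["y"] / row["n"] - p) < 4 * se

    def test_overdispersion_inflates_between_household_variance(self):
        base = GeneratorConfig(n_households=800, seed=21, model_truth=_flat_truth(0.2))
        over = GeneratorConfig(
            n_households=800, seed=21, model_truth=_flat_truth(0.2, dispersion=5.0)
        )
        hh = generate_households(base)
        v1 = (lambda p: (p["produce"] / p["total"]).var())(generate_panel(hh, base))
        v2 = (lambda p: (p["produce"] / p["total"]).var())(generate_panel(hh, over))
        assert v2 > 2 * v1
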