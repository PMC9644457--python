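"""GEE fit, sandwich covariance and outcome-scale contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from producetrends import (
    ModelSpec,
    annual_change_contrast,
    baseline_percent,
    build_design,
    design_row,
    fit_gee,
    sandwich_covariance,
    wald_ci,
)
from producetrends.labels import AGE_LABELS, CELLS, INCOME_LABELS

statsmodels = pytest.importorskip("statsmodels.api")


def _reference_fit(design):
    """Independent reference: grouped-binomial GLM with cluster-robust
    covariance, which coincides with working-independence GEE."""
    glm = statsmodels.GLM(
        np.column_stack([design.y, design.n - design.y]),
        design.X,
        family=statsmodels.families.Binomial(),
    )
    codes, _ = pd.factorize(design.clusters)
    return glm.fit(cov_type="cluster", cov_kwds={"groups": codes, "use_correction": False})


class TestDesign:
    @pytest.mark.parametrize(
        "t,sin_val,cos_val", [(3, 1.0, 0.0), (12, 0.0, 1.0), (6, 0.0, -1.0)]
    )
    def test_harmonic_terms(self, t, sin_val, cos_val):
        x = design_row(ModelSpec(grouping="none"), None, t)
        names = ["const", "sin", "cos", "t"]
        row = dict(zip(names, x))
        assert row["sin"] == pytest.approx(sin_val, abs=1e-12)
        assert row["cos"] == pytest.approx(cos_val, abs=1e-12)
        assert row["t"] == t

    def test_unit_circle_invariant(self, panel):
        d = build_design(panel, ModelSpec(grouping="age"))
        s, c = d.X[:, d.names.index("sin")], d.X[:, d.names.index("cos")]
        np.testing.assert_allclose(s**2 + c**2, 1.0, atol=1e-12)

    def test_column_count_full_interaction(self, panel):
        # const + sin + cos + t + (4 age + 5 income + 20 products) mains
        # + the same 29 group-by-time products = 62
        d = build_design(panel, ModelSpec(grouping="age_by_income"))
        assert len(d.names) == 62

    def test_indicators_sum_to_at_most_one(self, panel):
        d = build_design(panel, ModelSpec(grouping="age"))
        main = [i for i, nm in enumerate(d.names) if nm.startswith("age[") and not nm.endswith(":t")]
        sums = d.X[:, main].sum(axis=1)
        assert set(np.unique(sums)) <= {0.0, 1.0}

    def test_unseen_label_rejected(self, panel):
        bad = panel.copy()
        bad.loc[bad.index[0], "age_group"] = "105-110"
        with pytest.raises(ValueError, match="age labels"):
            build_design(bad, ModelSpec(grouping="age"))


class TestFit:
    def test_intercept_only_equals_pooled_logit(self, panel):
        spec = ModelSpec(grouping="none", include_seasonal=False)
        d = build_design(panel, spec)
        d.X = d.X[:, :1]
        d.names = ["const"]
        fit = fit_gee(d)
        pooled = panel["produce"].sum() / panel["total"].sum()
        assert fit.params[0] == pytest.approx(float(logit(pooled)), abs=1e-12)

    @pytest.mark.parametrize("grouping", ["none", "age", "income"])
    def test_matches_reference_implementation(self, panel, grouping):
        d = build_design(panel, ModelSpec(grouping=grouping))
        fit = fit_gee(d)
        ref = _reference_fit(d)
        np.testing.assert_allclose(fit.params, ref.params, rtol=1e-6)
        np.testing.assert_allclose(fit.cov, ref.cov_params(), rtol=1e-6)

    def test_covariance_symmetric_psd(self, panel):
        fit = fit_gee(build_design(panel, ModelSpec(grouping="age")))
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-12)
        assert np.all(np.diag(fit.cov) >= 0)

    def test_all_zero_response_flags_separation(self, panel):
        degenerate = panel.copy()
        degenerate["produce"] = 0
        fit = fit_gee(build_design(degenerate, ModelSpec(grouping="none")))
        assert fit.separation and not fit.converged

    def test_robust_close_to_model_based_with_independent_clusters(self):
        # one observation per cluster, correctly specified binomial:
        # the sandwich and model-based SEs agree asymptotically
        rng = np.random.default_rng(3)
        n_obs = 20_000
        t = rng.integers(1, 34, size=n_obs)
        eta = -1.6 + 0.002 * t
        n = rng.poisson(60, size=n_obs) + 1
        y = rng.binomial(n, expit(eta))
        panel = pd.DataFrame(
            {
                "household_id": np.arange(n_obs),
                "month": t,
                "produce": y,
                "total": n,
            }
        )
        fit = fit_gee(build_design(panel, ModelSpec(grouping="none", include_seasonal=False)))
        robust = np.sqrt(np.diag(fit.cov))
        model = np.sqrt(np.diag(fit.model_cov))
        np.testing.assert_allclose(robust, model, rtol=0.05)


class TestContrasts:
    def test_all_zero_coefficients_give_50_percent(self, panel):
        fit = fit_gee(build_design(panel, ModelSpec(grouping="none")))
        fit.params[:] = 0.0
        fit.cov[:] = 0.0
        res = baseline_percent(fit)
        assert res.estimate == pytest.approx(50.0)

    def test_zero_slope_gives_zero_annual_change(self, panel):
        fit = fit_gee(build_design(panel, ModelSpec(grouping="none")))
        fit.params[fit.names.index("t")] = 0.0
        res = annual_change_contrast(fit)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.ci_low == pytest.approx(-res.ci_high, rel=1e-6) or res.se == 0

    def test_monotone_in_slope(self, panel):
        fit = fit_gee(build_design(panel, ModelSpec(grouping="none")))
        idx = fit.names.index("t")
        changes = []
        for slope in (0.0005, 0.001, 0.002):
            fit.params[idx] = slope
            changes.append(annual_change_contrast(fit).estimate)
        assert changes == sorted(changes) and changes[0] < changes[-1]

    def test_time_origin_shift_leaves_annual_change_invariant(self, medium_panel):
        spec = ModelSpec(grouping="age")
        fit1 = fit_gee(build_design(medium_panel, spec))
        shifted = medium_panel.copy()
        shifted["month"] = shifted["month"] + 12  # same calendar phase, new origin
        fit2 = fit_gee(build_design(shifted, spec))
        for a in AGE_LABELS:
            c1 = annual_change_contrast(fit1, a)
            # anchor midpoints differ by the shift; compare slopes via the
            # invariance of the per-month logit slope contrast
            s1 = fit1.params @ (
                design_row(spec, a, 1.0, seasonal=False)
                - design_row(spec, a, 0.0, seasonal=False)
            )
            s2 = fit2.params @ (
                design_row(spec, a, 1.0, seasonal=False)
                - design_row(spec, a, 0.0, seasonal=False)
            )
            assert s1 == pytest.approx(s2, abs=1e-6)
            assert abs(c1.estimate) < 5  # sanity: percent-per-year scale

    def test_cell_absent_from_model_raises(self, panel):
        fit = fit_gee(build_design(panel, ModelSpec(grouping="age")))
        with pytest.raises(KeyError):
            baseline_percent(fit, "not-an-age")

    def test_formatting_matches_reporting_style(self):
        from producetrends.gee import ContrastResult

        res = ContrastResult("18-24 x 0-14.9K", "baseline_percent", 12.2, 11.1, 13.3, 0.561)
        assert str(res) == "12.2% (CI 11.1; 13.3)"


class TestWaldCI:
    def test_standard_normal_quantile(self):
        assert wald_ci(0.0, 1.0) == pytest.approx((-1.959964, 1.959964))

    def test_zero_se_degenerate(self):
        assert wald_ci(5.0, 0.0) == (5.0, 5.0)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0.0, -1.0)

    def test_backsolves_published_interval_width(self):
        lo, hi = wald_ci(12.2, 0.561)
        assert (round(lo, 1), round(hi, 1)) == (11.1, 13.3)
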