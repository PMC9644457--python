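"""Fit the seasonal + linear produce-purchasing trend model.

Simulates a cohort of loyalty-card households under the default
calibration, builds the household-month binomial panel directly, fits the
working-independence GEE stratified by age group, and prints each group's
baseline percent produce purchased (January 2016, seasonal included) and
its average annual change, both with cluster-robust 95% CIs.
"""

from producetrends import (
    GeneratorConfig,
    ModelSpec,
    annual_change_contrast,
    baseline_percent,
    build_design,
    fit_gee,
    generate_households,
    generate_panel,
    grand_mean,
)
from producetrends.labels import AGE_LABELS

cfg = GeneratorConfig(n_households=3000, seed=1)
households = generate_households(cfg)
panel = generate_panel(households, cfg)
print(f"panel: {len(panel)} household-months from {panel['household_id'].nunique()} households")
print(f"grand mean percent produce purchased: {100 * grand_mean(panel):.1f}%\n")

fit = fit_gee(build_design(panel, ModelSpec(grouping="age")))
print(f"GEE converged in {fit.iterations} iterations ({fit.n_clusters} household clusters)\n")
print(f"{'age group':>10}  {'baseline':>22}  {'annual change':>22}")
for age in AGE_LABELS:
    b = baseline_percent(fit, age)
    c = annual_change_contrast(fit, age)
    print(f"{age:>10}  {str(b):>22}  {str(c):>22}")

print(
    "\nBaseline is the expected percent of food items that are fresh produce"
    "\nas of January 2016; annual change is the per-year difference in that"
    "\npercent after removing seasonality. The youngest households trend up"
    "\nfastest; the oldest barely change."
)
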