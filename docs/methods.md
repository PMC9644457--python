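# Methods

## The statistical model

The analysis unit is the household-month. For household *i* in study
month *t* (an integer 1..T, T = 33 by default, with t = 1 mapped to
January 2016), Y_it counts fresh produce items out of n_it food items and
is modelled marginally as grouped-binomial with

    logit E[Y_it / n_it] = b0 + bS1 sin(2πt/12) + bS2 cos(2πt/12) + bL t
                           + bX X_i + bXL (X_i × t)

The two harmonics encode a single annual cycle (period fixed at 12
months); bL is a linear secular trend on the logit scale; X_i are dummy
indicators for the demographic grouping (five collapsed age groups, six
collapsed income groups, or the full 5 × 6 interaction), coded against
reference levels 18–24 and 0–14.9K. Results are always re-expressed per
cell, so the reference choice is inert. The full-interaction model has 62
columns: intercept, two harmonics, time, 29 group terms (4 age + 5
income + 20 products) and the same 29 crossed with time.

Estimation is by generalized estimating equations under a working
independence correlation. In that case the estimating equations coincide
with the weighted-logistic normal equations (weights n_it, outcomes
Y_it/n_it) and are solved by iteratively reweighted least squares. The
fit is therefore deterministic; convergence is declared when the
maximum absolute coefficient change, relative to the largest current
coefficient, falls below 1e-8 (cap: 100 iterations). Degenerate
responses (all-zero or all-n produce counts) and diverging linear
predictors (|eta| > 30) are flagged as separation; the partial estimate
is returned unfitted for inference rather than raised, so pipelines can
report the failure.

Inference uses the cluster-robust empirical sandwich covariance
A⁻¹ B A⁻¹, where A = X'WX is the working-model information
(W = n·mu·(1−mu)) and B sums, over household clusters, the outer products
of cluster score contributions X_c'(y_c − n_c·mu_c). No small-sample
correction is applied: the intended regime has thousands of household
clusters, where such corrections are negligible. The estimator was
verified in the test suite against an independent reference (a grouped
binomial GLM with cluster-robust covariance, which is algebraically
identical under working independence) to ≤ 1e-6 relative error.

### Outcome-scale contrasts

Two derived quantities are reported per demographic cell, both with
delta-method 95% Wald intervals (z = 1.959964) using the robust
covariance:

* **Baseline percent** — 100·expit(eta) at t = 1 *with seasonal terms
  included*: "baseline" names a calendar instant (January 2016), not a
  deseasonalised level. A flag computes the seasonal-free variant.
* **Annual change in percent produce purchased** — the cell's per-month
  logit slope is the derivative of the linear predictor in t (extracted
  as a contrast: the design row at t = 1 minus the row at t = 0, seasonal
  zeroed); it is rescaled to a percent-per-year quantity as
  100·[expit(eta0 + 12·m) − expit(eta0)], with eta0 the seasonal-free
  predictor at the window midpoint t = (1 + T)/2. A logit slope has no
  unique percent-scale counterpart because expit is nonlinear; anchoring
  the 12-month difference at the midpoint makes the quantity symmetric in
  the window and reduces to 1200·m·p(1−p) for small slopes. The
  definition is isolated in one function so an alternative rescaling can
  be substituted.

The midpoint anchor makes the annual change invariant to shifting the
time origin (only the intercept absorbs the shift); this is tested
numerically.

## Descriptive series

Monthly descriptive curves are item-weighted means of household produce
proportions (weight = the household's food-item count that month), which
algebraically equal the pooled proportion ΣY/Σn per month and group —
weighting by items is what controls for family size. The 95% interval
uses a design-based between-household variance,
Var = Σ w_i²(p_i − p̄)² / (Σ w_i)², treating the household as the sampling
unit; the construction of the interval is this package's choice, made
because a weighted mean of correlated within-household counts has no
canonical binomial interval. The grand mean is ΣY/Σn over all rows.

## Cohort and counting rules

* Non-food departments (pharmacy, general merchandise, floral, health
  and beauty — configurable) and explicit non-food item patterns (candy
  moulds/making supplies, pet food, coupons) are removed.
* Items not for everyday consumption are removed: produce party trays at
  or above 1 lb, cheese/cold-cut party trays at or above 2 lb, beer
  kegs. Thresholds are inclusive.
* Households headed by someone 90 or older are removed entirely.
* Removal attributes each item to the **first** matching rule in a fixed
  order, so the removal log partitions the removals exactly; the filter
  is idempotent.
* An item is **fresh produce** iff its department is produce and its
  category is one of 13 fresh categories (summer fruit, berries, grapes,
  seasonal/specialty, apples and pears, salad vegetables, citrus,
  tropical fruit, bananas, melons, potatoes and onions, cooking
  vegetables, salad leaf). Frozen, dried, canned and juice items in the
  produce department stay in the food denominator but never in the
  numerator.
* Items are counted once per unique (transaction, description, class)
  line regardless of quantity — the outcome is a purchase frequency.
* The modelling cohort is complete-case on age group, income group and
  household size. A missing family (yes/no) flag alone does not exclude
  a household: it is descriptive only, which is why the three
  descriptive tables carry different totals.
* Raw strata are collapsed deterministically: six raw age groups to five
  (35–44.9 and 45–54.9 merge) and nine raw income groups to six; a
  further collapse to five income levels aligns with the ACS county
  table.

The 33-month window is kept as configured even though January 2016 to
October 2018 inclusive spans 34 calendar months; the window end is a
parameter and T = 33 is the default rather than a re-interpretation.

## The synthetic generator

The generator emulates the study conditions so that every downstream
stage can be tested against a known truth:

* **Demographics.** Raw age shares (2.8, 14.2, 17.5, 17.6, 36.8, 11.1%)
  and raw income shares (5.9, 3.9, 6.0, 9.3, 10.0, 27.9, 16.3, 12.0,
  8.7%) are chosen so the collapsed margins match the published county
  tables; the published tables only print collapsed margins, so the
  within-collapse splits are this package's choice. An extra 1.6% of
  households get a 90–99 head-age label so the age exclusion is
  exercisable. Household size shares follow the published size margins;
  49.6% of households are families. Age and income are drawn
  independently — the published table shows mild dependence, but the
  joint structure of the *outcome* lives entirely in the per-cell model
  parameters, so model recovery is unaffected.
* **Missingness.** Independent per field family: 4% age, 9% income, 15%
  family-and-size (one mask for both, as both stem from the same
  commercial enrichment). Only marginal rates are published; joint
  independence across field families is an assumption.
* **Visits and baskets.** Visits per household-month are Poisson(5),
  consistent with the published median of about five store visits per
  month; baskets hold 1 + Poisson(19) items (about 100 food items per
  household-month, a plausible full-shop scale — no basket size is
  published). Months with zero visits produce no panel row.
* **Outcome truth.** Per-cell January-2016 baseline percents come from
  an additive age × income grid (age mains 13.5/15.6/15.0/16.3/16.8,
  income mains 13.9–17.1, the two extreme corners pinned at 12.2% and
  19.3%), reflecting the published pattern: produce share rises with
  income, rises non-monotonically with age, and 25–34 sits above both
  neighbours. Seasonal amplitude is 0.09 on the logit scale peaking in
  May (bS1 = 0.09·sin(2π·5/12), bS2 = 0.09·cos(2π·5/12)), giving a
  peak-to-trough swing of about 2.5 percentage points at p ≈ 0.17 —
  inside the published 2–3 point band, peaking in the April–July
  window. Annual-change targets run from 1.42 %/yr (youngest, lowest
  income) across 1.30/1.15/1.00/0.85 to 0.69 %/yr within the youngest
  row, then 0.45/0.35/0.25 %/yr for the middle rows and 0.03 %/yr for
  the oldest. Each target is converted to a per-month logit slope by a
  small fixed-point solve so that the generating truth's annual change,
  *by the package's own midpoint-anchored definition*, equals the target
  exactly while the January-2016 percent stays anchored at the cell
  baseline. The population-weighted grand mean implied by this
  calibration is about 17%.
* **Overdispersion.** Optionally, the per-household-month success
  probability is drawn from a Beta with mean p and concentration
  (m − d)/(d − 1) at mean monthly item count m, inflating Var(Y) by
  about the factor d relative to binomial. The default d = 1 keeps the
  exact binomial regime so oracle tests are clean.
* **Streams.** The household table and the transaction/panel draws use
  two independent streams spawned from the master seed, so regenerating
  one table does not perturb the other. Identical config + seed gives
  byte-identical tables.
* **Two granularities.** `generate_transactions` emits item-level
  records whose descriptions carry a within-transaction slot suffix
  (distinct items never collide) plus a configurable share of exactly
  duplicated lines, so unique-item counting is exercised without biasing
  the binomial structure; it also mixes in a configurable share of
  filter-target products covering every exclusion rule, including
  sub-threshold trays that must be *retained*. `generate_panel` draws
  household-month (Y, n) pairs directly from the same mean model for
  simulation studies where item-level detail is irrelevant.

What the generator does **not** emulate: prices and spending, brand-level
assortment, day-of-week structure, correlation between demographics and
visit frequency, informatively missing timepoints, and any
demographic-outcome dependence beyond the cell means. Passing tests
therefore show that the pipeline recovers the assumed data-generating
process, not that the published estimates are correct for the real
proprietary data — those printed, data-dependent values (e.g. a 12.2%
baseline in one cell) are not reproducible without the data, and the
default calibration merely places the truth near them.

## Problem sizes and numerical choices

Simulation tests use sizes chosen to keep Monte-Carlo error well inside
the asserted tolerances: marginal calibration at 10^5 households with 3σ
binomial bounds; oracle equivalence on a fixed 500-household panel;
parameter recovery over 600 replicates of 1,000 households (coverage of a
95% interval is then estimated to within about one percentage point);
seasonal-shape checks at 3,000 households; the acceptance script
simulates 50,000 households so the rarest cell (youngest age, lowest
income — about 0.17% of households before complete-case losses) still
holds roughly 60 households. Percentages in the descriptive tables are
rounded half-away-from-zero at one decimal, matching how the published
tables print; the chi-square treats loyalty and county sources as
independent samples, an acknowledged approximation since loyalty
households are a subset of the county.

## Known limitations

* Only the independence working correlation is implemented; inference is
  robust to that choice, efficiency is not.
* The percent-per-year rescaling is one of several defensible
  definitions of a percent-scale slope; see above.
* The design-based CI for the monthly weighted mean ignores within-
  household binomial sampling noise, which is negligible whenever
  households purchase more than a handful of items but not for very
  sparse months.
* No adjustment weights the loyalty sample toward census margins; the
  representativeness module only quantifies the discrepancy.
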