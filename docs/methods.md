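# Methods

## Scope and model structure

The package estimates the short-term economic burden of low birth
weight (LBW, < 2.5 kg; VLBW, ≤ 1.5 kg) for a reference cohort of 1000
live births in a rural district of Southern Mozambique with 12% LBW and
1% VLBW prevalence.  Three engines share one probabilistic-sensitivity-
analysis (PSA) core:

1. an eight-component health-system cost model (supplementation,
   incremental post-delivery admission, referral transport and
   admission, weighing visits, excess first-year admissions,
   kangaroo-mother-care training);
2. a household cost model for routine care and excess admissions, split
   into direct and indirect costs;
3. an age-weighted, discounted DALY engine for LBW-attributable infant
   deaths and transient neonatal morbidity.

Every uncertain input is a declarative distribution (point, triangular
`low/mode/high`, or uniform).  Inputs are sampled independently — no
correlation structure is modelled — and each model input draws from its
own child random stream derived deterministically from the root seed and
the input's name, so adding or removing a component never perturbs the
draws of another.  Simulated quantities are reported as the mean with an
empirical 95% interval (2.5th/97.5th percentiles, linear interpolation);
how the original study computed its intervals is unstated, so the
percentile convention — standard PSA practice — is a package choice, not
an inference.  The default draw count is 10,000 (< 1 s per model on one
CPU); the degenerate all-point configuration short-circuits to exact
constants so deterministic runs report zero interval width.

## Health-system cost model

Per draw, the LBW count is `1000 × p_LBW` with
`p_LBW ~ Triangular(0.10, 0.12, 0.14)`; baby counts stay fractional
(expected-value semantics) rather than being integerised.  Component
formulas and the distributions behind them follow the published input
tables: e.g. multivitamins are `n_LBW × 90 days ×
Triangular(0.0018, 0.0044, 0.0777) US$`, incremental post-delivery
admission is `n_LBW × max(U(2,4) − 1, 0) × 17.28 US$` — one night is
attributed to the delivery itself, not to LBW — and referral admission
is `33 × U(14,21) × 51.84 US$`.  The total is the per-draw sum of the
eight components, so additivity holds draw by draw, not only in the
means.

Choices where the published inputs underdetermine the model:

* **Transfers (33/1000) and excess-admission babies (112/1000).**  Both
  counts are implied exactly by the published component arithmetic
  (33 × 17.5 × 51.84 and 112 × 6 × 17.28) and are consistent with the
  stated transfer policy (all 10 VLBW plus ≈30% of the 1.5–2.0 kg band)
  and with one excess admission per LBW baby surviving the neonatal
  period (120 − 8).  Both are configurable.
* **Transport to the referral hospital.**  The itemised ingredients
  (3 h of a driver at 0.27 US$/h plus fuel for 80 km) come to roughly
  10 US$ per transfer — far below the ≈147.56 US$/transfer implied by
  the published component total.  The component therefore uses an
  explicit all-inclusive per-transfer cost (default 147.56 US$,
  covering vehicle, staff and overheads) while the bare ingredient
  estimate is computed and reported alongside for transparency.
* **Iron supplementation.**  The unit price is sampled from its full
  triangular distribution like every other input, giving a mean
  component of ≈23.0 US$; the published 19.52 US$ matches a
  mode-only calculation instead.  The distribution-based value is
  reported; no attempt is made to match the mode-only figure.
* **Kangaroo-mother-care training.**  Recipients default to 50% of LBW
  babies (the published "proportion with the need"); training time is
  `Triangular(5, 7, 15)` minutes of nurse time at 0.03375 US$/min.
* **Exchange-rate uncertainty.**  All inputs are already in US$; a
  multiplicative exchange-rate distribution is supported but defaults
  to a point mass at 1 because no parameters for it were published.

Population scaling (e.g. to the 3,322 live births of 2007) is linear in
cohort size.  Per-baby averages divide the simulated total by the
best-estimate LBW count (120); the non-LBW comparator is one
post-delivery bed-day plus an average admission episode
(17.28 × (1+6) = 120.96 US$).

## Weighing-visit schedule

Follow-up of an LBW infant requires one weighing visit per week until
the weight reaches 2.5 kg.  The visit count simulates the weekly weight
trajectory: each week the infant gains 7 × the daily rate of its current
weight band, and the first visit at which 2.5 kg has been reached is
still counted (the confirmatory visit); infants born at ≥ 2.5 kg need
none.  This rule is monotone non-increasing in both birth weight and
daily gain.

The daily-gain table is a replaceable placeholder: the growth reference
the study used is not reproduced here.  Defaults of 17 g/day below 2 kg
and 21 g/day at 2–2.5 kg lie in the range reported for LBW infants and
were calibrated once so that, over the study-like birth-weight
distribution (mean 2.26 kg), the implied mean schedule matches the
observed average of ~2.1 weighing visits per baby.  The published
routine-visit component (49.71 US$) implies ≈2.45 visits per baby — more
than its own reported sample mean of 2.13 — and is not targeted; the
model reproduces the observed visit count, leaving this component a few
US$ below the published figure (immaterial against the total).  Gain
uncertainty enters as a single ±25% triangular scale factor on the
table; the per-draw mean visit count is evaluated over a fixed panel of
representative LBW birth weights (default 200, truncated normal with
realised mean 2260 g, SD 200 g on (1000, 2500)).

## Household cost model

Each surveyed record carries direct costs (transport, food/phone,
accommodation, a fixed 0.15 US$ user fee) and indirect costs: wage
earners report income losses directly; housewives' time is valued at the
statutory minimum monthly wage (37 US$) over 208 working hours/month
(48 h-week convention — the study states no conversion, so this is a
package choice).  Outpatient attendance showed no significant LBW
excess, so outpatient costs are excluded by default
(`include_outpatient=False`).

Uncertainty uses the ±25% triangular rule applied per record (direct and
indirect parts perturbed separately so `total = direct + indirect` holds
in every draw); applying it to the cohort mean instead is configurable.
The triangular perturbation is mean-preserving, so the simulated mean
estimates the sample mean while the interval reflects both the rule and
the cohort size.  The admission model additionally reports the indirect
share of the total.

## DALY engine

YLL for a death at age `a` integrates the discounted (rate `r`),
age-weighted life-years over the residual life expectancy `L`:

    YLL(a) = ∫_a^{a+L} [K·C·x·e^{−βx} + (1−K)]·e^{−r(x−a)} dx

evaluated in closed form (the `r = 0` and `K = 0` limits analytically,
never by division by zero), and verified against numerical integration
to < 10⁻⁶ relative error.  The age-weighting constants
(C = 0.1658, β = 0.04, K = 1) are the standard global-burden values —
they are not printed in the study but `yll(0) = 32.17` reproduces its
VLBW figure (257.44 / 8 deaths = 32.18), confirming the choice; all are
overridable.  YLD applies the disability weight (0.256) to the same
discounted, age-weighted stream over a stochastic episode duration
(uniform 2–21 days) from the onset age; recipients default to all LBW
newborns (≈0.005 DALY per 1000 births — immaterial, configurable to
survivors only).

Death counts per 1000 births (8 of 10 VLBW, 17 of 110 other LBW, all at
age 0 by default) are direct inputs: 17 does not follow from the 12%
case-fatality rate (110 × 0.12 = 13.2) and the study does not say how it
was constructed.  With these inputs the engine yields 804.2 DALYs per
1000 births, ~3% below the published 826.63; the gap would close if the
non-VLBW deaths carried a later mean age at death or extra YLD, but
since the study is silent the discrepancy is documented rather than
calibrated away.  Published-total arithmetic (826.63 × 3.322 = 2746.06)
is kept as a data-consistency check on the benchmark constants, separate
from the engine's own output.

## Regressions

The log-linear model regresses `log(total household cost)` on birth
weight **in kg** by OLS: the reported slope −5.30 is only dimensionally
consistent with kg (a per-gram slope would annihilate costs within
grams), even though the study describes weight "in grams".  Zero-cost
records cannot be log-transformed and are dropped with a warning
(negative costs are an error); the study's minimum observed cost was
0.19 US$, so its data had none.  The effect of +100 g is reported both
ways: the linear log-scale reading (−0.53 → 53%) that matches the
published claim, and the exact multiplicative effect
(1 − e^{−0.53} = 41%); neither is silently corrected.

The admission model is a Poisson GLM with log link on an LBW indicator,
exposure fixed at one infant-year per child (no person-time was
published, so deaths' partial exposure is ignored — consistent with the
generator, whose death flags do not truncate admission counts).  With a
single binary covariate the model is saturated: the fitted rate ratio
equals the ratio of group sample means, which the tests verify to 10⁻⁸
against the closed form.

## Synthetic data generator

The generator emulates the study conditions: 87 routine-care and 46
admission-arm exit interviews (generated independently; any overlap in
the original arms is unstated), and a 990-infant follow-up cohort with
117 LBW.  Birth weights are truncated normal on (1000, 2500) g with the
location solved numerically so the *realised* mean is 2260 g (naive
truncation at the 2.5 kg cutoff would bias the mean ~44 g low); the SD
(200 g) is a free calibration default — only the mean was reported.
Routine-arm totals follow `exp(13.58 − 5.30·w_kg + ε)`,
`ε ~ N(0, 1)`; the noise SD is a free default chosen so the generated
mean/median ratio is strongly right-skewed like the reported
distribution (mean 23.04 vs median 4.06 US$).  One VLBW record per
87 interviews (matching the observed frequency) produces a
referral-scale high-cost outlier of order a few hundred US$; its cost
breakdown is not claimed.  Admission-arm totals are Gamma(shape 2) with
mean 8.50 US$ and a Beta-distributed indirect share with mean 0.75.
Occupations are 84% housewife; indirect costs are encoded as hours lost
(housewives) or reported income losses (wage earners) so the household
model reconstructs exactly the generated totals.  Cohort admissions are
Poisson with baseline 0.235/infant-year and rate ratio 1.52 for LBW;
death flags use the 80%/12% case-fatality rates (background non-LBW
mortality is not modelled — it cancels from every incremental quantity).

What the generator does **not** emulate: the real joint distribution of
cost items, geographic/seasonal structure, correlation between weight
and occupation, or measurement error in reported costs.  Passing
recovery tests therefore shows the estimators are consistent under the
assumed data-generating process, not that the original survey data would
reproduce the published household means.

## Numerical and testing choices

* Reproducibility: one root seed per run; per-component child seeds via
  a CRC32 hash of the component name (always < 2³¹); identical config +
  seed gives byte-identical CSV output.
* Percentiles use the `a + (b−a)·g` interpolation form so constant draw
  vectors summarise bit-exactly to the constant.
* Parameter-recovery tests run 200 replicates and require ≥ 90% CI
  coverage of the generating slope and rate ratio (nominal 95%, binomial
  noise allowed for).
* Problem sizes: reporting runs use 10,000 draws; the per-LBW-baby
  rounding check uses 100,000 draws with a 500-weight visit panel
  because the expected value (424.6 US$) sits ≈0.1 US$ above the 424.5
  rounding boundary and needs the Monte Carlo error pushed well below
  that margin.

## Known limitations

* Short-term burden only: no long-term disability, educational or
  productivity losses, and no full life tables (a single scalar life
  expectancy).
* Inputs are treated as independent; no variance-based sensitivity
  indices are computed.
* The health-system model is an expected-value cohort model, not a
  patient-level microsimulation; there are no capacity constraints.
* The household means reported by the original survey (24.12/23.04,
  median 4.06, admission 8.50 US$) are functions of unpublished
  microdata; the package covers them by generator-calibration recovery
  tests, not by reproduction.
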