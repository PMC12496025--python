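# Methods

This note documents the models implemented in `carebundle`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot establish.

## 1. Provider decision model

A provider treating identical patients can deliver two costly care processes.
Costs are `c1 >= k1`, `c2 >= k2`, and joint provision enjoys a synergy
`s >= 0`, so `c12 = c1 + c2 - s`. Under a **bundled** scheme the funder pays
`P` only when both processes are delivered (support assumption
`P > k1 + k2`); under an **itemized** scheme each process earns its own price
(`p1 > k1`, `p2 > k2`). Providers maximise profit:

- bundled: deliver both iff `P > c12`, otherwise nothing — partial provision
  earns nothing and is never chosen on financial grounds;
- itemized: profit argmax over {none, only 1, only 2, both}, which off
  boundaries reduces to the familiar half-plane rules (only 1 iff `c1 < p1`
  and `c2 > p2 + s`; both iff `c1 < p1 + s`, `c2 < p2 + s`,
  `p1 + p2 + s - c1 - c2 > 0`; symmetrically for only 2).

**Ties.** The model is silent on indifference (profit exactly zero or equal
profits). We resolve ties to the lower-effort option (none > only 1 >
only 2 > both), consistent with the strict inequalities of the decision
rules; cost draws landing exactly on a boundary in the region classifier are
labelled `degenerate` rather than assigned arbitrarily, which keeps the
partition property exactly testable.

**Scheme comparison.** At `P = p1 + p2` the cost plane partitions into
regions A/B (both under bundling, one process under itemization), C/D
(nothing under bundling, one process under itemization) and the agreement
cells. Two useful exact results back the Monte Carlo: (i) itemized joint
provision is nested in bundled joint provision whenever `s >= 0`; (ii) for
independent uniform costs every region is a polygon, and
`region_area_uniform` computes its measure by clipping half-planes against
the support rectangle (shapely), giving a closed-form oracle for
`simulate_population`.

**Welfare special case.** With equal mass in A and C, equal mass in B and D,
and the symmetric configuration `p1 = p2`, funder spending is identical
under the two schemes; total patient benefit is identical iff
`b12 = b1 + b2` and strictly higher under bundling iff `b12 > b1 + b2`. The
equal-mass construction is realised exactly with a finite-support ("points")
population, so the spending identity is checked to machine tolerance rather
than Monte Carlo error. (Note that equal region masses alone do not equalise
spending: bundled spending is `(p1+p2)(mA+mB)` against itemized
`2 p1 mA + 2 p2 mB`, so either `p1 = p2` or `mA = mB` is additionally
required.)

Sampling families: independent uniform (truncated above, since the model's
nominal support is unbounded), independent shifted lognormal, a Gaussian
copula coupling of those marginals, and the exact finite-support family.

## 2. Synthetic audit cohort

The generator emulates the structure of the national hip-fracture audit for
England (treated) and Wales (control), April 2008 - March 2015: patient-level
categorical case-mix (age band, sex, admission source, ASA grade,
pre-fracture mobility, fracture type), hospital membership in a growing
panel (105 to 165 hospitals in England, 5 to 13 in Wales, linear
interpolation; early joiners persist), monthly admission dates uniform
within financial year, and eight binary care-process indicators
(bpt1-bpt4, bpt6-bpt9; bpt5 is excluded from all analyses as it was not
collected before April 2011).

**Correlated indicators.** Criterion indicators are generated from a
one-factor Gaussian copula. The latent score of patient *i* in hospital *h*
on criterion *j* is

    L_ijh = sqrt(a) U_h + sqrt(r - a) Z_i + sqrt(1 - r) E_ij,

with criterion *j* achieved iff `L_ijh < Phi^{-1}(p_j)`; `p_j` is the
published achievement proportion for that country, financial year and
criterion, so every marginal is matched by construction. `U_h` is a
persistent scalar hospital intercept with variance share `a` (default
0.03), shared across criteria and years; it induces within-hospital
clustering that the hospital fixed effect absorbs in estimation.

**Bundle-level calibration.** The within-patient equicorrelation `r` is not
a free parameter by default: per (country, year) cell it is solved by
Brent's method so that the model-implied probability of achieving *all*
criteria in the era-specific bundle (seven criteria before April 2012,
eight from April 2012 when the pre-operative cognitive assessment joined
the payment rule) equals the published all-criteria proportion. The joint
orthant probability is computed by 80-node Gauss-Hermite quadrature. The
achievable range is `[product of marginals, min marginal)`; two Wales cells
(2013, 2014) print bundle proportions slightly below the independence
product (by at most 0.7 pp) and are clamped at `r = 0`, as negative
dependence is not representable in a one-factor model. Fixed correlations
(scalar or per cell) can be supplied instead, e.g. `r = 0` for
independence designs.

**Missingness.** The audit records age, sex and fracture type for all
patients; admission source, ASA and mobility can be "unknown". Each of
those three fields is masked independently, completely at random, at the
per-field rate that makes the *row-level* any-masked share equal the
published exclusion shares (17.5% England, 18.8% Wales). Criterion
indicators are never masked: the audit codes unachieved criteria as
missing, and the analysis codes missing as zero, so indicator missingness
is achievement failure, not missing data.

**Cohort sizes.** Patients per country-year are exact cell totals,
allocated to active hospitals by a gamma-weight multinomial (shape 5),
giving overdispersed, negative-binomial-like cluster sizes with exact cell
totals. Defaults are 12,000 England / 3,000 Wales per year (about 105,000
patients) — roughly one third of the real register, with the control
country oversampled relative to its true 5% share to stabilise the
control-group means. Calibrated reproduction runs (acceptance script and
acceptance tests) use 15,000 per country-year (210,000 patients), chosen so
Monte Carlo error (≈0.5 pp on the headline contrast) is small against the
±3 pp reproduction tolerance; the full pipeline at that size runs in
seconds.

**What the generator does not model.** Mortality, length of stay, costs,
seasonality (hooks exist, default off), case-mix gradients in achievement
(the published covariate coefficients are small; covariates are drawn
independently of the indicators by default), within-year trends (all
months of a financial year share the year's calibration cell), and any
real hospital-identity structure beyond printed counts. Passing tests
therefore validate the estimation machinery and the calibration logic, not
distributional fidelity to restricted patient records.

## 3. Estimation

`FixedEffectsLPM` is ordinary least squares on within-hospital-demeaned
data (the fixed effect absorbed by demeaning, equivalent to explicit
hospital dummies — verified to 1e-8 in tests), with the cluster-robust
sandwich covariance assembled hospital by hospital. Defaults, chosen where
the published analysis states only "clustered at the hospital level":

- **CR1 small-sample factor** `G/(G-1) * (N-1)/(N-K)`, with `K` counting
  regressors plus absorbed intercepts (the convention of the common
  absorbing-regression tools); CR0 is available behind a flag and equals
  HC0 when every cluster is a singleton.
- **t inference with G−1 degrees of freedom** (Wales contributes as few as
  5-13 clusters); joint Wald tests report both the chi-square p-value and
  an F version (`W/q` against `F(q, G-1)`), the latter used for size
  simulations.
- Singleton hospitals are retained (they contribute no within-variation
  but count toward N); their number is reported.
- Rank deficiency after demeaning raises an error naming the collinear
  columns rather than silently dropping them.

**Specifications.** The average-effect model enters the England × post
interaction plus financial-year dummies, calendar-month dummies and
case-mix dummies (reference categories: age 60-64, female, admitted from
hospital, ASA 1, full mobility, extracapsular fracture, year 2008/9,
April); the post main effect is collinear with the year dummies and the
England main effect with the hospital effects, so neither is entered —
only the interaction is identified. The period model replaces the single
interaction with three (2010/11 bonus £445; 2011/12 £890; 2012/13-2014/15
£1,335). The pre-trend model uses the eight pre-policy quarters (reference
first) with England × quarter interactions; calendar-month dummies are
omitted there because year-specific quarter dummies and month dummies are
exactly collinear over a two-year window. Both a joint Wald test of the
interactions (with and without the final, anticipation-prone quarter) and
the summed-coefficient linear combination are reported, as the published
"joint test" row is ambiguous between the two. Robustness variants:
balanced panel (hospitals in all years with ≥30 patients/year), limited
case-mix (age/sex/fracture only, no missingness exclusions), seven-criterion
bundle definition in all years, and exclusion of the October 2009 - March
2010 anticipation window.

**Count outcome.** The number-of-criteria-met outcome uses the
era-specific criterion set (7 then 8) by default, since the published
definition is not stated; the seven-criterion column is always available.

**Sequential analysis.** On post-policy rows, `Pre` = 1 iff any of
{bpt1, bpt3, bpt4, bpt6} is missed and `Post` = 1 iff all of
{bpt7, bpt8, bpt9} are met; bpt2 is excluded throughout. bpt4 is included
in the pre-surgery set in all post-policy years by default (the published
set listing is unconditional), with a flag restricting it to the years it
was actually incentivized. Three variants mirror the published columns:
raw contrasts (whose coefficients equal the 2×2 cell-mean contrasts
exactly), time dummies + covariates, and additionally hospital fixed
effects (the England main effect then drops). Note that the raw contrast is
confounded by pooling years with different achievement levels — with
independent criteria it is still negative — so null-effect checks condition
on time.

## 4. Calibrated reproduction

The acceptance computation generates a cohort calibrated to the published
proportions with equal patients per year, runs the pipeline, and compares
six estimates (average bundle effect; three period effects; surgery within
36 h; bone health assessment) with the published regression estimates at a
±3 pp tolerance. That tolerance is the gap between covariate- and
panel-adjusted regression estimates and the raw difference-in-differences
implied by the published proportions alone (e.g. 52.9 raw vs. 52.5
published for the average effect; 62.8 vs. 60.6 for the third period):
the synthetic cohort can match the published cell proportions, but not the
register's unpublished year-by-hospital patient weights. Year weights are
configurable where a user wishes to explore that sensitivity.

## 5. Known limitations

- Only non-negative within-patient equicorrelation is representable; the
  two clamped Wales cells overshoot their printed bundle proportions by up
  to 0.7 pp.
- The published criterion-correlation matrices for the appendix are not
  available in text form; the copula default reproduces bundle-level joint
  achievement, not the full pairwise structure (fixed matrices can be
  supplied per cell).
- The coverage of cluster-robust confidence intervals is slightly below
  nominal (≈92% at 95% nominal in the shipped simulation) — expected for
  CR1 with unbalanced clusters and a small control-country cluster count;
  wild-cluster bootstrap is out of scope.
- The bpt4 single-criterion estimate is not comparable to the published
  one, which appears to use a restricted window that the text does not
  describe.
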