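# Methods

## Data model and conventions

The unit of input is one subgroup estimate: (setting, survey year,
indicator, dimension, subgroup, estimate, population share). Estimates are
percentages in [0, 100] — the scale on which every quantity here is
reported — and population shares are proportions in [0, 1]. Within a cell
(one setting × year × indicator × dimension) shares are rescaled to sum to
1 when they are within 1e-3 of 1, which absorbs the rounding carried by
published extracts; larger deviations are treated as data errors rather
than silently normalized.

A cell enters the analysis only when *every* subgroup of its dimension is
present (completeness rule): a partially observed wealth breakdown would
bias every measure that uses the full gradient, so it is excluded and
logged instead. Settings are restricted to the low, lower-middle and
upper-middle World Bank income groups; high-income and unclassified
settings are filtered out with the reason recorded. The income catalogue is
user-supplied, not hard-coded, because classifications are fiscal-year
specific.

The national average of a cell is the population-share-weighted mean of its
subgroup estimates unless a survey-reported value is supplied. Recomputation
is the default because the PAR calculation needs a national average on
exactly the same population as the subgroup breakdown; a supplied value
always wins when present, and both paths are exercised in the tests.

## Summary measures

**Difference and ratio** compare the most-advantaged and most-disadvantaged
subgroups (urban/rural, richest/poorest quintile, secondary+/no education,
mothers 20–49/15–19). For adverse indicators (non-receipt of vaccines) the
comparison is reversed so a positive difference and a ratio above one always
read as "the disadvantaged subgroup is worse off". Child sex is non-ordered;
male − female is a reporting convention, not an advantage claim. A missing
comparison subgroup yields a not-applicable result, never an exception,
because downstream aggregation must be able to run over ragged panels.

**SII and RII** summarize the whole gradient of an ordered dimension.
Subgroup $j$ is placed at the ridit-style midpoint rank
$x_j = \sum_{i<j} w_i + w_j/2$ and the estimates are regressed on the ranks
with population-share weights. SII is predicted(rank 1) − predicted(rank 0)
in percentage points; RII is their ratio. Two links are implemented:

- *logit* (default): a weighted GLM with binomial variance fitted to
  $y_j/100$. Predictions stay inside [0, 100] for any gradient, which
  matters for indicators near the boundary (BCG coverage near 100%,
  non-receipt near 0%). Estimates of exactly 0 or 100 are clipped to
  [0.01, 99.99] before the transform, since the link is undefined at the
  boundary and published tables do reach 0.0 and 100.0.
- *linear*: weighted least squares. Simple and exactly analytic, but the
  extrapolation to rank 0 can leave [0, 100]; when the rank-0 prediction is
  ≤ 0 the RII is reported not-applicable with a note rather than as a
  negative ratio.

Every SII/RII result records the link that produced it. By default SII/RII
are reported for economic status and education only — the two dimensions
with enough ordered subgroups for the regression to add information over the
pairwise measures — and a flag lifts the restriction to any ordered
dimension. Two-subgroup dimensions (age, residence) get difference and
ratio by default.

The fits are delegated to statsmodels (WLS, and GLM with binomial family and
variance weights); the test suite validates both against independently coded
solvers — the 2×2 normal equations solved by Cramer's rule, and a from-
scratch IRLS loop — to 1e-8 relative error on randomized cells, so the
package's numbers do not rest on one implementation.

**PAR** is the most-educated subgroup's estimate minus the national
average; the potential average adds it back to the national average (clamped
to [0, 100] with a note when clamping occurs, which requires an externally
supplied national average inconsistent with the subgroup data). Signed PAR
is the default; an optional truncation mode maps sign-adverse values
(reference subgroup below the national average on a coverage indicator) to
zero for users who prefer the attributable-risk convention that inequality
elimination cannot worsen the average.

## Change over time

Eras default to 2004–2013 and 2014–2023 and are configurable. Per (setting,
indicator) — per indicator, because one setting's older surveys differ in
indicator coverage — the latest recent-era survey anchors the pair and the
older-era year minimizing |anchor − 10 − year| within a 5–15-year window is
chosen. Equidistant candidates resolve to the *earlier* year: the longer
window makes the annualized change less noisy. The per-decade change is
(v₁ − v₀)/gap × 10, applied identically to difference, ratio, SII and RII;
ratio-scale measures are differenced on their own scale (no log transform),
so a "change in ratio of −0.2" means the ratio itself fell by 0.2.
Indicator–dimension trend cells observed in fewer than 5 settings are
excluded (`trend_cell_gate`), which reproduces the natural exclusion of
late-schedule vaccines such as rotavirus from decade comparisons.

## Benchmarks

Cross-country summaries are sample medians (mean of the central pair for
even n) with 95% confidence intervals from distribution-free order
statistics: the tightest pair of order statistics whose exact
Binomial(n, 1/2) coverage reaches the nominal level, with the most
symmetric pair breaking width ties. The method is assumption-free and
conservative (realized coverage ≥ nominal, verified by simulation in the
tests); below n = 6 no pair reaches 95%, so the full range is returned with
a low-coverage note. A seeded percentile bootstrap (2,000 resamples) is
provided for comparison; outputs state which method produced them.
Interquartile ranges use linear interpolation of order statistics (numpy's
default convention), stated explicitly because quartile conventions differ
across software.

## Synthetic panels

The generator emulates the *structure* of a multi-country survey-based
panel, not any real country's values. Defaults are chosen to be realistic
for recent low- and middle-income survey data:

- 92 settings (20 low, 40 lower-middle, 32 upper-middle income);
- per-indicator baselines at levels typical of recent cross-country
  medians (DTP3 81.9%, full immunization 63.2%, zero-dose 7.0%, …);
- setting-level random effects (sd 10 pp) and income-group shifts
  (−12/0/+6 pp) produce the wide between-country spread seen in real
  panels;
- linear subgroup gradients: education and wealth gaps of 12 pp, residence
  2 pp, maternal age 4.4 pp, sex 0 pp, with low-income settings multiplied
  by 1.5 (economic inequality is largest there) and non-receipt indicators
  reversed and scaled by 0.6 (non-receipt gaps are smaller in absolute
  terms because prevalence sits near zero);
- non-receipt indicators coupled to their coverage counterpart
  (0.5 pp per pp of counterpart shortfall), so they are anti-correlated
  with coverage per setting by construction;
- two eras: a +5 pp/decade national trend and a −2 pp/decade gradient
  trend (coverage improving, inequality narrowing modestly);
- binomial sampling with denominator 500 per subgroup estimate (an
  optional overdispersion divisor emulates design effects), 5% missing
  subgroup estimates, and rare (4%) rotavirus availability in older-era
  surveys;
- quintile shares are exactly 0.2; education, residence, age and sex shares
  are drawn per setting from seeded distributions.

Gradients are linear in subgroup order, which matches the step-wise
education patterns seen in real data and keeps the truth table analytic.
True subgroup probabilities are clamped to [0.5, 99.5] before sampling, so
ceiling/floor effects compress gradients for settings near the boundary —
as they do in reality. `truth_table` returns the noise-free measure values
implied by the same seeded construction (including clamping), which is the
oracle used by the parameter-recovery tests; it tabulates the truth for all
cells, including ones the sampled panel omits as missing.

What the generator does **not** emulate: real-country covariance between
indicators beyond the adverse coupling, spatially structured (sub-national)
inequality, non-random missingness patterns (e.g. the education dimension
being unavailable in specific survey programs), recall bias, and
design-effect correlation between subgroups of one survey. Passing
recovery tests therefore show that the pipeline's estimators identify known
structure under survey-scale sampling noise — not that any specific
real-world dataset would yield the same numbers.

## Problem sizes and numerical choices

The default panel (92 settings, 9 indicators, 5 dimensions, 2 eras,
denominator 500) is the package's reference scenario; the recovery tests
use a 50-setting, denominator-1,000 scenario where binomial noise on a
single estimate (se ≈ 1.5 pp) leaves the cross-setting median within the
stated 2 pp tolerance of the configured gradients. The GLM is run to a
deviance tolerance of 1e-12 so that agreement with the brute-force IRLS
oracle holds at 1e-8 relative error. Ties in "most advantaged" cannot occur
(subgroup orderings are fixed catalogues), so no tie-breaking is defined
for the pairwise measures.

## Known limitations

- No standard errors or confidence intervals for setting-level SII/RII;
  the cross-country medians carry the only interval estimates.
- The exact regression family behind published SII/RII figures varies
  across tools; both links are implemented and labelled, and analyses
  should state which they used.
- Survey microdata processing (design weighting, wealth-index construction)
  is upstream of this package: inputs are already-disaggregated estimates.
- Only two time points are supported; no joinpoint or spline trends.
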