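# Methods

## Study design and data model

The package targets 1:1 matched case-control studies: each hypertension
case is paired with one control of the same sex whose age differs by at
most 5 years. A subject record carries the pair identifier, case/control
status, sex, age, height (cm), weight (kg), waist and hip circumference
(cm) and a binary family-history flag. Derived quantities are BMI =
weight / (height in m)², its four-level category, WHR = waist/hip and a
sex-specific WHR abnormality flag (> 0.90 male, > 0.80 female; the cutoff
value itself is normal).

BMI categories follow the Chinese adult standard with half-open intervals
so that the categories partition (0, ∞): low < 18.5, normal [18.5, 24.0),
overweight [24.0, 28.0), obese ≥ 28.0 kg/m². The standard's verbal form
leaves the fractional gaps 23.9–24.0 and 27.9–28.0 unassigned; the
half-open convention closes them, and 28.0 goes to obese. For interaction
analyses BMI is binarized as normal vs abnormal, where abnormal pools
low, overweight and obese.

Rows failing field validation are dropped with logged reasons rather than
imputed. Pair-matching violations (sex mismatch, age gap > 5) are
warnings by default and errors under strict validation, since matching
criteria describe how the data were collected, not a property software
can repair. Pairs lacking exactly one case and one control are excluded
from pair-based analyses but retained for unconditional ones.

## Contingency analysis

The 2×4 joint-exposure ("Botto–Khoury") table counts cases and controls
over the four (FH, BMI-abnormal) states. Crude odds ratios against the
doubly-unexposed reference use the cross-product ratio with Woolf
log-scale confidence intervals, SE(log OR) = √(1/a + 1/b + 1/c + 1/d)
and a normal quantile (1.959964 at α = 0.05). The Woolf method was chosen
because it reproduces the published per-row intervals to the printed
precision. Zero cells raise a typed error unless the Haldane–Anscombe
+0.5 continuity correction is requested, in which case all four counts
are bumped and the estimate is flagged.

Group comparisons use the Welch (unpooled) two-sample t statistic from
summary statistics, with Welch–Satterthwaite degrees of freedom; with the
equal group sizes of a 1:1 design this is numerically identical to the
pooled form, so the choice matters only for unequal-n reuse. Categorical
comparisons use the Pearson chi-square without continuity correction.

## Interaction measures

With OR₁₁, OR₁₀, OR₀₁ the crude odds ratios (risk ratios under the
rare-disease approximation, reference risk normalized to 1):

    RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1
    AP   = RERI / OR₁₁
    PAP  = RERI / (OR₁₁ − 1)
    SI   = (OR₁₁ − 1) / ((OR₁₀ − 1) + (OR₀₁ − 1))

These satisfy RERI = AP·OR₁₁, PAP = RERI/(OR₁₁−1), SI =
(OR₁₁−1)/((OR₁₁−1)−RERI) and PAP = 1 − 1/SI, which the property suite
checks on random triples. Exact additivity (OR₁₁ = OR₁₀ + OR₀₁ − 1)
zeroes RERI, AP and PAP and sets SI = 1 simultaneously. Interaction is
classified positive/none/negative by the sign of RERI. SI with a
non-positive denominator and PAP with OR₁₁ ≤ 1 are undefined and raise a
typed error rather than returning sentinels; the reporting layer shows
such measures without a value.

### Confidence intervals

Two routes, both reported because the published intervals' provenance is
unstated and neither is claimed to match them:

- **Delta method** (Hosmer–Lemeshow): each measure is a function of the
  log odds ratios (β₁₁, β₁₀, β₀₁); the gradient is propagated through
  their 3×3 covariance. For a 2×4 table that covariance is Var(βᵢ) =
  Σ 1/count over the cell and reference, with off-diagonal terms equal to
  the shared reference contribution 1/a₀₀ + 1/b₀₀ — identical to the
  saturated logistic model's covariance. RERI and AP get normal intervals
  on their own scale; SI is handled on the log-SI scale with
  exponentiated bounds; the PAP interval is the monotone transform
  1 − 1/SI of the SI interval.
- **Pair-resampling bootstrap**: matched pairs are resampled with
  replacement (preserving the design), the 2×4 table and measure are
  recomputed per replicate, and a percentile interval is taken. Replicates
  with undefined measures are dropped and counted; more than 20% undefined
  attaches a warning. The seed is a required argument.

Delta-method RERI intervals are known to be conservative when the
component OR estimates are strongly skewed (small reference cells, large
ORs): in our simulations at 342 pairs their coverage of the true RERI
runs near 97%, and under an additive null that retains large main effects
the type-I error drops to roughly 1.5%. Under the global null (no
exposure effects) calibration is close to nominal. This is a property of
Wald-type RERI intervals, not of the implementation, and is why the
bootstrap is offered alongside.

## Regression

Unconditional logistic regression (optionally sex-adjusted) is maximum
likelihood via Newton iterations to gradient tolerance 1e-8 with at most
100 iterations, covariance from the inverse observed information;
rank-deficient designs and separation raise typed errors. Conditional
logistic regression for 1:1 pairs maximizes the conditional likelihood,
which for a single binary exposure reduces to the discordant-pair ratio
(McNemar identity) — an identity the tests exploit. The estimation
machinery is statsmodels' `Logit` and `ConditionalLogit` behind the
package's interface. The joint-exposure design codes the four states as
three mutually exclusive indicators, so a saturated unconditional fit
reproduces the crude ORs and Woolf variances exactly (to 1e-6 in tests);
Wald CIs use the normal quantile for the same reason. Since pairs are
matched on sex, the sex term is dropped from conditional fits.

The original report's "multilevel" logistic model (with an intraclass
correlation of 0.248) is not specified enough to reproduce — the
clustering unit and random-effect structure are unstated — so the package
offers the two design-respecting estimators above instead; a
random-intercept model is out of scope.

## Synthetic studies

The generator emulates the study conditions: 342 pairs, ages 28–87.
Disease follows a logistic model, logit P = β₀ + β_FH·FH + β_cat(BMI
category) + β_int·FH·1[BMI abnormal]. Defaults: population margins from
the study's control group (BMI ~ N(23.46, 3.18²) kg/m², FH prevalence
0.617, age truncated-normal 62 ± 10.7 on [28, 87]); effect sizes are the
logs of the reported per-category odds ratios (FH 4.986; low 1.528,
overweight 3.333, obese 7.312); baseline odds logit(0.05), giving a
population prevalence near 23%. Height is sex-specific normal (168/158.5
± 6 cm), weight is back-solved from BMI and height, and waist/hip are
drawn with correlation 0.8 to BMI around the control-group means — a
plausible constant, not an estimate from the study, since no raw data are
available. FH and BMI are independent by default; an odds-scale
association knob exists. Exposures are independent of age and sex and
disease depends only on the exposures, so sex/age matching does not
distort the exposure odds ratios the 2×4 table estimates.

Because the interaction parameter lives on the log-odds scale while the
target RERI lives on the additive OR scale, β_int is calibrated by
Brent root-finding against the *theoretical* crude-table RERI, computed
exactly by enumerating the eight FH × BMI-category strata with
normal-CDF category probabilities (no Monte Carlo; verified against a
400,000-draw simulation in tests). The paper-like default targets
RERI = 5.674, yielding OR₁₁ = 13.29, OR₁₀ = 4.99, OR₀₁ = 3.63. The
additive-null configuration used for type-I-error calibration is the
global null (all exposure effects and β_int zero, so the OR triple is
exactly (1, 1, 1)) with the baseline raised to keep prevalence at the
paper-like level; a variant retaining the BMI main effects with β_FH =
β_int = 0 (also exactly additive) is provided for studying the
conservativeness noted above.

Matched sampling draws cases without replacement and, for each, one
unused same-sex control within the 5-year age window; exhaustion raises
an error reporting the achievable pair count. Identical seeds give
byte-identical CSV output.

### What the simulator does not emulate

Selection and recall biases, secular trends, measurement error beyond
0.1-unit rounding, FH misclassification, the unanalysed questionnaire
covariates (these can only be carried as noise columns), and any
age/sex dependence of the exposures. Passing recovery tests therefore
show the estimators are correct under the stated generative model, not
that the original study was free of bias.

## Validation scale choices

The recovery study runs 600 simulated studies of 342 pairs (and 300
under the null): enough that the Monte-Carlo standard error of the mean
RERI (~2%) is small against the 10% bias criterion, while a full suite
run stays under two minutes. At 342 pairs the crude-OR RERI estimator
carries a genuine upward small-sample bias of about 7% (log-normal OR
skew), which is within the criterion but visibly nonzero; it vanishes
with study size, as the 3,000-pair single-study test shows.

## Known limitations

- Crude-table measures are unadjusted; confounding must be addressed by
  the matched design or the regression route.
- Odds ratios approximate risk ratios only for reasonably rare outcomes;
  at the simulator's 23% prevalence the approximation is visible in the
  gap between the per-category ORs fed in and the aggregated cell ORs
  that come out.
- The delta-method RERI interval inherits the conservativeness described
  above; for small studies prefer reporting both CI routes.
- The published counts of the motivating study are internally
  inconsistent (column totals and the both-exposed row do not match its
  stated design), so the package reproduces exactly only the rows that
  are arithmetically self-consistent; the remaining printed values are
  treated as inputs, not targets.
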