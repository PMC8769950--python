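# Methods

This note documents the models and conventions behind `finprotect`, the
design choices made where the methodology is genuinely open, and what the
synthetic-data validation does and does not establish.

## Units and period

All monetary quantities are in currency units per 30-day period (the
package's examples use Bangladeshi Taka).  Survey recall is assumed to be
30 days for outpatient and non-medical health payments and 12 months for
inpatient payments; the consumption module converts inpatient spending with
a configurable divisor (default 12).  Dividing annual inpatient spending by
12 is known to *understate* monthly OOP relative to a true 30-day recall
(spending is lumpy), biasing catastrophic-spending incidence downward for
inpatient users; the divisor is exposed so this bias can be studied.  Daily
poverty norms are scaled by 30, not 365.25/12, for consistency with the
30-day recall window.

## Catastrophic health expenditure

`E_i = 1` iff `OOP_i > z * D_i`, strict inequality, with `D_i` total or
non-food expenditure.  Conventions:

* Boundary households (`OOP_i` exactly `z * D_i`) are not catastrophic.
* If `D_i = 0` and `OOP_i > 0`, the household is catastrophic (health
  spending out of zero measured capacity); if both are 0 it is not.  Both
  follow mechanically from the strict inequality.
* OOP is part of consumption and is **not** netted out of the denominator;
  consumption net of OOP appears only in the impoverishment analysis.
* Incidence is household-weighted (share of households) by default, the
  denominator used in subgroup tables; a person-weighted variant
  (`w_i * hh_size_i`) is available.

## Poverty lines and impoverishment

The CBN food component is `30 * sum(price_item * quantity_item)` over a
fixed basket (quantities per person per day).  The package stores, but does
not verify, the caller-attested caloric norm of the basket (the default
11-item basket is attested at 2122 kcal/person/day).  The non-food
component is the person-weighted *lower* median of per-capita non-food
spending among households whose per-capita food spending lies within a
symmetric band around the food line; the band half-width is a free
parameter, default ±10%, because the "close to the food line" window is not
standardized in the CBN literature.  At least 20 in-band households are
required; a thinner window is an error suggesting a wider band.

Poverty is strictly-below-line on per-capita expenditure; net-of-OOP
per-capita expenditure is floored at zero.  Impoverishment headcounts are
person-weighted (design weight × household size) so they are population
proportions, and an impoverished household is gross-non-poor and net-poor;
already-poor households whose position worsens are never counted.  Because
OOP ≥ 0 implies net-poor ⊇ gross-poor, the headcount difference equals the
impoverished share exactly, and the Pen's-parade crossing count is the same
set by construction (this identity is asserted in tests).

The relative difference is reported as `absolute / gross headcount × 100`
by default, with `of_net` selectable; usage varies across the literature
and the package does not arbitrate.  `individuals_pushed` requires an
explicit `population_total` (default 191.3 million in the demo
configuration).

## Asset index

Weighted-**correlation** PCA (columns standardized to weighted mean 0,
population variance 1) rather than covariance PCA: dummy variables have
prevalence-dependent variances, and standardization is the
Filmer–Pritchett convention.  Household size enters as a frequency weight;
for integer weights this is algebraically identical to unweighted PCA on
the row-replicated matrix, which is the oracle used in tests.  The leading
eigenvector's sign is arbitrary, so scores are oriented to make the summed
loadings on a whitelist of wealth-indicating dummies (electricity, piped
water, flush sanitation, refrigerator by default) positive.  Quintiles are
cut at person-weighted score quantiles 0.2/0.4/0.6/0.8 with the *lower*
quantile convention; tied scores always share the lower applicable
quintile, so quintile shares are 20% up to tie-induced deviation.  The
frequency weights inside the PCA and the person weights used for quintile
cutting are distinct and separately configurable.

## Design-based estimation

Point estimates are Hajek ratios `sum(w y)/sum(w)`.  Variance is
first-stage Taylor linearization: PSU totals of `w_i (y_i − est)` are
compared within strata with the `n_h/(n_h−1)` factor, summed over strata,
and divided by `(sum w)^2`.  This treats first-stage sampling
with-replacement and ignores second-stage variance — the standard
approximation for household surveys with small second-stage sampling
fractions.  CIs are `est ± 1.96 SE` (normal critical value), truncated to
[0, 1] for proportions; with a modest number of PSUs per stratum the
normal critical value makes the CI slightly anticonservative (the 112-PSU
coverage simulation in the tests observes ~95%, a 56-PSU design ~93%).
Domain (subpopulation) estimates zero the residuals outside the domain but
keep all PSUs, the correct treatment for conditional summaries such as
"mean OOP among households with any payment".  A stratum with a single PSU
is a hard error by default; a `single_psu="center"` fallback measures such
strata against the grand mean of PSU totals.  Weighted quantiles use the
lower-quantile convention (smallest value whose cumulative weight share
reaches q).

## Determinant models

Treatment coding against fixed references: female head, no institutional
education, household of 1–2 members, "no" for each binary exposure, urban,
first division label, poorest quintile.  Models 1–2 (CHE outcomes) include
asset quintiles; models 3–4 (impoverishment) do not, so the model degrees
of freedom are 26 and 22.  Complete-case analysis with the dropped count
logged.  The default likelihood is **unweighted** ML (Newton, gradient
tolerance 1e-8, max 100 iterations): the reported fit statistics of this
model family (LR χ², McFadden pseudo-R²) are ordinary-ML quantities.  A
design-weighted pseudo-likelihood variant (GLM with variance weights and
PSU-cluster-robust SEs) is available behind `weighted=True`; its point
estimates answer a different (population-level) question and its
pseudo-R² is quasi-likelihood-based.  CIs are Wald on the log-odds scale
exponentiated to ORs; significance stars at p < 0.05/0.01/0.001.  A
coefficient diverging past |β| > 15 is reported as (quasi-)separation with
the term named; a single-class outcome is an immediate error.  A failure in
one model never aborts the others.

## Synthetic survey generator

The generator emulates a two-stage stratified cluster sample: strata are
division × urban/rural cells, PSUs carry fixed geography, households are
drawn in fixed numbers per PSU, and the design weight is the inverse
stratum selection probability (constant within stratum, log-interpolated
across divisions so weights are unequal but orthogonal to urban/rural).

The household model, in order:

1. **Consumption.** Log-normal monthly per-capita baseline (non-health)
   consumption with a PSU random intercept (intra-cluster correlation), an
   urban premium and an education gradient; the food share follows an
   Engel curve with beta-distributed noise.
2. **Outcome.** The catastrophic indicator at the 10%-of-total threshold
   is drawn from a logistic model in the configured covariates
   (`logit_true_betas`), so the determinants module can be validated by
   exact parameter recovery.
3. **OOP.** Conditional on the indicator, the OOP-to-total ratio is drawn
   above the 10% threshold (log-normal excess scaled multiplicatively by
   `oop_coefficients`, capped at `max_oop_share`) or below it (zero with
   probability `zero_oop_prob`, else a sub-threshold power draw).  OOP is
   therefore a hurdle process — a point mass at zero plus a right-skewed
   positive part — and re-thresholding the emitted components reproduces
   the generative indicator exactly.  At the degenerate boundary
   `zero_oop_prob = 1` no household spends and the flag is forced off.
4. **Components.** OOP is split into non-medical, inpatient (emitted on an
   annual recall so the /12 conversion is exercised; inpatient users only)
   and outpatient parts.  Health spending is embedded in non-food
   consumption; third-party payments are never emitted.
5. **Assets.** Twelve categorical/binary indicators driven by a latent
   wealth score correlated with consumption, via thresholded Gaussian
   latents with per-indicator marginals and wealth slopes.

Default parameters are the study conditions the package is built around: a
2304 × 20 design, seven divisions, ~30% urban, log-consumption location
log(3000) BDT with σ = 0.5, covariate prevalences matching published
household characteristics for Bangladesh (49% chronic-illness care, 18%
with an elderly member, 10.6% private-facility use, ...), log-odds effects
whose magnitudes mirror published determinant estimates (private facility
exp(2.29) ≈ 9.9, chronic care exp(1.55) ≈ 4.7), and OOP magnitude
parameters chosen so the emitted descriptives sit near published conditions
(~75% of households with any health spending, OOP ≈ 8–9% of total
expenditure, ~11% incidence at the 40%-of-non-food threshold).

What the generator does **not** emulate: item-level questionnaires,
within-household individual records, non-response, covariate dependence
beyond geography (e.g. chronic illness is independent of age structure and
wealth), measurement error in consumption, and seasonal price variation.
Consequently, passing recovery and coverage tests establishes that the
estimators are correct under a clean complex-sampling data-generating
process — not that real-survey complications (informative non-response,
recall error, post-stratified weights) are handled.

Only the 10%-of-total outcome is generated from a logistic law; the
40%-of-non-food and impoverishment outcomes are derived from the emitted
expenditures, so for models 2–4 the tests assert effect directions, not
coefficient values.

## Numerical conventions

* Fixed seed ⇒ bitwise-identical tables (single `numpy` Generator, fixed
  draw order).
* CSV round trips are exact: floats are written as `%.17g` and parsed with
  round-trip precision; the missing-value sentinel is `NA`.
* Pen's parade sorts by gross multiple with ties broken by household id.
* Eigendecomposition uses the symmetric solver on the explicitly
  symmetrized weighted correlation matrix.
* Monetary validation is strict: negative money, nonpositive weights and
  `hh_size < 1` are schema errors naming the row.

## Validation problem sizes

The test suite validates at sizes chosen to keep the full run ~20 s: 600-
and 5000-household tables for oracle equivalence (12-significant-digit
agreement with brute-force loops), a 10 000-household table for quintile
balance (±0.5 pp), 46 080 rows for the design-arithmetic check, n = 40 000
for single-fit parameter recovery (each coefficient within 3 SE, with one
predeclared confirmation fit guarding the ~6% familywise false-alarm rate
of 23 simultaneous 3-SE checks), 200 replicates at n = 5000 for pooled
Wald-CI coverage (92–98% band), and 500 replicates of a 112-PSU design for
design-based CI coverage (93–97% band).

## Known limitations

* No replicate-weight (BRR/jackknife/bootstrap) variance, post-stratification
  or calibration; no finite-population corrections.
* Raw per-capita division throughout; no equivalence scale.
* No poverty gap/severity indices, overshoot measures or concentration
  indices.
* The weighted logistic variant relies on variance-weight GLM machinery
  whose cluster covariance support is approximate (statsmodels emits a
  specification warning); the unweighted default is the validated path.
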