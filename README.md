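# finprotect

Financial risk protection analysis for household expenditure surveys:
catastrophic health expenditure (CHE), impoverishment from out-of-pocket
(OOP) health payments, cost-of-basic-needs (CBN) and international poverty
lines, PCA-based asset quintiles, design-based estimation for stratified
cluster samples, and logistic determinant models.

The package is aimed at health-financing and health-equity analysts who
work with Household Income and Expenditure Survey (HIES)-style microdata —
one row per household, with survey design columns (PSU, stratum, weight),
consumption components, OOP payment components on mixed recall windows, and
categorical asset indicators.  Because such microdata are usually
restricted, the package ships a synthetic survey generator that emulates a
two-stage stratified cluster design (e.g. 2304 PSUs x 20 households) with
known ground-truth parameters, so every estimator can be validated by
parameter recovery and brute-force oracles.

## Methods in brief

**Catastrophic health expenditure.** Household *i* with monthly total
consumption expenditure *x_i*, food expenditure *f_i* and monthly OOP
payments *OOP_i* faces CHE when

    E_i = 1  iff  OOP_i > z * D_i,

with *D_i = x_i* (threshold *z* = 0.10) or *D_i = x_i − f_i* (non-food
capacity, *z* = 0.40).  Incidence is the design-weighted headcount
Σ w_i E_i / Σ w_i with a Taylor-linearized 95% CI.

**Impoverishment.** With poverty line *PL* (CBN: priced food basket plus
the band-median non-food allowance; IPL: 1.9 international dollars/day at a
PPP rate, e.g. 28.27 BDT per intl$), a household is poor when per-capita
expenditure falls strictly below *PL*.  Impoverishment from OOP is the
person-weighted headcount difference between poverty on gross consumption
and on consumption net of OOP — equivalently the share of gross-non-poor
households made net-poor.  Pen's parade plots households by gross
consumption as a multiple of *PL*, with "paint drop" bars down to the net
multiple.

**Asset quintiles.** Dummy-coded asset indicators are standardized and the
first principal component of the household-size-frequency-weighted
correlation matrix is the wealth score (Filmer–Pritchett); quintiles are
cut at person-weighted score quantiles so each holds 20% of the population.

**Determinants.** Four logistic models, logit(Y_i) = β0 + Σ_k β_k X_ki,
with outcomes CHE (both thresholds, models 1–2, adjusted for asset
quintiles) and impoverishment (national and international lines, models
3–4); ORs with Wald 95% CIs, log-likelihood, LR χ² and McFadden pseudo-R².

## Worked example

```python
import finprotect as fp

cfg = fp.GeneratorConfig(n_psu=500, households_per_psu=20, seed=42)
df = fp.add_aggregates(fp.generate_households(cfg))   # 10 000 households
design = fp.SurveyDesign()                            # weight / psu_id / stratum_id

for spec in fp.CANONICAL_SPECS:                       # (total, 0.10), (nonfood, 0.40)
    est = fp.che_headcount(df, spec, design)
    print(f"CHE ({spec.denominator}, z={spec.z:.2f}): "
          f"{100*est.estimate:.1f}% (95% CI {100*est.ci_low:.1f} to {100*est.ci_high:.1f})")

from finprotect.poverty import DEFAULT_FOOD_PRICES, DEFAULT_FOOD_BASKET
line = fp.cbn_line(df, DEFAULT_FOOD_PRICES, DEFAULT_FOOD_BASKET, design=design)
res = fp.impoverishment(df, line, design, population_total=191_300_000)
print(f"impoverished by OOP payments: {100*res.absolute_difference:.2f}% "
      f"({res.individuals_pushed/1e6:.2f} million people)")
```

prints

```
CHE (total, z=0.10): 27.1% (95% CI 26.3 to 28.0)
CHE (nonfood, z=0.40): 10.2% (95% CI 9.6 to 10.9)
impoverished by OOP payments: 5.60% (10.72 million people)
```

Read: under the 10%-of-total rule, 27.1% of households in this synthetic
population face catastrophic health spending (10.2% under the stricter
40%-of-non-food rule), and OOP payments push 5.6% of the population —
10.7 million people when scaled to a 191.3-million population — below the
CBN poverty line (2595 BDT per capita per 30 days here: a 1143 BDT food
component plus a 1452 BDT non-food allowance).  Fitting determinant model 1
on the same table recovers the generator's effect structure: OR 4.33 for
chronic-illness care, 10.19 for private-facility use (n = 10 000,
pseudo-R² = 0.206).

The same pipeline runs from the shell:

```bash
finprotect simulate --out households.csv --seed 7
finprotect che --input households.csv --out che.csv --by chronic_care,division
finprotect report --out bundle/ --seed 7      # full output bundle
```

`report` writes the characteristics table, the OOP summary (unconditional
and conditional on any payment), CHE incidence by subgroup, the
impoverishment summary under both poverty lines, Pen's parade (CSV + PNG),
the four model tables and a run manifest that fully determines the outputs.

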