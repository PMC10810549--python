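# Methods

## Study emulated by the package

The analysis pipeline reproduces a national cross-sectional design:
all surgical stays for colorectal cancer (ICD-10 C18–C20) over five
years, mainland residents and mainland hospitals only, hospitals with
fewer than five such patients over the period excluded, records with
missing required fields removed last. The primary outcome is death
within 30 days of surgery; the exposure is the competitiveness of the
hospital's market. Every filter step is logged as a flowchart whose
arithmetic is checked by the test suite.

The 30-day boundary is inclusive (a death on day 30 counts): the study
definition does not fix the boundary, and "within 30 days" is
conventionally closed. The clock starts at the surgery date.

## Market delimitation and competition

*Fixed radius.* The recruitment area of a hospital is every
municipality whose centroid lies within 30 km (inclusive) of it, by
great-circle distance on a 6371-km sphere. A second hospital is a
competitor when (i) it is itself located inside the disk and (ii) at
least 1% (inclusive) of its own admissions originate from the area.
Reading (ii) against the competitor's *total* admissions is the most
literal interpretation of the rule; road distance and all-cause
admissions are not available in this setting, so great-circle distance
and cohort admissions stand in — both documented as configuration
(`MarketConfig`).

*Patient flow.* Municipalities sending fewer than 2 patients are
dropped (occasional recruitment); the market is the union of the share
rule (≥ 3% of the hospital's remaining admissions) and the cumulative
rule (the shortest descending-share prefix reaching 40%). The union
reading follows the "or" in the rule's statement; ties in the ranking
are broken by municipality id for determinism.

A hospital with an empty disk, or with only single-patient
municipalities, has an *undefined* market: its competition level is NA,
it appears in the descriptive tables' NA row, and it is excluded from
the model fits — mirroring how such hospitals are handled in practice
(they are rare: ~1% of hospitals at the default conditions).

*Indices.* Competitor counts (radius method, main analysis) and the
Herfindahl–Hirschman index on the patient-flow market (sensitivity
analysis). Shares are computed over all hospitals recruiting from the
market's municipalities and sum to one; HHI is their squared sum
(monopoly 1, n equal rivals 1/n). Hospitals are banded at the
25/50/75 percentiles of the index over hospitals (numpy's linear
interpolation; the exact quantile definition is not fixed by the design
and is configurable). Ties at a cut point go to the lower-competition
band. Competitor counts are heavily tied integers, so the four bands
are legitimately unequal — the same behaviour seen in real data — while
the continuous HHI yields near-quarters.

## Charlson comorbidity index

The Quan (2005) ICD-10 mapping of the 17 Charlson conditions with the
original weights (1/2/3/6), shipped as `data/quan_charlson_icd10.csv`
(condition, prefixes, weight, hierarchy) so sites using a coding
variant can edit it. A condition is present when any diagnosis code,
uppercased and undotted, starts with one of its prefixes; of each
hierarchy pair (uncomplicated/complicated diabetes, malignancy/
metastasis, mild/moderate-severe liver disease) only the severe member
scores. Scores are banded 0–2 / 3–4 / >4. The index cancer itself is
included in the two-year lookback pool by default (an "overall
diagnosis" reading; a flag excludes it), so every patient carries at
least the malignancy weight of 2 — the 0–2 band is then dominated by
patients with no other weighted comorbidity.

## Synthetic claims generator

The generator emulates the *structure* of a national claims extract,
not its confidential content. One global seed is expanded into
per-stage substreams (geography / admissions / outcomes), so each stage
is reproducible independently.

*Geography.* Municipalities are scattered uniformly over a lat/lon box
of roughly mainland-France extent (plus a small overseas box, default
2% of municipalities, to exercise the residence filter). Density is
log-linear in the distance to the nearest of 25 urban centres
(log-density = 3 + 4.5·exp(−d/20 km) + N(0, 0.7²)), giving a spatially
clustered field with quartiles near 30/90/270 inhab/km². Population is
density × a lognormal commune area. Hospitals are placed in
municipalities drawn with probability ∝ density, with replacement, so
cities host several hospitals; 8.4% are teaching hospitals, which get a
+0.5 attractiveness bonus on top of N(0, 0.5²) heterogeneity. The
default 726 hospitals reproduce the hospital spatial density of the
real national landscape, which is what makes the competition structure
realistic: competitor-count quartiles around 1/3/7, HHI quartiles
around 0.13/0.19/0.27, and a handful of undelimitable markets.

*Admissions.* A patient draws a residence municipality ∝ population,
then a hospital under a gravity model, P ∝ exp(attractiveness −
0.08·distance_km) — a flow half-distance of ~9 km, chosen as a
realistic scale for surgical care-seeking. The flow mechanics are a
modelling choice of this package (observational studies only observe
the flows), validated by its limit behaviours in the tests: extreme
decay sends everyone to the nearest hospital, zero decay with equal
attractiveness gives uniform choice.

*Covariates* are drawn to match the descriptive margins of a large
national colorectal-cancer cohort: age ~ N(70.4, 12.2²), 44.4% female,
emergency 10.3%, obesity 12.4%, malnutrition 21.7%, neo-adjuvant 12.3%,
the six-procedure mix, deprivation as a standard-normal municipal
score. Charlson bands target a 75/13/12 mix via age-graded band
probabilities (older patients are more comorbid; all other covariates
are mutually independent — the simplest structure that still stresses
confounding adjustment). Within a band, a concrete condition set is
sampled and emitted as ICD-10 codes, so the scoring module recovers the
intended band exactly.

*Outcomes.* Per-hospital intercepts u_h ~ N(0, σ²) with σ = 0.3 by
default; death is Bernoulli with logit p = baseline + Σ β·x + u_h, and
the death day is uniform on days 0..30 after surgery (only the 30-day
indicator matters downstream, so the within-window distribution is
free; later deaths are not simulated). The default β are the logs of
published adjusted odds ratios for this clinical setting (e.g. highly
competitive 0.69, emergency 2.93), so effect sizes are realistic and
recovery is testable. The baseline logit (−4.555) was calibrated once,
numerically, so the marginal mortality at the default conditions is
3.6%, and then frozen. For outcome generation, hospitals whose market
cannot be delimited are treated as non-competitive.

What the generator does *not* emulate: real geography and commune
structure, billing-record layout, within-patient repeat stays,
correlated comorbidity profiles, seasonal or secular trends, deaths
after day 30. Passing tests therefore demonstrate correctness of the
pipeline's logic and estimator under a known truth — not the
transportability of any particular odds ratio to real data.

## Mixed-model fitter

The marginal likelihood integrates each hospital's intercept out of its
Bernoulli product. Each one-dimensional integral is evaluated by
Gauss–Hermite quadrature adapted per hospital: nodes are centred at the
conditional mode of u_h (found by damped Newton on a strictly concave
objective) and scaled by the curvature there. Order 15 is the default —
mode-centred rules of that order are accurate to ~1e-8 relative on
problems like these (the suite checks against brute-force integration
and order-25 agreement). At σ below 1e-8 the likelihood switches to the
exact ordinary-logistic expression.

Optimisation is over (β, log σ) — the log transform keeps σ ≥ 0
unconstrained — with L-BFGS-B from an IRLS warm start and a small
multi-start over σ ∈ {0.1, 0.5} against boundary local optima.
Standard errors come from the observed information (central-difference
Hessian); intervals are Wald with ±1.96·SE, matching the symmetric
95% intervals conventional in this literature, and p-values are
two-sided. Coefficients beyond |β| > 15 raise a separation error naming
the covariate; optimiser failure flags the fit and warns — never a
silent bad fit.

Design matrices are treatment-coded against stated reference levels
(non-competitive, ≤60 years, female, Charlson 0–2, right colectomy,
caseload ≤50/yr, teaching, lower deprivation, very rural). A level
absent from the data drops its column with a warning; a constant
indicator is an error. Obesity is recorded but not in the default
model specification, matching the adjusted models this design reports.

## Problem sizes and calibration checks

Default conditions: 5 000 municipalities, 726 hospitals, 30 000 stays —
the hospital count at full scale (it drives the competition structure),
the patient count scaled to a desk-sized cohort. At this patient count
nearly all hospitals fall in the ≤50/yr caseload band, so the caseload
covariate contributes no columns at default scale; it activates at
larger `n_patients`. Parameter recovery is checked at 150 hospitals ×
30 000 patients over 50 outcome replicates (mean estimated OR within
[0.62, 0.77] of a true 0.69; 95% CI coverage ≥ 88%), the σ = 0
reduction against an independent ordinary-logistic fit at 200 000 rows
(agreement to 1e-4 per coefficient; the large per-group size keeps the
boundary estimate of σ near zero so the comparison is sharp), and the
null-model mortality against its binomial expectation at 200 000
patients.

## Known limitations

* Quartile categorisation of a continuous exposure discards
  information; it is kept because the emulated design uses it.
* Competitor shares are computed on cohort admissions, not all-cause
  admissions (the extract is the cohort); the share threshold is
  configurable for databases where all-cause volumes exist.
* The Wald intervals ignore the uncertainty of σ̂'s boundary behaviour;
  profile intervals are not implemented.
* Single-realisation estimates at the default scale carry visible
  sampling noise (≈1 000 deaths); replicate studies should use the
  outcome-substream replication pattern shown in the test suite.
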