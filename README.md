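# hospcomp

Does competition between hospitals lower post-operative mortality?
`hospcomp` implements, end to end, the epidemiological pipeline used to
answer that question for colorectal-cancer surgery on national claims
data: it delimits each hospital's market, measures the competition the
hospital faces, derives patient and hospital covariates from
administrative records, and estimates the adjusted association between
market competitiveness and death within 30 days of surgery. Because the
real claims extract (the French PMSI) is confidential, the package
ships a synthetic claims generator with known ground truth, so every
stage — including the mixed-model estimator — is validated by parameter
recovery rather than by trust.

It is aimed at health-services researchers and biostatisticians who
want a tested, reusable implementation of these market and competition
primitives, or a simulation bench for mixed-effects mortality models on
clustered administrative data.

## What it computes

**Markets.** Two standard delimitations per hospital *h*:

* *fixed radius* — the municipalities within 30 km of *h*; competitors
  are other hospitals located in the disk that recruit ≥ 1% of their own
  admissions from it;
* *patient flow* — after dropping municipalities sending a single
  patient, the municipalities sending ≥ 3% of *h*'s admissions, united
  with the top-ranked municipalities jointly reaching 40% of cumulative
  admissions.

**Competition.** The number of competitors (radius method) and the
Herfindahl–Hirschman index on the patient-flow market,

    HHI_h = Σ_j s_j² ,

where `s_j` is hospital *j*'s share of all admissions originating from
*h*'s market (shares 40/30/20/10% give HHI = 0.30). Hospitals are
banded at quartiles into non / slightly / moderately / highly
competitive; for HHI, lower is more competitive.

**Outcome model.** A random-intercept logistic regression over stays
*i* in hospitals *h*,

    logit P(death30_ih = 1) = x_ih' β + u_h ,   u_h ~ N(0, σ²),

with treatment-coded covariates (competition level, age band, sex,
Charlson band, malnutrition, emergency admission, neo-adjuvant therapy,
procedure, caseload band, hospital status, deprivation tertile,
recruitment-area density quartile). The marginal likelihood integrates
`u_h` out by adaptive Gauss–Hermite quadrature (order 15, mode-centred);
Wald 95% intervals are reported on the odds-ratio scale. The Charlson
index is computed from ICD-10 codes with the Quan mapping (original
1/2/3/6 weights), shipped as an editable CSV resource.

## Worked example

The numbered scripts under `analysis/` run the study on a synthetic
dataset at the default conditions (726 hospitals, 5 000 municipalities,
30 000 stays over five years):

```sh
python analysis/01_simulate.py --seed 0 --out results/data
python analysis/02_build_cohort.py
python analysis/03_delimit_markets.py
python analysis/04_fit_mortality_model.py
python analysis/05_report_tables.py
```

With seed 0 the cohort keeps 29 265 of 30 000 stays (727 overseas
residents, 8 stays at sub-volume hospitals removed), crude 30-day
mortality is 3.6%, and the main fit prints:

```
Random-intercept logistic fit: 29265 stays, 708 hospitals
log-likelihood -4110.86   sigma(hospital) 0.2327   converged: True
term                                          OR    2.5%   97.5%         p
competition_category[highly]                0.59    0.44    0.78    <0.001
competition_category[moderately]            0.94    0.76    1.18     0.613
competition_category[slightly]              0.93    0.77    1.11     0.397
...
```

Read: stays in highly competitive markets have ~0.6 times the adjusted
odds of 30-day death of stays in non-competitive markets; the generator's
true odds ratios were 0.69 / 0.88 / 1.02 and its true hospital SD 0.3,
so this single realisation recovers the truth within sampling noise
(the test suite quantifies recovery over 50 replicates).

`run_pipeline` (module `hospcomp.report`) performs the same sequence as
one call from a `PipelineConfig` (or a YAML file) and writes every
table plus a seeded manifest.

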