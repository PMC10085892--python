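# cvcost

Individual-level prediction of annual UK healthcare costs associated with
cardiovascular events. The package encodes published regression models of
annual primary care costs (one-part generalised linear model, Poisson
variance, identity link) and annual hospital inpatient costs (two-part
model: logistic regression for the probability of incurring any cost, and
a Poisson-identity GLM for the cost conditional on incurring any),
estimated separately for people without and with previous cardiovascular
disease (CVD). All monetary values are 2020 UK£.

On top of the published coefficient sets the package provides:

* **Prediction** — per-year cost trajectories for covariate profiles with
  annually updated age and time-since-event categories (MI, stroke,
  coronary revascularization, diabetes, cancer, vascular and non-vascular
  death), including event co-occurrence interactions and the rule that
  hospital costs are certain in years with same-year revascularization.
* **Excess costs** — population-average excess annual costs per event and
  timing via recycled prediction, rounded to the nearest £10, with
  percentile bootstrap confidence intervals (resampling participants).
* **Simulation** — synthetic cohorts matching the published baseline
  marginal distributions, annual event hazards with death absorbing, and
  person-year cost panels generated from the encoded models; plus
  pro-rata allocation of multi-year admission costs to annual periods.
* **Estimation** — re-fitting models of the same form from person-year
  panels: six candidate family/link pairs under quasi-likelihood IRLS,
  cluster-robust (sandwich) standard errors grouped by participant,
  two-part hospital fitting, model-comparison diagnostics (modified Park
  test, cross-validated RMSE/MAE, Hosmer–Lemeshow) and bidirectional
  stepwise covariate-block selection at the 1% level.

## Command line

```bash
# per-year predictions for profiles in a CSV (one row per person)
cvcost predict --profiles profiles.csv --stratum without_cvd \
    --horizon 5 --out predictions.csv

# excess-cost table (defaults to the reference individual as population)
cvcost excess --stratum without_cvd --bootstrap 1000 --seed 1 \
    --out excess.csv

# simulate a synthetic person-year panel
cvcost simulate --config sim.yaml --out simdir/

# re-estimate the models from a panel and report parameter recovery
cvcost fit --panel simdir/panel.csv --stratum without_cvd --out fitdir/
```

Profile CSVs use the `CovariateProfile` field names
(`sex, ethnicity, townsend_quintile, smoking, physical_activity, diet,
bmi_category, ldl_mmol_per_l, hdl_mmol_per_l, creatinine_umol_per_l,
sbp_mmhg, dbp_mmhg, on_antihypertensive, severe_mental_illness,
prior_type1_diabetes, prior_type2_diabetes,
years_since_diabetes_diagnosis_at_entry, prior_cancer,
years_since_cancer_diagnosis_at_entry, prior_cvd_category,
age_at_entry_years`) plus optional event first-occurrence year columns
(`mi_year, stroke_year, crv_year, diabetes_year, cancer_year, vd_year,
nvd_year`). Omitted fields default to the reference category.

## Coefficient fixture

The published models ship as JSON
(`src/cvcost/fixtures/published_models.json`, schema version 1): six
coefficient sets (2 strata × {primary, hospital part 1, hospital part 2}),
each an ordered term list with covariate transforms, category levels,
interaction components, and coefficients as printed (£ for cost parts,
odds ratios for the logistic part). Temporal categories merged during the
original selection are marked `merged_with_preceding` and resolve to the
preceding category's value at load time. A checksum test guards the
transcription.

## Known limitations

* Odds ratios are encoded as printed (rounded); two-part reference
  predictions therefore match the published values to within ~1–2%, not
  exactly.
* Published variance–covariance matrices are not reproduced; individual
  prediction intervals are out of scope.
* The published hospital-care excess table averages over the original
  cohort, which is access-restricted; hospital excess on synthetic
  populations is approximate (primary-care excess is exact by linearity).
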