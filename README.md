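# ntcpkit

Normal-tissue toxicity (NTCP) modeling from cumulative dose–volume
histograms: EQD2 dosimetric feature extraction, rank-based univariate
screening, collinearity clustering, bootstrap LASSO stability selection
with validation AUC, and six-bin observed-vs-predicted calibration — plus
a synthetic cohort generator with a known logistic ground truth so the
whole pipeline is testable end to end without patient data.

## Pipeline

1. **`cohort`** — synthetic cohorts: smooth monotone sigmoid DVHs (highly
   collinear Dx metrics by construction), clinical covariates (age, sex,
   KPS, smoking, pack-years, serum A2M with a smoking shift, chemotherapy,
   fractionation menu incl. SBRT), and CTCAE grades 0–5 drawn from a
   configurable logistic outcome model whose coefficients are saved for
   parameter-recovery tests.
2. **`dvh`** — EQD2 conversion `D·(d + α/β)/(2 + α/β)` with `d = D/n_fx`
   (defaults α/β = 10 esophagus, 3 lung/heart), Dx grid (x = 5…100% in 5%
   steps), mean/max dose, and fractional fDx = Dx / treatment days
   (physical dose by default, switchable).
3. **`screen`** — Spearman rs vs ordinal grade (t-approximation p;
   seeded permutation option) and Wilcoxon rank-sum between grade <2 and
   ≥2 groups; candidates pass at p < 0.1, with an always-include list
   (treatment days, SBRT, chemo).
4. **`decorrelate`** — Pearson correlations among dosimetric variables,
   average-linkage clustering on 1 − |r| cut at |r| > 0.75, one
   representative per cluster (best |rs| with the endpoint).
5. **`lasso`** — stratified 2/3–1/3 split balanced on subtype × outcome,
   1,000-bootstrap L1 logistic ensemble (5-fold CV penalty per replicate,
   standardized predictors, coefficients reported on the original scale),
   per-replicate validation AUC (Mann–Whitney), feature selection and
   pair co-selection frequencies, and a final refit with bootstrap SDs,
   odds ratios and percentile CIs.
6. **`calibrate`** — six equal-size risk bins on the validation set,
   observed vs mean predicted incidence, and a markdown run report.

## CLI

```bash
ntcp simulate --n-patients 258 --seed 1 --out-dir cohort/
ntcp features --dvh-csv cohort/dvh.csv --clinical-csv cohort/clinical.csv --out features.csv
ntcp screen --features-csv features.csv --endpoint esophagitis --out screen.csv
ntcp cluster --features-csv features.csv --screen-csv screen.csv --structure esophagus
ntcp run --config config.yaml --out-dir out/      # full pipeline + report
```

Exit codes: 0 ok, 1 validation/configuration error, 2 runtime error.

Example `config.yaml`:

```yaml
endpoint: esophagitis        # or pneumonitis
seed: 1
n_boot: 1000
screening_alpha: 0.1
correlation_threshold: 0.75
lambda_rule: {kind: cv, folds: 5}   # or {kind: fixed, lam: 2.0}
synthetic: {n_patients: 258}        # or dvh_csv/clinical_csv paths
```

### File formats (CSV, UTF-8, header row)

- **DVH** (long): `patient_id, structure, dose_gy, volume_fraction` —
  cumulative curves, volume fraction 1.0 at 0 Gy, non-increasing.
- **Clinical**: `patient_id, age, sex, kps, smoking_status, pack_years,
  a2m_mg_dl, chemo_timing, rt_modality, total_dose_gy, fraction_number,
  treatment_days, subtype` plus `grade_<endpoint>` columns (0–5).
- **Features**: one row per patient with `{structure}_D{x}`,
  `{structure}_mean`, `{structure}_max` (EQD2 Gy), `esophagus_fD{x}` etc.
  (Gy/day), clinical covariates, and per endpoint `grade_<endpoint>` /
  `<endpoint>_ge2`.

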