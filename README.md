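# streamsem

A tested, reusable pipeline linking watershed land use to stream water
quality and benthic macroinvertebrate condition via recursive path analysis
(all-observed structural equation modelling).

## What it does

- **`streamsem.bmi_index`** — Benthic Macroinvertebrate Index scoring from
  per-taxon saprobic values `s`, frequencies `h`, and indicator weights `q`:
  `(4 - sum(s*h*q)/sum(h*q)) * 25`, on the 0–100 scale.
- **`streamsem.path_model`** — the core estimator: a line grammar for path
  models (`A -> B`, `A ~~ B`, optional `= value` to fix a parameter),
  implied-covariance algebra `(I-B)^-1 Psi (I-B)^-T`, maximum-likelihood
  fitting of free parameters to a sample covariance/correlation matrix with
  standard errors, critical ratios and p-values from the numerical Hessian,
  and direct / indirect / total effect decomposition.
- **`streamsem.fit_indices`** — NFI, TLI, CFI, GFI, AGFI, RMSEA against an
  independence baseline, with inclusive pass/fail thresholds
  (≥ 0.90 / RMSEA ≤ 0.05).
- **`streamsem.preprocessing`** — descriptive statistics, exact
  Kolmogorov–Smirnov normality screening (known-parameter and Lilliefors
  variants), natural-log transformation with scale-aware zero handling, and
  z-standardization.
- **`streamsem.refinement_pipeline`** — the full workflow: preprocess → fit
  the hypothesized model → indices → stepwise pruning of structural paths
  with |C.R.| < 1.96 → refit → indices → effects, with plain-text and JSON
  reports.
- **`streamsem.synthetic_data`** — linear-Gaussian simulation from any fully
  specified recursive path model, raw-scale marginal mapping
  (affine / method-of-moments lognormal), and taxa tables that reproduce a
  target BMI score exactly. Bundled example targets and the six-variable
  land-use/water-quality model live in `streamsem.presets`.

## CLI

```sh
# simulate 111 sites from the bundled refined population model
streamsem simulate --n 111 --seed 42 --raw --out sites.csv

# score BMI from a long-format taxa table (site,taxon,s,h,q)
streamsem bmi --taxa taxa.csv --out bmi.csv

# descriptive statistics
streamsem describe --csv sites.csv

# log-transform + standardize
streamsem preprocess --csv sites.csv --log bod,tn,tp,urban_pct,agri_pct --out prepped.csv

# fit a model spec to a site table
streamsem fit --csv prepped.csv --model model.txt

# full pipeline from a config file
streamsem run --config run.yaml
```

A minimal `run.yaml`:

```yaml
simulate:
  n: 111
  seed: 42
log_vars: []        # empty: data are already standardized
threshold: 1.96
outdir: out
```

With real data, replace the `simulate` block by `sites_csv: sites.csv`
(columns `site_id,urban_pct,agri_pct,bod,tn,tp,bmi`) and optionally
`taxa_csv: taxa.csv` to compute the `bmi` column from taxa records.

## Model spec grammar

```
# paths:            source -> target   [= fixed value]
# (co)variances:    a ~~ b             [= fixed value]
urban_pct -> bod
agri_pct -> bod
bod -> bmi
urban_pct ~~ agri_pct
```

Exogenous variables (no incoming path) get free variances automatically;
endogenous variables get one free residual (structural-error) variance each.
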