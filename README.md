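# bodycomp

How well do the anthropometric indices used throughout epidemiology — body
mass index (BMI), waist circumference (WC) and hip circumference (HC) —
predict what they are proxies for: the actual volumes of body fat and muscle
compartments measured by whole-body MRI? And what does imperfect prediction
do to relative-risk estimates that use anthropometry in place of, say,
visceral fat?

`bodycomp` is a reusable, tested implementation of the statistical pipeline
of a large MRI validation study (≈600 men and ≈600 women, two centers, three
10-year age bands), together with a calibrated synthetic-cohort generator so
that every stage runs and is testable without any data download. It is aimed
at epidemiologists and biostatisticians working on validation/calibration
studies and measurement-error correction.

## The statistics at the core

* **Residual-method adjustment** — every predictor and outcome `v` is
  replaced by the residuals of `v ~ age + height` within sex, so downstream
  associations are free of body-size and age variation (BMI included: within
  sex, raw BMI still correlates ≈0.2 with height).
* **Correlation machinery** — Pearson matrices with Fisher-z CIs
  (`tanh(atanh r ± z_{1−α/2}/√(n−3))`); multiple R² directly from a
  correlation matrix (`R² = cᵀR⁻¹c`); signed partial correlations via the
  R²-increment (type-II SS) identity `r_p² = (R²_full − R²_red)/(1 − R²_red)`,
  cross-checked against the precision-matrix route; eigenvalue repair for
  near-PSD printed matrices.
* **Regression engine** — per-sex OLS of each MRI compartment on BMI+WC+HC,
  partial correlations with CIs, variance inflation factors, and Harrell-style
  bootstrap optimism correction of R² (B=100).
* **Attenuation** — under classical measurement error with a log-linear risk
  model, a proxy explaining a fraction R² of exposure variance attenuates the
  log relative risk by exactly that R²; verified by direct simulation.
* **Synthetic cohorts** — 12-stratum design; published mean/min/max marginals;
  Gaussian-copula shifted-gamma residuals calibrated so the age/height-adjusted
  correlation matrices converge to the published 9×9 targets while
  `TAT = VAT + SAT + CAT` and `TBV = TAT + SMT + rest` hold exactly for every
  record and all volumes stay positive.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 0      # 1,200 records, 1,159 usable
python analysis/02_adjust_and_correlate.py
python analysis/03_prediction_models.py
python analysis/04_bootstrap_validation.py
python analysis/05_attenuation.py
```

Stage 3 prints, for the seed-0 cohort (n = 581 men, 578 women):

```
male (n=581):  outcome  R2%  best predictor (partial r)
   TBV:  92%   BMI (+0.66 [+0.61, +0.70])
   TAT:  83%   WC (+0.48 [+0.41, +0.54])
   SAT:  80%   HC (+0.35 [+0.28, +0.42])
   VAT:  64%   WC (+0.46 [+0.40, +0.53])
   CAT:  44%   WC (+0.35 [+0.27, +0.42])
   SMT:  45%   BMI (+0.53 [+0.46, +0.58])
```

the study's central finding in miniature: anthropometry predicts aggregate
compartments (TBV, TAT, SAT) very well, but visceral and coronary fat and
muscle much less well, with WC the best single predictor of VAT. Stage 4
shows overfitting is negligible at this scale (corrected R² ≈ 0.6 pp below
apparent), and stage 5 quantifies the consequence: with a VAT calibration
R² of 0.65, a true relative risk of 1.5 per SD of VAT is observed as ≈1.28
when anthropometry stands in for MRI.

The same pipeline is scriptable via the CLI: `bodycomp simulate`,
`bodycomp analyze cohort.csv`, `bodycomp attenuate --r2 0.65` (global flags
`--config/--seed/--out/--sex/--bootstrap-reps/--alpha`).

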