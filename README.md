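# accmeta

Meta-regression of classification accuracies across gene-expression studies.

Published microarray classification studies report wildly different
accuracies, and only part of that spread is sampling noise.  `accmeta` is for
biostatisticians who want to ask *why*: it models the reported accuracies of
many studies jointly and quantifies how much of the between-study variation
is attributable to study-level factors — the disease category, the medical
question (diagnostic / prognostic / response-to-treatment), the microarray
colour system, training-set size, the cross-validation technique, the
gene-selection strategy, the classifier family, and the number of genes in
the final model.

## Model

Each published classification model *j* from study *D* contributes a grouped
binomial outcome: out of n<sub>Dj</sub> evaluated samples, a<sub>Dj</sub>
were classified correctly.  The model is a random-intercept logistic
regression on the log-odds scale,

    a_Dj ~ Binomial(n_Dj, pi_Dj)
    logit(pi_Dj) = x_Dj' beta + b_D,        b_D ~ N(0, sigma^2)

where x<sub>Dj</sub> collects the study factors and b<sub>D</sub> is a
study-level random intercept inducing within-study correlation.  Because raw
accuracy is biased toward the majority class, the class-imbalance level
(majority-class share of the training set) is forced into every model as a
correction covariate.

Estimation maximizes the marginal likelihood — the binomial likelihood
integrated over b<sub>D</sub> — by adaptive Gauss–Hermite quadrature centred
at each cluster's conditional mode (one node = Laplace approximation, the
default).  On top of the fitter the package provides:

* **Univariable scan** — null model (intercept + imbalance) vs null + one
  factor, compared by AIC and likelihood-ratio test.
* **Backward elimination** — from the full eight-factor model, repeatedly
  delete the factor whose removal lowers AIC most; the imbalance covariate
  is exempt.
* **Explained variation** — total = (σ²_null − σ²_full)/σ²_null; each
  factor's relative contribution is (σ²_{−k} − σ²_full)/σ²_null from
  leave-one-factor-out refits, all on the log-odds scale.
* **Jackknife stability** — the whole selection is replayed with each study
  left out; agreement is the share of runs selecting the full-data set.
* **Synthetic corpora** — a generator with the exact statistical structure
  above, used for parameter-recovery and selection-stability validation.

## Data

The original row-level study table behind the published 48-study corpus is
not redistributable.  `data/synthetic_study_table.csv` is a deterministic
**synthetic stand-in** (built by `analysis/01_build_study_table.py`) that
reproduces the published corpus structure exactly where it is printed — 48
studies, 61 model rows, and the medical-question × cross-validation cell
counts with their mean accuracies — while all remaining fields are filled
deterministically with realistic values.  Model-based outputs on this table
are therefore *not* expected to equal the published ones.

## Worked example

```bash
accmeta all --input data/synthetic_study_table.csv --outdir out --seed 1
```

writes the scan, elimination trace, variance decomposition, jackknife table
and crosstab as CSVs plus a run log.  The same steps as numbered scripts:
`analysis/01…07`.  On the shipped table, `analysis/04_backward_elimination.py`
ends with

```
retained factors: medical_question, cv_technique (+ forced imbalance)
...
  intercept: 3.056232 (se 0.517135)
  imbalance: -1.461519 (se 0.698997)
  medical_question[prognostic]: -0.014841 (se 0.233981)
  medical_question[response-to-treatment]: -0.805950 (se 0.158338)
  cv_technique[single]: 0.490268 (se 0.134351)
```

i.e. on this corpus the medical question and the cross-validation technique
carry the signal: response-to-treatment questions run about 0.81 log-odds
below diagnostic ones, and single (non-nested) cross-validation inflates
accuracy by about 0.49 log-odds.  `analysis/06_jackknife.py` reports that
removing any single study leaves that selection unchanged
(`agreement: 1.000`), and `analysis/07_parameter_recovery.py` validates the
estimator on synthetic corpora (bias of the factor effect ≈ 0.008, 95%-CI
coverage 0.95 over 200 replicates at 200 studies).

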