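# csbn — Conditional Survival Bayesian Networks

Clinical survival models built by regression (Cox proportional hazards and
friends) cannot score a patient whose predictor values are partially
missing: every covariate in the linear predictor must be observed or
imputed first. `csbn` implements a hybrid that removes the imputation step.
A discrete Bayesian network learned over the clinical covariates carries
their joint distribution, and a **survival node** `E` attached to the
Cox-selected predictors carries the functional conditional distribution

```
P(E = 1 | x, t)  =  1 − S0(t) ^ exp(x·β)
```

where `β` are the multivariable Cox coefficients and `S0` the Breslow
baseline survival. For a patient with missing predictors, likelihood
weighting over the covariate network marginalizes the unobserved parents,
yielding a horizon survival probability

```
P(E = 0 | evidence, t)  =  E[ S0(t) ^ exp(x·β) | evidence ]
```

with a Monte-Carlo standard error, and no imputed dataset anywhere. The
package is aimed at biostatisticians building prognostic models on EHR-style
cohorts with routinely incomplete covariates.

## What is inside

| module | contents |
| --- | --- |
| `csbn.cohort_io` | cohort CSV + YAML schema handling, age-bin / tertile discretization, complete-case splitting |
| `csbn.cox_core` | Newton–Raphson Cox partial likelihood (Breslow ties), Breslow baseline, hazard-ratio tables, univariate screen |
| `csbn.lasso_cox` | L1-penalized Cox path (proximal Newton + coordinate descent), tenfold CV, 1-SE rule |
| `csbn.bayesnet` | tabu-search structure learning (BIC), bootstrap arc-strength model averaging, MLE CPTs, likelihood weighting |
| `csbn.model` | survival-node attachment, prediction under partial evidence, full training pipeline, JSON model files |
| `csbn.benchmark` | synthetic-cohort generator (log-normal events, Weibull censoring, MCAR missingness) and the CSBN vs impute-then-Cox experiment |
| `csbn.evaluate` | horizon AUC with censoring exclusion, Harrell C, calibration deciles, decision curves |

## Worked example

```python
import numpy as np
from csbn import (Cohort, VariableSpec, PipelineConfig,
                  train_from_cohort, predict_survival_probability)
from csbn.benchmark import default_simulation_config, generate_cohort

# a synthetic 6000-patient lung-cancer-style cohort, split 1:1
config = default_simulation_config(N=6000, seed=7)
dataset = generate_cohort(config, replicate_seed=7)

model = train_from_cohort(dataset.train, config.pipeline)
print(model.provenance["selected"])

# a patient with only three observed predictors
evidence = {"stage": "III", "smoking": "Current", "age": "(59,74]"}
p, se = predict_survival_probability(model, evidence, t=3.0,
                                     samples=10_000, seed=1)
print(f"3-year survival {p:.3f} (MC se {se:.4f})")
```

Output from this exact script:

```
['gender', 'age', 'smoking', 'COPD', 'stage', 'targeted_therapy', 'ILD', 'respiratory_failure', 'fibrinogen', 'radiotherapy', 'chemotherapy', 'pleural_effusion', 'eosinophil']
3-year survival 0.588 (MC se 0.0018)
```

The pipeline screened the covariates univariately (p < 0.05), learned the
covariate network with bootstrap-averaged tabu search, selected the
predictor set by LASSO-Cox at the 1-SE lambda (13 predictors here), refit
the unpenalized Cox model and attached the survival node. A stage-III
current smoker aged 60–74 whose remaining predictors are unknown gets a
3-year survival probability of about 0.59 by marginalizing those
predictors through the network — no imputation, and the Monte-Carlo error
of the estimate is reported alongside.

There is also a CLI for shell use:

```bash
csbn prepare  --input cohort.csv --schema schema.yaml --out prepared/
csbn train    --input cohort.csv --schema schema.yaml --out model.json
csbn predict  --model model.json --input patients.csv --schema schema.yaml --out pred.csv
csbn evaluate --model model.json --input test.csv --schema schema.yaml --out metrics/
csbn simulate --reps 20 --out results/
```

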