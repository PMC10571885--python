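# ndeepsurv

Recurrent survival deep learning for low-event-rate censored cohorts.

Large health-examination cohorts follow initially healthy subjects for
years and record whether and when a rare event — e.g. a site-specific
cancer diagnosis — occurs. Most subjects are right-censored, per-site
event rates are often below 2%, and follow-up time is only known to the
calendar year. This package provides a family of hazard-risk models for
such data, from the classical Cox proportional-hazards regression to an
LSTM-based network (nDeep) and its multitask variant, together with the
full evaluation machinery: a composite training loss, Harrell's
concordance index, nested hyperparameter tuning with cross-validated
bootstrap scoring, permutation feature importance, and a synthetic
cohort simulator with known ground truth.

## Models

All models map a subject's covariate vector *x* to a scalar hazard risk
score per event type (higher = earlier event expected):

- **Cox PH** — linear risk β·x, with β maximizing the Breslow partial
  likelihood by damped Newton–Raphson.
- **DeepSurv-style MLP** — feed-forward ReLU network (dropout,
  batch-norm, weight decay available), scalar risk head.
- **DeepHit-like multitask net** — shared fully connected layers plus
  one sub-network per task, each receiving the raw input through a
  residual connection.
- **nDeep** — the subject's (single-visit) covariate vector is unrolled
  into an *n*-step sequence, processed by three stacked LSTM layers; the
  final hidden state feeds one fully connected layer that outputs the
  risk.
- **multitask nDeep** — a shared FC block feeding *K* task-specific
  nDeep stacks, each with an input residual connection.

Networks are trained by minibatch gradient descent on the composite loss

```
L = L1 + λ·L2
L1 = −Σ_{i: E_i=1} [ r_i − log Σ_{j: T_j ≥ T_i} exp(r_j) ]      (Cox partial likelihood)
L2 = Σ_{(i,j) acceptable} exp(−(r_i − r_j)/σ)                    (ranking loss)
```

where an *acceptable pair* (i, j) has subject i's event observed
strictly before subject j's time. Accuracy is Harrell's c-index: the
fraction of acceptable pairs ranked correctly by risk (0.5 = chance,
1 = perfect), with 0.5 credit for risk ties.

The neural networks run on a small reverse-mode automatic
differentiation engine over numpy included in the package
(`ndeepsurv.autodiff`), verified against central finite differences.

## Worked example

```python
import numpy as np
from ndeepsurv import (SimulationConfig, simulate_cohort, split_train_test,
                       ModelSpec, OptimizerConfig, train_model, concordance_index)

beta = np.zeros((10, 1)); beta[:3, 0] = [1.0, -1.0, 0.7]   # 3 informative of 10 features
cfg = SimulationConfig(n=4000, d=10, beta=beta, baseline_rate=0.011,
                       followup_years=10, seed=0)
ds, _ = simulate_cohort(cfg)                     # ~20% events at the 10-year horizon
train, test = split_train_test(ds, seed=0)       # stratified 4:1 split

spec = ModelSpec(kind="ndeep", lstm_hidden=16, n_lstm_layers=3, n_steps=4)
model = train_model(spec, train, seed=0,
                    opt_cfg=OptimizerConfig(lr=1e-3, batch_size=256, epochs=30))
c = concordance_index(model.predict_risk(test), test.T, test.E[:, 0])
print(round(c, 3))
```

prints

```
0.823
```

i.e. the network ranks ~82% of comparable subject pairs in the order
their events actually occurred, recovering the planted
proportional-hazards signal (the Cox fit on the same data reaches
~0.83; chance is 0.5). The `examples/` directory contains one short
script per capability — simulation + preprocessing, the Cox baseline,
nDeep training, multitask competing risks, and the nested benchmark
with permutation importance — each printing the numbers it computes.

A thin CLI mirrors the analysis stages:

```
ndeepsurv simulate --n 2000 --seed 1 --out cohort.csv --truth-out truth.json
ndeepsurv preprocess cohort.csv --schema schema.yaml --out clean.csv
ndeepsurv benchmark clean.csv --schema schema.yaml --models coxph,ndeep --out report.csv
```

## Layout

- `src/ndeepsurv/dataset.py` — data model, CSV I/O, derived biomarkers
  (BMI, pulse pressure, albumin/globulin ratio, creatinine clearance),
  sequence construction
- `preprocess.py` — left-censoring / 6-SD outlier / missingness filters,
  leakage-free imputation
- `autodiff.py`, `nn.py` — tensor engine, layers, Adam
- `losses.py`, `metrics.py` — composite loss, c-index
- `models.py` — the five model kinds and the training loop
- `workflow.py` — splits, TPE hyperparameter search, bootstrap scoring,
  nested cross-validated benchmark
- `importance.py` — permutation feature importance
- `simulate.py`, `studies.py` — cohort generator and canned studies
- `docs/methods.md` — modelling assumptions, defaults, and limitations
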