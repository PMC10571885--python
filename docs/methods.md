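# Methods

## Data model and time scale

A cohort is a subjects × features covariate matrix `X` (NaN = missing),
a follow-up time vector `T` in **whole years** (diagnosis year or exit
year minus enrolment year), and a 0/1 event indicator matrix `E` with
one column per event type. Calendar-year resolution means heavy ties in
`T`; every component is written for tied data (Breslow denominators in
the partial likelihood, strict-inequality acceptable pairs, 0.5 tie
credit in the c-index).

## Preprocessing pipeline

Fixed order: (1) drop rows with negative follow-up time
(left-censored / inconsistent records); (2) remove rows with any
feature more than 6 SD from its mean — means/SDs computed once on the
full input to this stage, a single pass, zero-SD features skipped;
(3) drop features with ≥ 25% missing cells (strictly-below-25%
retained); (4) impute remaining missing cells with per-feature medians
(mean optional). Two leakage conventions coexist deliberately: the
outlier filter sees the whole sample (it precedes any split, mirroring
a filter-then-model pipeline), while imputation statistics are always
fit on training rows only. The SD filter is not idempotent (removing
rows changes means/SDs); re-running the pipeline may remove a few more
rows, which the exclusion reports make visible. Reports reconcile
exactly: `n_in = n_out + n_removed` at every step.

Derived clinical biomarkers (computed before filtering when requested):
BMI = WT/(HT/100)² (height in cm), pulse pressure = SBP − DBP,
albumin/globulin ratio, and Cockcroft–Gault creatinine clearance
(140 − AGE)·WT/(72·CREAT), ×0.85 for women (sex coded 1 = male,
2 = female). Non-positive denominators yield a missing value and are
counted in a report rather than raising.

## Losses

Training minimises `L1 + λ·L2` (default λ = 1, i.e. a plain sum):

- `L1` — negative log Breslow partial likelihood of the risk scores,
  risk set `R(t) = {j : T_j ≥ t}`, log-sum-exp stabilised by shifting
  with the detached maximum. Undefined (error) without events;
  shift-invariant in the scores.
- `L2` — `Σ exp(−(r_i − r_j)/σ)` over acceptable pairs (default
  σ = 1), computed via a factorisation `e^{−r_i/σ}·Σ_j e^{r_j/σ}` with
  detached mean-centring, O(n·events) rather than O(n²).

The ranking loss is defined directly on the scalar risk score: these
models emit one hazard score per subject and task, so risk ordering is
the natural (and only available) ranking surrogate for cumulative
incidence ordering. For optimisation the per-batch loss is divided by
the batch size — a constant scale that decouples the learning rate from
the batch size and changes no minimiser.

## Architectures

- **LSTM recurrence** — standard gates: logistic activations for
  forget/input/output gates (codomain (0,1)), tanh for cell input and
  output (codomain (−1,1)); `h_0 = c_0 = 0`. Input matrices are h×d;
  recurrent matrices are h×h — they multiply the previous hidden state,
  so a non-square recurrent matrix is rejected at construction.
- **Sequence construction** — with one examination visit per subject,
  the visit vector is replicated across `n_steps` steps (default 4, a
  tunable hyperparameter); the mask field leaves room for genuine
  multi-visit sequences, which no current operation exploits.
- **Residual connections** — task-specific blocks in the multitask
  models receive the raw input concatenated to the shared
  representation (dimension-safe for unequal widths); additive residual
  and no-residual ablation are config switches. The DeepSurv-style MLP
  deliberately has no residual path.
- **Initialisation** — uniform ±1/√fan-in; all randomness (init,
  shuffling, dropout) flows from one seeded generator, so a (spec,
  config, seed) triple reproduces training bit-for-bit.

## Cox baseline

Damped Newton–Raphson on the Breslow partial likelihood: analytic
gradient and information matrix accumulated over time-sorted risk sets,
step-halving to guarantee ascent, convergence at gradient norm < 1e-6
(cap 100 iterations). Complete separation is detected two ways: a
diverging coefficient norm, and a partial likelihood saturating at 1
(every risk set perfectly ordered); both raise with a suggestion to
regularize. A constant covariate has zero gradient at β = 0 and
converges there immediately.

## Evaluation protocol

Outer loop: event-stratified K-fold cross-validation (default 5 folds,
so each fold is a 4:1 split — this reconciles the single-split and
5-fold descriptions of the protocol); a single stratified 4:1 split is
also available. Stratification on the target task's event indicator is
essential at sub-2% event rates, where unstratified splits routinely
produce event-free partitions. Inner loop per fold: a validation subset
(p = 0.2) is sampled from the training rows; hyperparameters are tuned
on validation c-index with a Tree-structured Parzen Estimator (default
60 trials; random search available) — tuned per fold, which is the
leakage-free reading of the protocol; the tuned model is refit on the
fold's training rows. Scoring: the held-out fold is resampled with
replacement 30 times and the c-index averaged over resamples (mean and
sample SD reported); resamples without acceptable pairs are skipped and
logged. Imputation statistics, tuning and training never see test-fold
rows.

The in-package TPE splits observed trials at the γ = 0.25 quantile into
good/bad sets, fits Gaussian kernel densities to each (log-scale for
log-uniform dimensions, smoothed frequencies for categoricals), and
proposes the candidate maximising the good/bad density ratio among 24
draws, after 10 random startup trials.

## Permutation feature importance

Score = baseline c-index − mean c-index over `n_repeats` (default 10)
evaluations with that feature's column freshly shuffled, all other
columns intact. Computed on held-out data by default so a score
reflects generalisable reliance on the feature. Scores are not
additive and small negative values for irrelevant features are normal
sampling noise.

## Synthetic cohorts

The generator emulates the statistical structure the models assume:
standard-normal covariates (optional equicorrelation), per-task
proportional hazards `h(t) = h0 · exp(β·x)` with constant baseline
hazard (Weibull optional), administrative censoring at a follow-up
horizon (default 10 years), and observed times floored to whole years
(`round_to_years=True`) to mirror calendar-year follow-up. Baseline
rates for a target event fraction come from `calibrate_baseline_rate`
(closed form `−log(1−p)/horizon` under β = 0, common-random-number
Monte-Carlo bisection otherwise, tolerance 1e-3). Competing-risks mode
lets the first event censor the others — the realistic setting for
multitask benchmarks; without it, multitask indicators share a single
follow-up clock and are only an approximation intended for single-task
use. Planted gross outliers (values at 8 SD) and missing cells are
recorded in the truth object so preprocessing can be audited exactly.

What the generator does *not* emulate: the covariance and marginal
shapes of real clinical biomarkers, informative (non-administrative)
censoring, secular trends, or multi-visit trajectories. Passing the
simulation studies therefore shows the algorithms are implemented
correctly and behave as the theory predicts under their own
assumptions — not that any model attains a particular accuracy on real
cohort data.

**Calendar-year rounding and Cox consistency.** Flooring ~70%-event
continuous times into ~10 year bins creates massive ties; under the
Breslow convention this attenuates fitted Cox coefficients by roughly
0.2 at |β| = 1, an asymptotic bias, not a finite-sample one.
Coefficient-recovery studies therefore use `round_to_years=False`
(continuous times), where the estimator is consistent; the rounded mode
remains the default because it is the realistic study condition for
*ranking* models, and c-index-based comparisons are unaffected by the
attenuation.

## Study problem sizes

The canned studies in `ndeepsurv.studies` use desk-scale settings
chosen once: null calibration at n = 2000 (event rate ≈ 18%, 15
epochs), signal detection at n = 4000 with 3 informative of 10 features
and ~20% events (30 epochs, 16 hidden units), Cox recovery at n = 2000
with ~30% censoring, importance discrimination at n = 2000 with 10
permutation repeats, and a reduced benchmark (2 folds, 3 repeats, 5 TPE
trials, 2 competing-risk tasks). Model performance is scored on an
independently simulated evaluation cohort of the same size and law —
for a simulation study this is the gold standard: it is exactly the
generalisation error under the generative law and has lower variance
than a 400-row held-out split. Event rates in the studies (15–25%) are
far above the motivating cohort's (0.2–2.2%): rare-event rates at
n ≈ 2000 leave too few events to train or even to score stably, and the
properties under test (chance-level calibration, signal recovery,
importance ranking) do not depend on the rate. The simulator reproduces
the rare-event regime when asked (see `calibrate_baseline_rate`).

## Known limitations

- Single-visit sequences only: the replication scheme is one reading of
  how a static vector becomes an n-step sequence; genuinely
  longitudinal records are out of scope.
- Breslow ties only (no Efron correction); time-constant covariates in
  the risk set.
- Minibatch training uses within-batch risk sets — a standard, slightly
  biased approximation of the full-cohort partial likelihood;
  full-batch mode exists for small n.
- The numpy networks are CPU-oriented; widths beyond a few hundred
  units or very long sequences will be slow.
- Checkpoint serialisation of network weights is not implemented; a
  fitted model lives in process (refit from seed is exact).
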