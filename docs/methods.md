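# Methods

`wardhmm` models older-adult inpatient admission episodes (AEs) as daily
sequences of latent clinical states. This note records the model, the
pipeline conventions, the synthetic-cohort design, and the numerical and
design choices a maintainer would want to know. Every number quoted here is
computed by the test suite or by `scripts/acceptance.py`; nothing is copied
from external results.

## The model

Each admission episode is a multivariate time series: one row per day, 23
columns (17 blood tests and the bedside vital signs, with blood pressure
entering as systolic and diastolic readings). Days are modelled by a hidden
Markov model with multivariate Gaussian emissions:

- initial state distribution π (length K),
- row-stochastic transition matrix A (K×K),
- per-state emission mean μ_k (length 23) and **full** covariance Σ_k.

The model is unsupervised: it sees only the (normalized, imputed) episode
matrices. Outcomes, diagnoses and phenotypes are held out and used
afterwards to interpret the fitted states. Parameters are estimated by
Baum-Welch EM; per-day states are assigned by Viterbi decoding (posterior
argmax is available via `decode(..., method="posterior")` — the two
disagree only at state boundaries, and the default follows the convention
of assigning the jointly most probable path). All recursions are in log
space: with 23 correlated dimensions, scaled arithmetic underflows on long
episodes.

EM details: k-means initialization of means (within-cluster covariances,
uniform π, 0.8 self-transition boost on A), `n_restarts=3` keeping the best
final log-likelihood, relative-improvement stop at `tol=1e-4`,
`max_iter=200`, ridge `cov_reg=1e-6·I` on every covariance update. A state
whose responsibility mass vanishes is re-seeded from a random pooled day
and logged in the fit report. Emission densities are evaluated through
Cholesky factors; parameter validity (stochastic rows, SPD covariances) is
checked by `HMMParameters.validate`.

## Pipeline conventions

**Daily binning.** Events are binned into calendar days from admission
(day 0 internally, "Day 1" in all reports). A blood test observed more than
once in a day keeps the earliest record. A vital sign observed several
times keeps the record nearest in time to the day's earliest blood draw —
the blood draw anchors the day's clinical snapshot — falling back to the
earliest vital record on days without blood tests. Events timestamped
before admission are rejected and counted.

**Rich and poor days.** A day is *rich-information* iff at least 14 of the
17 blood tests and at least 4 vital signs were observed; otherwise
*poor-information*.

**Inclusion rules**, applied in this order with one logged reason per
exclusion: first episode per patient only → length ≥ 3 days → first and
last day rich → poor days strictly fewer than ⅓ of the length (2 poor days
in 6 is excluded; 2 in 7 is kept).

**Split.** Patient-level 80/20 train/hold-out split (`round(0.8·n)`), so
11,158 patients split into 8,926/2,232.

**Normalization.** Per variable, inverse-rank-normal scores with the Blom
offset, Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks for ties, fitted on
training data only. Hold-out values are mapped by interpolating the fitted
value→score curve, clamped at the training extremes, so the hold-out set
never contributes ranks. A constant training variable maps to 0 with a
warning. Missingness masks are never altered by normalization.

**Imputation** is two-step and produces m = 10 completed datasets.
*Step 1 (rich days):* chained-equation multiple imputation with predictive
mean matching over the pooled rich-day rows. Predictors per target: the
other 22 variables minus those with |Pearson r| > 0.8 against the target,
minus candidates in the worst decile of missing fraction, minus those whose
missingness indicator has |φ| > 0.8 with the target's; age, sex and
admission diagnosis are always included (an optional discharge-specialty
column is supported but absent from the minimal synthetic phenotype).
Variables are visited in decreasing-missingness order for 10 sweeps;
each missing cell receives the observed value of a donor drawn uniformly
from the 5 nearest fitted values (type-0 PMM: deterministic OLS
coefficients; the method was specified without hyperparameters, and the
donor mechanism — imputed values are always observed values — is the
property downstream code relies on). *Step 2 (poor days):* per-variable
linear interpolation in day index within the episode, independent of other
variables and patients; inclusion guarantees rich (hence complete) first
and last days, so every poor-day cell has flanking values. Per-cell
provenance ({observed, MI, LI}) is tracked, and observed cells are never
modified. Downstream model fitting uses completed dataset 1 by default
(configurable); an insensitivity check across imputations is part of the
test suite's scope only through decoding agreement, since fitting m full
models per run is not informative at synthetic scale.

## State-space size selection

K is chosen by 2-fold concordance: split the training patients in half,
fit one model per half, decode the *entire* cohort with both, count the
K×K patient-day co-occurrence matrix, match labels with the Hungarian
algorithm, and score the matched fraction. The selected K is the largest
grid value scoring ≥ 0.8 (configurable) — the aim is a state space both
reproducible and large enough to capture heterogeneity. If nothing clears
the threshold the argmax-score K is returned with a warning. The default
production grid ends at K = 17.

The same machinery maps states between models trained on different
datasets: Hungarian matching on hold-out co-occurrence, with a matched pair
voided ("unmapped") when its co-occurrence is below 1% of patient-days, and
the Pearson correlation of the concatenated matched mean vectors as the
agreement summary.

**Why the selection study plants an exchangeable truth.** Stability-based
selection has a documented failure mode: if one planted state is elongated
(anisotropic covariance), a (K+1)-state model splits that state along its
principal axis — a *population* property, identical in both folds — so the
spurious extra state reproduces and the concordance score stays high.
Conversely a state with very small occupancy can be missed by one fold.
The state-count recovery study therefore plants K_true = 4 with spherical
covariances (no preferred split axis, so an extra state is genuinely
non-identifiable) and a skewed stationary occupancy (0.45/0.20/0.20/0.15,
mirroring the uneven state frequencies of real cohorts), separation 4,
100 episodes of mean length 8. Under these conditions the concordance
curve is near 1 up to K = 4 and drops clearly below the 0.8 threshold
beyond it. Cohort generator *defaults* are unchanged (random full
covariances, Dirichlet occupancies).

## State interpretation

A patient's *main state* is the modal state over the episode's days, ties
broken in favour of the tied state occurring earliest. Main states are
cross-tabulated against a categorical label (outcome or admission
diagnosis); the global statistic is the Pearson chi-square, and per-cell
evidence is the standardized Pearson residual
r_ij = (O−E)/√(E(1−row_i/N)(1−col_j/N)), approximately standard normal
under independence. A cell is significant when its two-sided normal
p-value clears α/(K·C) with α = 0.001 — Bonferroni over the table's cells,
the family that matches per-cell significance boxing (raw (O−E)/√E
residuals are not comparable to a normal reference, which is why the
standardized form is used). Cells with zero expected count are
non-testable. Reporting labels 'a', 'b', … are assigned by descending state
frequency within the inpatient-mortality group; internal indices stay
integers.

## Outcome prediction benchmark

Features come from the first three admission days only: either the 23
daily values per selected day ("mvts") or a one-hot state indicator per
selected day ("states"), optionally plus phenotypes (age and CFS numeric,
sex and diagnosis one-hot in fixed category order). Tuning is nested inside
the training cohort: 80/20 inner split, 5-fold cross-validated grid search
on the inner-train part (logistic: penalty strength over 1e-3…1e3; random
forest: trees {100, 300}, depth {None, 5, 10}, features/split {√p, 0.3},
min-split {2, 10}, min-leaf {1, 5}, bootstrap {on, off}), scored on the
inner 20%, repeated 10 times with distinct sub-seeds. The best-scoring
configuration is refitted on the full training cohort and scored once on
the untouched hold-out. Multiclass problems use one-vs-rest AUC, and the
*weighted* ROC-AUC is the class-prevalence-weighted mean of the one-vs-rest
AUCs. `tune_and_evaluate` refuses overlapping train/test indices, which is
the leakage guarantee the tests assert.

**Benchmark generative design.** If episode outcomes depend *only* on the
discrete latent states and decoding is nearly perfect, the one-hot decoded
state is an oracle feature — Viterbi even smooths over the whole episode,
so a day-3 state summarizes evidence from later days — and the states
representation wins. That is the opposite of what happens with real
patients, whose risk varies with the continuous physiology within a state.
The benchmark cohort therefore plants mortality as trajectory plus
presenting acuity: the log-odds of inpatient mortality are
base + mean_t(state logit) + w·mean_{t≤3}(x_t), with weights w on four
acute-physiology variables (neutrophils, urea, respiratory rate, pulse
rate) whose values also carry a persistent per-patient baseline offset
(`patient_effect_sd`, restricted to those variables — between-patient
heterogeneity such as chronically raised urea). Early raw values then
carry continuous risk information that no discrete state sequence can
represent, and the mvts-vs-states ordering is a genuine consequence of
compression rather than an artefact. Benchmark conditions: 2,000 episodes,
K_true = 5, separation 3, self-transition 0.92, mean length 7, state-logit
scale 3.2, base −2.2, w = 1.5, offset SD 0.7. The outcome model's default
remains purely state-driven (`mortality_value_weights=None`,
`patient_effect_sd=0`).

## Synthetic cohorts: what they emulate and what they don't

The generator emulates: one admission episode per patient with length
3 + Poisson(mean−3); irregular timestamped events (blood tests ≤ 2/day, the
earliest carrying the day's latent value exactly and duplicates jittered
with σ = 1% of the variable SD, so the earliest-record binning rule is
consequential but near-lossless; vitals 1-8 events/day); per-variable-day
MCAR missingness (defaults: blood tests 0.92, vitals 0.98) producing a
realistic mix of rich and poor days, with a hook for state-dependent
missingness; phenotypes (age ≥ 65, sex with the female fraction ≈ 0.472,
CFS 1-9, a single-letter admission diagnosis drawn from the modal state's
affinity row); and outcomes causally linked to states through the logistic
mortality model, with survivors split DA/PDR/PDM/PDRM at 0.70/0.15/0.08/0.07.

It does **not** emulate: variable-specific physiological ranges or units
(values are rank-normalized downstream, so only the joint shape matters);
repeat admissions; informative missingness by default; measurement-device
error structure; or calendar effects. Passing tests therefore demonstrate
that the *pipeline machinery* is correct and that planted signals of
realistic strength are recovered — not that any particular clinical
finding generalizes.

## Numerical choices and degenerate inputs

- Log-space forward/backward/Viterbi; logsumexp for stability.
- Covariance ridge 1e-6; SPD checked by Cholesky; symmetrization after
  each M-step.
- Empty observation streams yield all-missing episodes; empty episodes and
  K > total days are errors.
- PMM donor pools shrink with a warning when a variable has fewer observed
  values than donors; a variable with no observed values is an error.
- Linear interpolation without a flanking value is a hard error (cannot
  occur after inclusion + MI).
- Ties: rank ties averaged; main-state ties broken by earliest occurrence;
  Viterbi argmax ties resolved by lowest state index (numpy argmax).
- Problem sizes in the test suite and acceptance script (cohorts of
  100-2,000 episodes, grids to K=8) are chosen as the smallest sizes at
  which the studied effects are comfortably detectable.

## Known limitations

- The 2-fold concordance score has no finite-sample null correction; its
  value under independence is slightly above 1/K because Hungarian
  matching optimizes over bijections.
- Type-0 PMM understates between-imputation variance relative to fully
  Bayesian PMM; the pipeline uses the m datasets for sensitivity, not for
  Rubin-rules pooling (out of scope).
- The HMM assumes imputation-completed inputs; there is no missing-aware
  emission marginalization.
- Letter labels depend on the mortality-group frequencies of the cohort at
  hand and are reporting sugar only.
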