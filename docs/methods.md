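# Methods

This note documents the models and procedures implemented in `edscore`, the
parameters that matter, and the choices made where the design was genuinely
open. It states no numbers that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Scores

**ROX** = SpO2[%] / FiO2 / RR, rounded *half-up* to the nearest integer.
"Nearest integer" leaves the half-way case ambiguous; half-up is pinned (and
tested at 7.5 → 8) to avoid banker's-rounding drift across platforms. Inputs
must be non-missing; scoring never imputes, and a missing input yields an
explicit missing marker, never a default. Domain: SpO2 ∈ (0, 100],
FiO2 ∈ [0.21, 1.0], RR > 0.

**NEWS** uses the 2012 Royal College of Physicians banding, shipped as a
versioned YAML asset (`charts/news_2012.yaml`) so that chart revisions are a
data change, not a code change. Bands are upper-edge-inclusive intervals and
partition the real line; a sweep test checks that every value in the
physiological bounds lands in exactly one band. Supplemental oxygen is
derived as FiO2 > 0.21 (2 points) — FiO2 is the only oxygen-therapy variable
in the data model — and "not alert" (roused only by voice/pain, or
unresponsive) adds 3 points. The NEWS2 hypercapnic SpO2 scale is out of
scope.

## Synthetic cohort generator

There is no public ED registry to run against, so the generator *is* the
study population for testing purposes. Construction:

- Latent severity `z ~ N(0,1)` per visit. Death within 24 h with probability
  `expit(α + β·z)`; β defaults to 2.0 log-odds per SD (a strong but
  realistic severity gradient for a mortality outcome this rare), and α is
  solved by Gauss–Hermite quadrature + Brent so the marginal death rate hits
  the target prevalence (default 0.7 %). A non-finite or |β| > 50 effect is
  rejected rather than clamped.
- Each vital's conditional mean is linear in `z`, with intercept and slope
  chosen so the *stratum* expectations (alive/dead) land exactly on the
  configured targets (defaults: SBP 143/133 mmHg, HR 85.9/95.5 bpm,
  RR 17.8/23.3 /min, SpO2 96.7/93.1 %, temperature 36.9/36.4 °C). Residual
  SDs are set so the marginal SD matches the configured total-population SD
  (the published table reports inconsistent stratum SDs for SBP; the total
  column is used). When β = 0 the strata coincide and the loading degenerates
  to the prevalence-weighted marginal mean with zero slope.
- Values are truncated to physiological bounds (SpO2 ≤ 100, SBP 40–280,
  RR 4–60, temperature 30–43) and rounded to recording precision (integers
  for SBP/HR/RR/SpO2, 0.1 °C, 0.01 FiO2). Truncation shifts post-hoc means
  slightly — most visibly SpO2, whose ceiling at 100 % absorbs the upper
  tail — so the stratum-mean tests compare against a truncation-adjusted
  quadrature oracle rather than the raw targets, and the SpO2 SD check uses
  a wider tolerance.
- FiO2 is 0.21 (room air) unless on supplemental oxygen; the supplemental
  probability is logistic in `z` with both coefficients solved so the
  stratum means hit their targets (0.24/0.38), and the amount above room air
  is a clipped Gamma tail. This reproduces the spike-at-0.21 shape (most ED
  patients breathe room air).
- Alertness is logistic in `z`, calibrated to 95.7 % alert among survivors
  and 50 % among deaths (chosen to match the observed-data pattern that most
  patients are alert while deaths frequently are not). ICU admission
  (marginal 5 %), disposition (70 % of survivors discharged; deaths always
  admitted, encoding the primary-analysis assumption that discharged
  patients survive 24 h), and auxiliary labs (urea 6.2/12.0 mmol/L,
  leukocytes 9.0/13.0 ×10⁹/L — chosen as realistic, they exist to give the
  imputation models signal) all load on the same `z`.
- Presentation dates are uniform over 2019-01-01..2021-03-01, putting about
  half the cohort before the 2020-02-01 split.
- Joint correlation among vitals is induced *only* through the shared latent
  severity; real vitals have residual correlation (e.g. HR–temperature) the
  generator does not model. Passing tests therefore demonstrate correctness
  of the pipeline machinery and qualitative realism, not distributional
  fidelity to any registry.

**Missingness.** Per-variable rates default to the published imputed-value
fractions (RR 19.7 %, temperature 12.4 %, FiO2 49.6 %, alertness 68.1 %,
SBP 1.5 %, HR 3.3 %, SpO2 2.5 %; auxiliary labs 30 %, a choice reflecting
that bloods are not drawn on every visit). Mechanisms: MCAR (independent
flips), MAR (more missing for younger and discharged patients), MNAR (less
missing at high severity, emulating that vitals are registered when patients
look ill). Under every mechanism the model's intercept is solved on the
cohort so the marginal rate equals the configured rate; the mechanism shapes
who is missing, not how much. Observed values are never altered, and the
whole generation is deterministic given the seed (byte-identical CSVs).

## Exclusion and imputation

Records missing ≥4 of the 5 classic vitals are excluded before imputation
(their missingness is treated as non-random; imputation is not attempted)
and logged; the rule is idempotent.

Imputation is chained equations, written in-house because the pinned
procedure — predictive mean matching with k = 5 donors for continuous
vitals, logistic draws for the alertness flag, a fixed number of sweeps per
chain, independent seed substreams per chain, the outcome included as a
predictor — is a specific protocol rather than the default of any installed
implementation. Each of the m chains (default m = 20, 5 sweeps) initialises
missing cells from observed marginals and then cycles variables in order of
increasing missingness; continuous targets use an OLS fit with an
approximate Bayesian coefficient draw, matching missing predictions to the
5 nearest observed-prediction donors (PMM type 1), which guarantees imputed
values stay inside the observed physiological range. Missing FiO2 for
patients without the oxygen-therapy indicator (ICU admission) is pre-filled
with 0.21 — room air was evidently the default recording assumption — and
only the remainder is model-imputed (flag `fio2_room_air_default`).

Pooling follows the plain-average rule (pooled estimate = mean of per-set
estimates); between-imputation variance and Rubin's total variance are
computed and retained but are not the primary path.

## Evaluation

- **AUC**: Mann–Whitney concordance with ties = ½ via midranks; variance by
  DeLong structural components (implemented directly; no installed package
  provides the variance, and `sklearn.roc_auc_score` serves as the
  independent cross-check in tests). CI: normal approximation, truncated to
  [0, 1]. The paired DeLong test uses the joint structural-component
  covariance; a self-comparison returns difference 0, p = 1.
- **Risk model**: per-set univariable logistic fit of death on the integer
  score (single linear term, score entered sign-free), Newton-solved at
  tolerance 1e-10, intercept and slope pooled by averaging. The
  score-equation identity (mean predicted risk = prevalence) holds per set
  to solver tolerance (~1e-8, asserted). A spline alternative was considered
  and rejected for the primary path: the single linear term is the simplest
  mapping consistent with pooling intercepts and slopes.
- **Calibration**: patients grouped per integer score value (the natural
  resolution of both scores); per group: count, mean model-predicted risk,
  observed death fraction. Groups under the minimum size (default 20 for
  reporting) are dropped from the table but reported as skipped.
- **Decision curves**: thresholds 0.001–0.100 in steps of 0.001, covering
  the clinically cited 3 % and 5 % landmarks while staying within the risk
  range that matters at 0.7 % prevalence; the threshold 1.0 is rejected
  (division by zero). Net benefit, standardized net benefit (÷ prevalence,
  so ≤ 1 always) and treat-all/treat-none references are computed per
  imputed set from that set's own fitted risks and averaged across sets
  (the alternative — pooling predictions first — was noted and not taken,
  to keep every surface per-set-then-averaged).
- Pooling of AUCs and DeLong statistics across sets follows the same
  plain-averaging rule: mean AUC with the mean DeLong variance, mean AUC
  difference over the mean difference-variance for the z statistic.

## Study orchestration

`ScoreComparisonStudy.fit` runs exclusion → imputation → scoring →
evaluation on four subsets: all, pre-pandemic (presentation strictly before
the split date), post-pandemic (the split day itself belongs to the later
period — "till" vs "after" leaves the day ambiguous, so it is pinned here),
and the sensitivity analysis. Risk models are refit per subset. The
sensitivity analysis flips exactly `round(0.0004 × n_discharged_survivors)`
discharged survivors to deaths (uniform, seeded) and re-evaluates with the
same imputations: the flip touches ~0.04 % of discharged records, far below
anything the imputation models could register, so re-imputing would only add
noise. With fraction 0 the sensitivity report equals the primary report
exactly.

Everything is deterministic given the run seed: generation, missingness,
each imputation chain and the sensitivity draw use independent named
substreams, and two identical runs produce byte-identical JSON reports.

## Problem sizes in the test suite

Tests scale the simulations to what the checks need: marginal-calibration
checks run at n = 30,000–200,000 (where 3 Monte-Carlo SEs are tight enough
to be meaningful), the MCAR imputation-bias check at n = 20,000 with m = 5,
type-I-error simulation at n = 2,000 × 1,000 replicates, and end-to-end
determinism at n = 6,000 with m = 2. These sizes are the package's own
choices balancing statistical resolution against runtime.

## Known limitations

- The generator's single latent factor cannot produce vital-sign
  correlations beyond severity, nor multimodal presentations (e.g. COPD
  hypercapnia); conclusions about real-data score performance do not follow.
- The pre/post-pandemic subsets differ only by date — the generator does not
  shift case mix at the split — so the split-sample analysis exercises the
  machinery, not a genuine distribution shift.
- The chart asset covers the classic NEWS only; AVPU granularity is
  collapsed to the alert/not-alert flag.
- DeLong inference is asymptotic; at very small n or extreme AUCs the
  bootstrap comparison in the tests shows the expected approximation error.
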