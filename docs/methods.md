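# Methods

## The choice model

Each AGT offer is a reward *R* ∈ {3, 6, 9, 12} apples for an effort
*E* ∈ {0.2, 0.4, 0.6, 0.8} of the participant's maximum voluntary
contraction (MVC). Offers are coded as r = R / 12 and e = E before
entering the value function

V(r, e) = K + LinR·r + R²·r² + LinE·e + E²·e² + R×E·r·e,

with any subset of terms present; the probability of accepting is the
logistic of V. The logistic link is a design choice: it is the standard
rule for binary effort-discounting choices, it makes the subject-level
likelihood a Bernoulli GLM, and parameter signs (K > 0 raising
acceptance, LinE < 0 penalising effort) then read directly in logit
units. No separate temperature or lapse parameter is included — with an
intercept and freely scaled coefficients, an inverse temperature would
not be identified.

The package's reference ("winning") model has four terms: K, LinR, LinE,
E². On this design LinE and E² trade off strongly — both are monotone
decreasing transforms of a four-point effort grid — so the constrained
variant clamps LinE at −15 (in logit units per unit coded effort) and
estimates K, LinR and E². With the default coding this constant produces
linear effort costs from −3 (at e = 0.2) to −12 (at e = 0.8), a plausible
magnitude against reward benefits of up to +LinR. The coding, the
constant and the term family are all configurable; `enumerate_model_family`
spans every subset of the optional terms (intercept mandatory) together
with the clamped variants, and always contains the four-term model and
its constrained form.

## Hierarchical estimation

Subject parameters are partially pooled: θᵢₚ ~ Normal(μ₍g(i,p)₎ₚ, σ₍g(i,p)₎ₚ).
The hyper-grouping follows the prior-sharing scheme: `pooled` (one
hyper-distribution per parameter for the whole sample), `split_on(p)`
(separate group-level distributions for the single parameter of interest,
shared for the rest — the case–control configuration, run one parameter
at a time by `run_group_scheme`), or `split_all` (the sensitivity
configuration). Hyperpriors are weakly informative on the coded logit
scale: μ ~ Normal(0, 10), σ ~ Half-Normal(5); both are configurable.

### Sampler

No general-purpose MCMC framework is used; the sampler is a blocked
Metropolis-within-Gibbs scheme specialised to this hierarchy:

1. **Subject blocks.** Each subject's free-parameter vector is updated by
   random-walk Metropolis, vectorised across subjects. The likelihood
   uses per-design-cell sufficient statistics (accept counts per
   reward × effort cell), so one update costs a single
   (subjects × cells) matrix operation. Proposals are preconditioned by
   the Cholesky factor of each subject's inverse ridge-MAP Hessian — the
   local posterior covariance — which handles the strong K/LinR/E²
   posterior correlations; a per-subject scalar step size adapts during
   warmup to a 0.30 acceptance rate.
2. **Group means.** Conjugate Gibbs draws (normal–normal given the
   subject parameters and σ).
3. **Group standard deviations.** Metropolis on log σ with the
   half-normal prior and Jacobian, adaptive step.
4. **Group translation and scaling moves.** Two interleaved
   reparameterisation moves per hyper-group: a translation that shifts μ
   together with all of its subjects' parameters, and a scaling that
   multiplies σ together with the subjects' deviations from μ. These
   moves carry the sampler through the funnel-shaped geometry that
   appears when σ is small (e.g. near-complete pooling), which the
   component-wise updates alone traverse extremely slowly.

The sampler works in centred parameter space. A non-centred
parameterisation is the usual remedy for funnels in joint
Hamiltonian samplers; in this Gibbs scheme centring keeps the group-mean
update conjugate, and the translation/scaling moves provide the funnel
traversal instead. Chains start at jittered ridge-MAP estimates.
Defaults: 4 chains × 1000 warmup sweeps + 1000 stored draws with 10
sweeps per stored draw (`thin`); at these settings a 60-subject fit
reaches split-chain R-hat ≤ 1.01 and bulk ESS ≈ 400+ per quantity in
about half a minute on one CPU. `check_convergence` reports R-hat, bulk
ESS (via arviz) and the divergence count (identically zero for this
sampler — reported for interface completeness) against configurable
thresholds; fits that miss the thresholds are returned flagged, never
silently.

Point estimates are posterior means; constrained parameters are reported
at their constants and excluded from group tests with a logged notice.
`map_point_estimates` exposes the ridge-penalised per-subject Newton MAP
(ridge 0.1 keeps ceiling/floor subjects finite) used for chain
initialisation; it is also the cheap estimator for large replication
studies such as the type-I-error calibration.

### Model comparison

`compare_models` ranks fits by PSIS-LOO expected log predictive density
computed from the stored per-subject pointwise log-likelihood draws
(subjects are the exchangeable unit). Models with Pareto-k diagnostics
above 0.7 are flagged unreliable. The selection criterion is a design
choice; any alternative criterion can be added behind the same table
interface.

## The synthetic cohort generator

The generator is the testbed for every downstream stage; its defaults
define the study conditions the tests assume.

* **Populations.** Per group, free parameters are drawn from normals.
  Defaults: K ~ N(9, 3), LinR ~ N(6, 4), E² ~ N(−8, 6.5), LinE ≡ −15,
  with corr(K, E²) = 0.5. These values were calibrated once against the
  qualitative empirical pattern: cohort-mean acceptance around 65 %,
  per-subject overall rates spanning from below 40 % to exactly 100 %
  (the K–E² correlation puts some subjects at ceiling, as observed), cell
  curves monotone in reward and effort with a reward × effort
  interaction, and between-subject spread large enough relative to the
  80-trial estimation error that all parameters are recoverable
  (r ≥ 0.7 at n = 60). The between-parameter correlation is not part of
  the fitted hierarchy (whose priors are independent); it is a deliberate,
  mild misspecification matching how real populations violate the
  analyst's prior.
* **Group structure.** The default four groups (CTR 57, REL 36, REM 46,
  MDD 41) differ only in the mean of K: REM and MDD sit 0.39 pooled-sd
  units (1.17 logit units) below CTR/REL. LinR and E² distributions are
  identical across groups.
* **Age.** Ages are truncated-normal (35 ± 10, bounds 18–60). The default
  cohort adds 0.075 logit units of K per year of age (centred), inducing
  an age–acceptance correlation near 0.2; recovery and validation runs
  disable it.
* **Choices and exertion.** Choices are Bernoulli draws from the model;
  exertion omission follows the deterministic every-4th-accepted-trial
  rule (flooring at fraction × accepted), which makes the 25 % omission
  proportion exact and testable — whether the original task randomised
  this is unknown, and nothing downstream depends on it. Success on
  non-omitted accepted trials follows P(success | e) =
  logistic(6 − 4.5·e): monotonically decreasing, ≈ 99 % at 0.2 MVC and
  ≈ 92 % at 0.8 MVC, consistent with individually calibrated effort.
  Successes do not feed back into later choices (the task's outcomes are
  deterministic and fatigue is mitigated by design).
* **Questionnaires.** Four latent symptom factors (Low-mood, Apathy,
  Hedonia, Dysfunctional Attitudes) with group-specific mean shifts
  generate twelve instrument totals (standardised units) through a sparse
  loading matrix: depression/anxiety scales on Low-mood (the optimism
  scale negatively), three apathy sub-scales on Apathy, the two pleasure
  scales with opposite signs on Hedonia (their scoring conventions run in
  opposite directions), two dysfunctional-attitude short forms on the
  fourth factor. Sub-scales are simulated as separate indicators so every
  factor is identified. Noise sd defaults to 0.5.
* **Mis-calibration.** `generate_cohort(..., n_miscalibrated=k)` flags k
  subjects (round-robin across groups) as having failed the highest
  practice effort level, exercising the exclusion filter.

What the simulator does **not** emulate: reaction times, force
time-series, within-session fatigue or learning, missing data beyond the
calibration flag, and realistic questionnaire score ranges (totals are
latent-scale). Passing tests therefore demonstrate correctness of the
pipeline under the stated generative assumptions, not robustness to every
real-data pathology.

## Model-agnostic statistics

* **RM-ANOVA.** Acceptance proportions (per reward × effort cell, equal
  repetitions) are arcsine-transformed (arcsin √p) by default. The mixed
  design — two within factors, optional between-subject group, optional
  covariate — is computed by the orthonormal within-contrast GLM: each
  within effect is projected onto an orthonormal contrast basis, the
  between design (sum-coded group, mean-centred covariate) is fitted to
  the transformed responses, and the averaged univariate F is formed from
  type-III hypothesis and error SSCP traces. Greenhouse–Geisser ε and
  Mauchly's W come from the error covariance in contrast space; the GG
  correction is applied when Mauchly's test rejects at α = 0.05
  (configurable), and both uncorrected and corrected p-values are always
  reported. The implementation reproduces pingouin's `rm_anova` and
  `mixed_anova` exactly on the designs those functions cover.
* **Planned contrasts.** Two pooled contrasts (depression history:
  MDD+REM vs REL+CTR; any vulnerability: MDD+REM+REL vs CTR). Cohen's d
  is computed on raw, covariate-free values with the pooled sd; the
  significance test runs on (optionally transformed) values with the
  mean-centred covariate partialled.
* **Parameter ANCOVA.** One-way group ANCOVA per free parameter with age
  as covariate (pingouin), pairwise post-hocs with unadjusted p plus a
  Holm-adjusted column (the choice of post-hoc correction is genuinely
  open; both are printed so the reader can apply either convention).
* **EFA.** Maximum-likelihood extraction (scikit-learn) on standardised
  totals, followed by varimax and a Promax (κ = 4) oblique rotation
  implemented to the R convention; factor scores by Thurstone's
  regression method; salience marked at |loading| > 0.3. ML extraction
  was chosen over principal-axis as the better-defined default; the
  rotation and factor count are arguments.
* **Power.** One-way fixed-effects ANOVA power via the noncentral F
  distribution with noncentrality f²·N — at N = 180, k = 4, f = 0.25,
  α = 0.05 this evaluates to 0.804.
* **Exclusions.** Participants flagged as failing the 0.8-MVC practice
  level are removed with a per-subject logged reason; the filter is
  idempotent.

## Validation

* **Recovery.** `recover_parameters` simulates n subjects (80 trials
  each), refits with the same default hyperpriors a user would get (no
  oracle priors), and reports per-parameter correlation, bias and RMSE;
  degenerate (zero-spread) populations are flagged rather than producing
  undefined correlations.
* **Posterior-predictive check.** Per-subject predicted acceptance is the
  posterior-draw average of the model's acceptance probability, weighted
  over cells exactly as the schedule weights them; the headline statistic
  is the Pearson correlation with observed rates, computed on raw (not
  arcsine) rates to match how such recapitulation plots are drawn.
  Constant observed or predicted vectors are reported as degenerate
  (correlation undefined) instead of NaN propagation. Per-cell group
  curves are returned for plotting against the classic acceptance-surface
  panels.

## Problem sizes and numerical choices

Test and acceptance runs use the study-scale sizes (60–67 subjects,
80 trials) with a reduced 4 × 500 + 500 sampler configuration and 5
sweeps per stored draw; replication studies (type-I-error calibration,
interval coverage) use reduced cohort sizes and the MAP estimator, with
binomial tolerances matched to their replicate counts. Ties, degenerate
inputs and invalid designs raise typed errors (`DesignError`,
`ModelError`, `SpecError`, `InferenceError`, `StatsError`, `IOError_`)
naming the offending factor or subject. All randomness flows through
explicit integer seeds via `numpy.random.SeedSequence`; no global state.

## Known limitations

* The exact candidate list of the original 70-model comparison and the
  original hyperpriors/selection criterion are not public; the
  configurable family and PSIS-LOO are this package's stand-ins, with the
  four-term model guaranteed present.
* The random-walk sampler, while preconditioned and augmented with
  reparameterisation moves, is less draw-efficient than gradient-based
  samplers; strict diagnostics (R-hat ≤ 1.01, ESS ≥ 400) need the default
  (not reduced) settings.
* Group comparisons use posterior-mean point estimates (mirroring the
  two-stage analysis convention), not the full posteriors.
* Reaction-time, success-rate and fatigue analyses are out of scope; the
  simulator nevertheless produces success outcomes so such analyses can
  be prototyped.
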