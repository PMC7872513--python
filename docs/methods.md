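# Methods

`omiclocks` implements a five-layer biological-clock analysis on simulated
cohorts: per-omics-layer age predictors trained by cross-validated ridge
regression, age-residualized aging indicators, composite indices, and
determinant association testing under a permutation-based false discovery
rate. This note records the models, the defaults and why they were chosen,
and what the simulations do and do not establish.

## The synthetic cohort

The generator produces a phenotype table and one marker matrix per layer
(telomere, epigenetic, transcriptomic, proteomic, metabolomic) with a fully
recorded ground truth, so every downstream stage can be checked against a
known answer.

**Phenotypes.** Age is uniform on [18, 65] years; sex is Bernoulli with 66%
female (coded female = 1); the remaining determinants (education years,
alcohol units/week, smoking pack-years, physical activity in MET-min/week,
BMI, disability and physical-function scores, seven chronic-disease flags,
metabolic-syndrome component count 0–5, current-MDD flag, depression
severity, childhood-trauma score 0–4) are drawn from marginals matching a
middle-aged epidemiological cohort (e.g. BMI ~ N(25.6, 4.1²), disease
prevalences 3–18%). Determinants are mutually independent except that the
chronic-disease count is the sum of the disease flags and depression
severity is shifted upward in MDD cases. This independence is a deliberate
simplification: real determinants are correlated (smoking with sex, BMI with
metabolic syndrome), so the simulated association table is cleaner than a
real one.

**Latent aging deviations.** Each subject i carries one unit-variance
deviation per layer l:

    d_il = Σ_k γ_kl · x̃_ik + s_l · u_i + ε_il

with standardized determinants x̃, a shared standard-normal factor u, and
independent Gaussian noise scaled so Var(d_il) = 1 (the planted-effect
variance is measured on the realized sample, so unit variance holds up to
noise in ε only). The planted cross-layer correlation of layers l and m is
s_l·s_m. Default loadings (0.10, 0.25, 0.40, 0.45, 0.40 for telomere →
metabolomic) keep every pairwise correlation below 0.2, with the
proteomic–metabolomic pair highest (0.18) — the qualitative pattern of
weakly related layer-specific aging. Default determinant effects plant
modest signals for male sex, BMI, smoking, metabolic-syndrome count and the
depression measures on subsets of layers (γ between 0.06 and 0.15).

**Marker panels.** The layer's biological age is b_i = age_i + σ_l·d_il with
σ_l = 5 years by default (the scale of individual aging deviations; the
choice is a simulation convention, exposed in the config). Informative
markers are affine readouts

    m_ij = a_j · b_i + e_ij,   e_ij ~ N(0, c²)

with log-normal loadings |a_j| (σ_log = 1.5) and homoscedastic noise c set in
closed form so the GLS-optimal combination of the q informative markers
attains a target R² against b: c² = Σ_j a_j² · Var(b) · (1−R²)/R². The
log-normal spread makes per-marker information heavy-tailed — a few markers
carry large age signal while most are weak — matching the spectrum of real
omics age panels, where single markers can reach age correlations of 0.3–0.7.
Under an equal-information profile the same panel R² would be spread over
markers individually too weak to rank (|r| ≈ 3 standard errors at desk
scale), and no training-sample ranking procedure could find them; panel
recoverability is then bounded well below the oracle regardless of
implementation. Remaining markers are N(0, 1) noise. Batch and lab offsets
are drawn per (level, marker) and added to all markers. Default panel shapes
are scaled-down but proportionate: epigenetic 20 000 markers (500
informative), transcriptomic 5 000/200, proteomic 171/40, metabolomic
231/60, telomere a single T/S-ratio analogue.

Default panel R² targets (0.90, 0.55, 0.80, 0.52 for the four omics layers)
were set once so the implied clock–age correlations roughly emulate the
0.95/0.72/0.85/0.70 ordering reported for real five-clock panels. Note a
geometric cap: with σ_l = 5 y, cor(b, age) ≈ 0.94, so no clock can exceed
~0.94 against age in this simulation regardless of panel quality.

**Telomere.** T/S = mean − |slope|·(age − mean age) − loading·d + noise,
slope negative by construction. With `noise_sd=None` the residual SD is
solved analytically from r² = slope²Var(age)/(slope²Var(age) + loading² +
σ²) so that cor(−T/S, age) hits a target (default 0.30).

**Censoring.** Metabolite-like panels mask the lowest 2% of each marker as
missing; protein-like panels mask them with the detection limit recorded, to
be imputed at the limit downstream. Optional upper-limit censoring works the
same way.

**Follow-up.** Six-year mortality and per-category disease onset are
Bernoulli with logistic probabilities in standardized age and the layer
deviations; onset is defined only for subjects free of the disease at
baseline (the flag stays 0 for baseline cases). Default rates (2% mortality,
1–5% onset) reflect a middle-aged cohort in which such events are rare —
which is also why longitudinal models on desk-scale runs are underpowered,
as expected.

## Preprocessing

Per layer, in order: missingness handling → technical residualization →
quantile-normal transform. Missingness rules are platform-specific:
metabolite panels drop subjects with more than 25 missing markers, then
markers with more than 250 missing values (markers left with no observed
value are dropped regardless), then median-impute; protein panels drop
analytes missing in more than 30% of subjects and impute censored entries
at their detection limits. The metabolite thresholds are absolute counts
(they implicitly scale with panel and cohort size) and are exposed in the
config. Subject-before-marker filtering order follows the narrative order of
the platform conventions; it matters only when a subject's missingness drives
a marker over its threshold.

Residualization regresses every marker on batch/lab indicator codes (with
intercept) and keeps the residuals; a single-level factor reduces to
centering, and a level with one subject gets residual 0 (warned). The
quantile-normal transform maps marker values to Φ⁻¹((rank − 0.5)/n) with
average ranks for ties; the (rank − 0.5)/n offset is symmetric and bounded
away from 0 and 1. A constant marker maps to zeros with a warning. The
telomere layer bypasses preprocessing: it is a direct measurement, not a
panel.

## Clock training

For each omics layer, subjects are split into K = 10 folds (sizes differing
by at most one). Within each fold's training rows, markers are ranked by
|Pearson r| with age (constant markers rank last; ties keep input order).
For a candidate count k, the top-k training-ranked markers enter a ridge
regression of age with an unpenalized intercept:

    min_β Σ (y − β₀ − Xβ)² + λ‖β‖²

solved in closed form via eigendecomposition of XᵀX (or of the Gram matrix
XXᵀ when k exceeds the training size — identical coefficients, cheaper).
λ is chosen per fold by inner 5-fold CV minimizing validation MSE over a
log-spaced grid 10⁻³…10⁴ × (k/n): the top decade is included because for
standardized weak-signal panels the CV-optimal penalty routinely exceeds
10³·k/n, and a grid truncated there selects a boundary value. Candidate 0
means an intercept-only baseline predicting the training-fold mean age.

The held-out fold receives predictions from the training-only model, so no
test information enters ranking, penalty selection, or fitting. The
out-of-fold correlation with age, as a function of k, is the validation
curve; the selected k* is the smallest candidate within 0.01 correlation
units of the curve maximum (plateau rule). Candidate selection deliberately
sits outside the fold loop: the curve is computed from full CV runs per
candidate, and only k* varies globally. For small targeted panels
(proteins, metabolites) the candidate list is simply "all markers".

A caveat observed on simulated panels: the validation curve is not
monotone in k. Adding markers cannot reduce the information available to an
optimally weighted predictor, but a ridge with a single global penalty pays a
variance cost for every additional noise marker, so past the plateau the
curve can decline. The plateau rule's preference for the smallest adequate k
is what protects the final model from this regime.

## Indicators and composites

Biological aging per omics layer is the OLS residual of out-of-fold
predicted age on chronological age — mean zero and exactly orthogonal to
age, so age never needs to be a covariate for these indicators. The
telomere indicator is −T/S, z-scored, not age-regressed (its age dependence
is handled by an age covariate in association models). On the subjects with
all five layers (the overlap), the sum composite z-scores each indicator
(n−1 SD, scaling statistics computed on the overlap) and adds them; the PC1
composite takes the unit-norm leading eigenvector of the 5×5 correlation
matrix of the scaled indicators, sign-oriented so the loading sum is
positive, with scores = scaled indicators × loadings. PCA on the
correlation (not covariance) matrix makes the loading vector unit-norm and
scale-free.

## Association models

Every determinant–indicator pair gets a linear model with the outcome
(indicator) and determinant z-scored — the reported beta is the
standardized coefficient, equal to Pearson r in the no-covariate case. Sex
is always a covariate except when sex is the determinant, in which case sex
becomes the model outcome (and no sex covariate is added); the telomere
indicator additionally gets chronological age as covariate. Binary and
ordinal determinants are z-scored like continuous ones, so betas are
comparable across variable types. Complete-case filtering is applied per
model. Inference uses the t distribution with residual degrees of freedom.

The sex-adjusted Spearman matrix rank-transforms each indicator pair on
their pairwise-complete subjects, residualizes both rank vectors on sex, and
takes the Pearson correlation of the residuals (one of several
partial-Spearman constructions; chosen for transparency and verified against
an independent implementation in the tests). Interaction models add
moderator and determinant×moderator terms (moderator binary); longitudinal
models are linear probability models of a binary outcome on the z-scored
indicator with a sex covariate, reporting both the per-SD risk difference
and the fully standardized beta.

## Permutation FDR

Phenotype rows (determinants and covariates together) are shuffled against
the indicator block B times (default 1000) and all association models are
re-fit per permutation. For an observed p,

    FDR(p) = mean_b #{p_perm^(b) ≤ p} / #{p_real ≤ p},

capped at 1 and set to 1 when the denominator is empty. Counting is
inclusive (≤): a strict inequality would zero the denominator at the
smallest observed p. The significance threshold for a target FDR is the
largest observed p with FDR(p) ≤ target; when no observed p qualifies the
run reports "no threshold". No monotonization or step-up smoothing is
applied — the estimate is the raw ratio, which need not be monotone in p.
If a permuted model is degenerate (a rare binary determinant constant
within a layer's overlap after shuffling), that cell counts as a null
result (p = 1) rather than aborting the permutation.

## Numerical choices and degenerate inputs

- Ridge with λ = 0 falls back to minimum-norm least squares (rank-deficient
  designs included), documented rather than an error.
- Gram-matrix centering is done algebraically from the full Gram matrix, so
  inner-CV penalty paths cost one small eigendecomposition per split.
- Eigenvalues are clipped at 0 before inversion; tied leading eigenvalues in
  the PC1 step fall back to eigensolver order with a warning.
- Correlation of a constant vector (e.g. the intercept-only candidate's
  predictions) is defined as 0 in validation curves.
- Seeds: every stage derives its seed deterministically from the root seed
  and the stage name, so stages re-run in isolation reproduce the pipeline's
  results; identical (config, seed) gives byte-identical artifacts.

## Desk-scale problem sizes

The test suite and the acceptance script run scaled-down panels chosen to
exercise the full method at workstation scale: cohorts of 150–5000 subjects,
epigenetic-like panels of 250–4000 markers, 15–200 permutations in smoke
tests and 200–1000 in calibration runs. Clock-recovery checks use n = 1000
subjects, 2000 markers (100 informative, panel oracle R² = 0.49, deviation
scale 0 so that the oracle correlation against age is √R² = 0.7);
FDR-calibration checks use 20 global-null cohorts of n = 1000 with 20
determinants × 5 indicators and B = 200. These sizes are the package's
standard demonstration conditions; all are configurable.

## Indicator fidelity and attenuated associations

Determinant effects enter markers only through the latent deviation d, and
d contributes σ²/(Var(age) + σ²) ≈ 12% of biological-age variance at the
default σ = 5 y. A clock that tracks b with correlation ρ therefore yields
an indicator whose correlation with d is 0.346·ρ/√(1 − 0.88·ρ²) — about
0.26 for a ρ ≈ 0.62 clock and 0.66 for a ρ ≈ 0.93 clock. Realized
determinant–indicator betas are the planted γ times this fidelity, so
desk-scale association tables are sparser in significant findings than a
full-scale cohort would be. This is a property of the generative model (in
real panels, marker "noise" contains correlated biological variation that a
clock can exploit; here it is independent), and it is why the acceptance
demonstrations plant effects at full reported-beta scale yet recover
attenuated estimates.

## What passing tests do and do not show

The generator plants linear, homoscedastic, Gaussian structure: marker
panels are affine in a single latent biological age, determinant effects are
linear, and missingness is driven by detection limits only. Passing tests
therefore establish correctness of the estimators and the absence of
leakage/miscalibration under the model's own assumptions. They do not
establish robustness to nonlinear age trends, correlated determinants,
non-Gaussian marker noise, co-methylation/LD-like marker dependence,
informative missingness, or platform drift — none of which the generator
emulates. Longitudinal models are implemented and tested for correctness,
but desk-scale event counts are deliberately realistic (rare), so power
statements about them are out of scope.
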