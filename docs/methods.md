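# Methods

This note documents the models, numerical choices and simulation design
behind `atnpredict`, and what the synthetic cohort does and does not show
about real data.

## Biomarker dichotomization

CSF Aβ42 and p-Tau are bimodal in mixed cohorts of amyloid-normal and
amyloid-abnormal individuals, motivating a two-component Gaussian mixture
as the cut-off model. The EM fitter (`thresholds.fit_two_component_mixture`)
is self-contained rather than delegated to a library so that its
per-iteration log-likelihood trace is exposed and the monotone-ascent
property of EM can be asserted in tests; `sklearn.mixture.GaussianMixture`
serves as an independent cross-check in the test suite, never as the
implementation.

Fitting details: the first start splits the sample at the median and uses
within-half moments; the remaining `n_starts − 1` (default 10 total) starts
draw means from the data and perturb weights/scales; convergence is a
relative log-likelihood change below `tol` (default 1e-8) within 500
iterations; component SDs are floored at 1e-4 of the sample SD to avoid
variance collapse onto single points. Components are reported in
ascending-mean order. A `separation` diagnostic (|μ₂−μ₁| / pooled SD) lets
callers detect effectively unimodal data, where a two-component fit is
ambiguous (near-equal means or a near-zero weight are both legitimate
solutions).

The intersection cut-off solves w₁φ₁(x) = w₂φ₂(x) exactly — a quadratic in
x for σ₁ ≠ σ₂, linear for equal σ — and takes the root strictly between the
means, verifying the weighted densities agree at the root to 1e-8 relative.
Under extreme weight imbalance no root lies between the means; that raises
a dedicated error recommending the mean ± k·SD rule (default k = 2, the
common practice when the multiplier is unstated; the component and k are
configurable because conventions vary).

The shipped fixed cut-offs are Aβ42 < 1025 pg/ml ⇒ A+ and p-Tau > 24 pg/ml
⇒ T+, with strictly-inequality semantics throughout: a value exactly at the
threshold is biomarker-negative.

Scheltens MTA thresholds are 1.0 below age 65, 1.5 for 65–74 and 2.0 from
75 upward; N+ requires a score strictly above the threshold. Age exactly 75
is placed in the oldest band — the decade wording leaves the boundary
ambiguous, and contiguous coverage requires a choice; users relying on the
band edge should be aware this is a package decision.

## ATN groups and the exclusion cascade

The eight fully-observed flag combinations map to five categories through a
fixed truth table (asserted exhaustively in tests); any missing flag makes
the participant unclassifiable. The analytic-sample cascade excludes, in
order: clinical dementia/MCI diagnosis, then CDR ≥ 0.5 among the remainder,
then incomplete ATN among the remainder, attributing each participant to
the first stage that catches them so stage counts plus the analytic n sum
to the input n.

## Composite risk scores

The scoring engine is declarative: each score is a YAML table of
components, each mapping one participant field through sex-specific numeric
bands (half-open `[low, high)`) or flag points, optionally conditioned on a
second flag (used for treated vs untreated systolic-BP bands). Band
partitions are validated at load time — for every component and sex the
bands must tile the field's legal range with no gaps or overlaps.

Encoded defaults: the CAIDE mid-life dementia score (non-APOE variant — the
component list implies it; maximum 15 points), the Framingham general-CVD
point system, and the Framingham stroke risk profile. Two self-report
adaptations replace the lipid components: self-reported
hypercholesterolaemia scores CAIDE's 2 cholesterol points, and the
sex-specific Framingham diabetes points. Notes on fidelity to the source
tables:

* The general-CVD table keeps the source's negative points for untreated
  SBP below 120 mmHg, so totals are integers but not necessarily
  non-negative for very low-risk profiles.
* The stroke table's women-specific antihypertensive-treatment rule (an
  SBP-dependent increment) is encoded as a separate treated band set whose
  points equal untreated points plus the increment; men's treated bands are
  untreated + 2.
* Ages and pressures outside the sources' printed ranges (the stroke table
  starts at age 54) fall into the nearest boundary band, so the engine is
  total over the schema's legal ranges.
* Left-ventricular hypertrophy is rarely recorded in registry-style
  cohorts; it defaults to absent.
* The sources' inclusive band wording is mapped onto the half-open
  convention at the printed boundary (documented per table file).

A missing required field makes the score *incomplete* (no raw total) rather
than an error; incomplete scores are excluded from cohort z-standardization
(sample SD, n−1) and from downstream models, matching complete-case
modelling with per-model n.

## Synthetic cohort

`generate_cohort` is structure-first: you request counts per A/T/N
combination and the generator guarantees, by construction, that
re-classification under the active cut-offs reproduces them exactly. CSF
values are the cut-off plus/minus a half-normal margin (scales 220 pg/ml
for Aβ42, 6 pg/ml for p-Tau — chosen so the resulting marginal distribution
is visibly bimodal with realistic overlap near the cut-off); the Scheltens
score is drawn from the admissible half-point values on the required side
of the age threshold with geometrically decaying mass away from mild
scores.

Defaults encode the published cohort: 1500 participants; exclusion counts
82/171/237; analytic groups 567/211/67/31/134; per-group covariate marginals
(age, sex, education, APOE4, family history, vascular flags, cognition,
WML). The published tables give the two composite groups' totals but not
their split over combinations; the defaults use a completion consistent
with the published A+ = 309, T+ = 158 and N+ = 90 marginals
(A+T+N− = 57, A+T+N+ = 10, A−T+N− = 85, A−T+N+ = 6, A−T−N+ = 43). Any
completion with an A−T+ total of 91 and A+T+N+ plus A−T+N+ summing to 16
would match; this one spreads N+ thinly outside the pure-neurodegeneration
cell, consistent with the low overall N+ prevalence.

Covariates are sampled *independently within group* — the published tables
constrain only marginals. WML volume uses a log-normal matched to the
configured mean/SD (its published mean ± SD implies strong right skew; the
exact distribution is unknowable from summary statistics). MMSE is a
truncated, rounded normal on [0, 30].

Consequences for interpretation: passing tests show the pipeline's
arithmetic and estimators are correct under the published marginal
structure, not that the real cohort's joint covariate dependence is
captured. In particular, multivariable effect sizes and AUCs on the
synthetic cohort reflect the configured between-group mean/prevalence
differences only; within-group correlations (e.g. age with WML) are absent
unless configured.

`generate_from_model` is model-first, for estimator-recovery studies:
covariates come from stated base distributions and the outcome is sampled
from a logistic (binary) or softmax (multinomial, reference category's
linear predictor fixed at 0) model with user-supplied coefficients. The
binary path is the multinomial path with one non-reference category, making
the two modes exactly equivalent on matched seeds. Sampled labels are
realised as biomarker values on the appropriate side of the cut-offs so the
records classify back to their sampled groups. All randomness flows through
NumPy's `default_rng` (PCG64), so cohorts are bit-reproducible per seed
across platforms.

## Regression battery

All regression fits are maximum likelihood via statsmodels (`Logit`,
`MNLogit`), with Wald 95% CIs and p-values — the convention matching ratio
CIs that are symmetric on the log scale. Models are complete-case on
exactly the variables they use, so each result reports its own n. Study
site enters as fixed categorical effects (first site reference). The
multinomial fitter tries Newton first and falls back to L-BFGS when the
Hessian is near-singular (small groups crossed with many site dummies);
non-finite estimates are reported as non-estimable, as are coefficients or
standard errors beyond 50 on the log scale (quasi-separation), rather than
returned as numeric artefacts.

Group comparisons: one-way ANOVA with all 10 pairwise two-sample t-tests,
Bonferroni-multiplied (×10) and capped at 1, for continuous variables;
2×5 chi-square (no continuity correction) with *adjusted* standardized
residuals R = (O−E)/√(E(1−row/N)(1−col/N)) for binary variables, flagging
|R| > 2. The adjusted form is used because it is the variance-correct
cell-level statistic for post-hoc contingency analysis. A warning is
attached when any expected cell falls below 1. The Bonferroni helper is
plain α/m; both 0.05 and 0.5 family levels are exposed as presets because
published footnotes in this literature use either convention.

## ROC ladder

Model 1 is age + sex + APOE4. For the Alzheimer's-pathologic-change
contrast only, the basic model (and every superset) additionally carries
age×APOE4 and sex×MMSE product terms, with the interaction's main effects
included (hierarchical convention). A side effect: for that contrast the
MMSE-only extension adds no parameters beyond the basic model, so its
likelihood-ratio p-value is reported as absent.

AUC is the apparent (in-sample) midrank Mann–Whitney statistic on predicted
probabilities; no cross-validation or optimism correction, by design. CIs
use DeLong's placement-value variance. Nested-model comparison is the
likelihood-ratio chi-square with df equal to the added parameter count,
with *both* models refitted on the extended model's complete-case rows so
deviances are comparable — the alignment rule is a package decision, as the
sample-alignment convention is usually unstated in applied reports.

## Problem sizes and determinism

The test suite and the acceptance script use: n = 5000 per mixture fit
(median over five fits in the cut-off recovery check), n = 100,000 for
logistic/multinomial effect-recovery simulations, 20 replicate cohorts of
525 + 64 for the AUC neighbourhood checks, and 60–100 seeds for the
null-calibration (uniform-p) checks at n of a few hundred per seed — sizes
at which Monte-Carlo error is comfortably inside the stated tolerances
while the whole suite completes in a few minutes. Every stochastic
component takes an explicit seed; the pipeline fans a master seed out to
stages by SHA-256 hashing of the stage name.

## Known limitations

* Within-group covariate independence in the synthetic cohort (above).
* No imputation: missing biomarkers exclude participants; missing score
  components void the score.
* No PET or plasma operationalizations of A/T/N; CSF + MTA only.
* Two-component Gaussian mixtures only; no bootstrap CIs for cut-offs.
* The Framingham/CAIDE tables are faithful re-encodings of the cited point
  systems with the self-report adaptations, not calibrated risk
  probabilities; no risk-probability transform is provided.
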