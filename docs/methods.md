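# Methods

`lipidsig` implements a serum-lipidome analysis pipeline for gastric cancer
with two fitted models: a diagnostic lipid signature (a scored lipid panel
separating cancer patients from healthy donors) and a prognostic subtyping
of the cancer patients from the same lipid matrix. This note records the
models, their assumptions, the defaults and why, and what the synthetic
benchmark does and does not demonstrate.

## Preprocessing

Untargeted lipidomics intensities arrive as one table per ion mode with
per-sample internal-standard (IS) intensities and pooled-QC replicate rows
injected once per 20 study samples.

1. **QC filter.** A feature is kept iff its relative standard deviation
   across QC rows (sample SD with n−1 denominator, divided by the mean) is
   below 0.30. The (n−1) convention is the standard QC practice; features
   with zero QC mean are removed as degenerate.
2. **Normalization.** Each raw intensity is divided by the IS intensity of
   its sample and ion mode, then transformed to `log2(ratio) + 5`. The +5
   offset keeps typical values positive; it cancels under autoscaling.
   Non-positive raw values are imputed with half the feature's minimum
   positive value (configurable to reject instead).
3. **Mode merging.** Positive- and negative-mode matrices are concatenated
   with `pos:`/`neg:` feature-id prefixes so annotations never collide.
4. **Autoscaling.** Per-feature standardization with mean/SD fitted on the
   training cohort only and applied frozen everywhere else. The source
   description is silent on whether scaling preceded the train/test split;
   freezing training parameters is the leakage-free reading and is the
   default (scaling on the pooled exploration cohort is available by
   passing a different `fit_on` matrix).
5. **Cohort split.** Stratified 85/15 with the test count floored per
   stratum, reproducing a 266+266 cohort splitting into 227+227 / 39+39.

## Diagnostic signature

**Ranking.** PLS-DA is PLS1 regression (NIPALS with deflation) on a
mean-centered ±1 class coding. Two components by default: the published
signature was interpreted through component-1 contributions, indicating a
low-dimensional model; the count is configurable. Features are ranked by
the Wold VIP over all fitted components,

    VIP_k = sqrt( p · Σ_a SSY_a w_ak² / Σ_a SSY_a ),   Σ_k VIP_k² = p,

with ties broken by ascending feature id. A `components=1` option
restricts the VIP to component 1 for the alternative reading.

**Panel selection.** Serum lipidomes are strongly co-regulated, so the top
of the VIP ranking is redundant. The top 50 lipids are pruned by a single
greedy pass: the top lipid is always kept and each later lipid enters only
if its Spearman correlation with every already-kept lipid is below 0.5 in
absolute value. Absolute value is used because redundancy is
sign-symmetric; a signed mode exists. Correlations are computed on the
training cohort only, since selection is part of fitting.

**Scoring.** Gaussian LDA with pooled within-class covariance:
α = Σ⁻¹(μ₁−μ₀), α₀ = −½(μ₁+μ₀)ᵀΣ⁻¹(μ₁−μ₀) + log(π₁/π₀). The linear form
α'x + α₀ is the log-odds of cancer; the reported score is its logistic
transform, a probability in [0,1], and a sample is called positive iff the
score is strictly greater than 0.5 (a score of exactly 0.5 is negative).
This resolves the apparent tension between a linear score equation and a
[0,1] scale with a 0.5 cutoff: the linear discriminant is emitted alongside
the probability. When the pooled covariance is ill-conditioned
(condition number > 1e10) a ridge `1e-6·trace(Σ)/K·I` is added — panels up
to 50 lipids against ~400 training samples per fold can be near-singular.

**Model selection.** Panel sizes 2–50 (nested prefixes of the decorrelated
ranking) are crossed with candidate algorithms and scored by stratified
10-fold cross-validation repeated 10 times, re-standardizing inside each
training fold. Four algorithms are implemented natively (LDA, QDA, KNN
with k ∈ {3,5,7,9} tuned in-fold, elastic-net logistic); further
algorithms plug in through the `ClassifierSpec` interface. The best cell
maximises mean accuracy with ties broken toward the smaller panel, then a
fixed algorithm order. The VIP ranking is computed once on the full
training cohort, not re-derived inside folds (a strict nested mode can be
emulated by driving the grid manually); the repeated-CV accuracy is
therefore mildly optimistic for panel membership, which is why held-out
cohorts are evaluated separately.

## Evaluation

Sensitivity, specificity and accuracy are binomial proportions with exact
Clopper–Pearson 95% intervals (the diagnostic-test calculator convention);
table values are printed half-up at 3 decimals. AUC is the Mann–Whitney
statistic with ties counted ½; its CI is DeLong's from the placement-value
variances, truncated to [0,1]. The combined-diagnostic-panel comparator
calls a sample positive if any of CEA, CA19-9, CA72-4 strictly exceeds its
cutoff; the cutoffs were not printed in the source table, so the
conventional clinical thresholds (5 ng/mL, 37 U/mL, 6.9 U/mL) are defaults
and fully configurable. Samples with all three markers missing are excluded
from that comparator only.

## Prognostic subtyping

**Screen.** One univariable Cox proportional-hazards fit per lipid
(continuous covariate, Efron tie handling — follow-up is recorded in
months, so ties are routine). Lipids with Wald p < 0.05 are ranked by
ascending p and pruned by the same stepwise |SCC| < 0.5 rule. The screen
is a single vectorized Newton–Raphson across all lipids (they share the
risk-set structure); it is verified against lifelines per-feature fits in
the test suite.

**Consensus clustering.** Monti-style stability clustering: 1000
replicates, each subsampling 80% of patients without replacement,
clustering them, and cutting at every K in 2..6; consensus_ij is the
fraction of co-sampled replicates in which i and j co-cluster. The base
clusterer is hierarchical **Ward linkage on Euclidean distance**. The
often-quoted average-linkage/Pearson configuration is available
(`base="average"`) but is not the default: on benchmark matrices it chains
— peeling off singleton outliers instead of splitting the cohort — and its
subtype recovery was near-random where Ward and k-means were near-perfect.
K is chosen by the delta-area of the consensus CDF, with the argmax
restricted to K values whose PAC (consensus mass in (0.1, 0.9)) is ≤ 0.3;
the unrestricted argmax is structurally biased toward the smallest K. If
no K is confident, the smallest K is returned with a low-confidence flag.
The actually-used clustering configuration and K criterion were not
reported for the original analysis; these defaults are the package's
documented choice, not a reconstruction.

**Naming.** Subtypes are ordered by worse observed survival: the cluster
with the smallest restricted-mean survival time becomes SI, matching the
convention that SI carries the worse prognosis. Survival contrast is
reported as the Kaplan–Meier curves, the two-sided log-rank test, the
hazard ratio of SI vs SII from a one-covariate Cox fit, and two-year OS
read off the KM step function at exactly 24 months (right-continuous).

**Subtype predictor.** Elastic-net penalized logistic regression

    min_{β₀,β} (1/N) Σ w_i l(y_i, β₀ + βᵀx_i) + λ[(1−α)‖β‖₂²/2 + α‖β‖₁]

with α = 1 (lasso) by default, matching the glmnet default. λ is chosen by
5-fold cross-validated binomial deviance on a 20-point geometric path from
λ_max (the smallest λ zeroing all coefficients) down to λ_max/100. The
solver is scikit-learn's saga; because saga can leave the unpenalized
intercept short of its optimum once every coefficient is zeroed, the
intercept of the final model is polished by a one-dimensional Newton step,
which is exact. New samples take the subtype with the higher predicted
probability; an exact tie resolves to SI.

Multivariable Cox fits (subtype + clinical covariates) use lifelines with
Efron ties; categorical covariates expand against the first sorted level,
and collinear designs are rejected before fitting.

## Differential abundance, trends, enrichment

Group contrasts use Student's t with pooled variance by default — the
source figures state Student's t — with Welch available by flag; paired
pre/post-operative designs use the paired t over an explicit sample
bijection. Benjamini–Hochberg step-up controls FDR across lipids. Stage
trends z-score each lipid's stage-mean profile across pTNM stages I–IV
(shape, not magnitude) and cluster the profiles by Ward/Euclidean
hierarchical clustering cut at k = 3 by default; the original trend
clustering method was not described, so this is a documented stand-in.
Enrichment of a lipid list in user-supplied annotation sets (GMT format)
is the upper-tail hypergeometric test with BH adjustment; no pathway
database is bundled.

## Synthetic cohorts

The generator reproduces the statistical structure the pipeline assumes,
so that every stage is testable without the deposited data. Defaults (the
benchmark conditions):

- 581 lipid features on the log2 scale, unit within-group SD. Correlated
  blocks via a shared-factor Gaussian copula: within a block the latent
  Pearson correlation is `2·sin(π·ρ_s/6)` so the realized Spearman
  correlation is the target ρ_s (0.7 by default); exponentiation keeps raw
  intensities strictly positive.
- 40 disease-informative lipids in 10 blocks of 4, plus 20 correlated
  noise blocks of 10; remaining features independent. Each informative
  block carries one stage-trend family — monotone up, monotone down,
  biphasic (rise through stage II, partial decline after), or stage-flat —
  scaled so the average cancer-vs-healthy shift is `effect_size` (1.0 SD).
  Precancerous-lesion samples get half the stage-I shift.
- Stage distribution (0.20, 0.21, 0.38, 0.21) over I–IV, i.e. ~41%
  early-stage, matching the published training-cohort balance.
- Two latent prognostic subtypes among cancer patients, separated by
  1.5 SD on 20 dedicated prognostic lipids. These are planted as mutually
  independent features: the subtype shift itself induces ~0.36 pairwise
  correlation, which survives the |SCC| < 0.5 screen. (Planting them
  inside a correlated block would make the screen's decorrelation step
  collapse the block to one representative and destroy the signal — a
  scenario the pipeline is, by design, not meant to recover.)
- Per-lipid baseline abundance is drawn from a fixed stream shared by all
  cohorts: a lipid's typical level is a property of the lipidome, so
  models fitted on one synthetic cohort transfer to another, as they must
  for external-validation workflows.
- Survival: exponential event times (configurable Weibull shape with
  proportional hazards preserved) at baseline hazard 0.005/month for the
  low-risk subtype and hazard ratio 3.34 for the high-risk subtype;
  censoring is administrative at 60 months plus independent uniform
  dropout on (0, 180) months. With 266 patients this yields roughly
  90–115 events and a median follow-up in the 30–45 month range,
  comparable to the published exploration cohort (54 events at a median
  follow-up of 33 months, with a longer accrual window).
- Internal standards: per sample and mode, lognormal around 1e5 with 5%
  CV. QC replicates: one per 20 study samples, multiplicative lognormal
  noise at 10% CV around the pooled mean profile; 20 designated unstable
  noise features get 50% CV so the RSD filter has genuine work to do.
- Conventional tumor markers (CEA, CA19-9, CA72-4) are lognormal with
  group-specific parameters chosen to give the low sensitivity / high
  specificity typical of these markers.

What the generator does **not** emulate: batch/drift effects, missing
values, non-Gaussian heavy tails, annotation ambiguity, stage-dependent
censoring, or any relationship between the diagnostic lipids and survival
beyond the planted subtypes. Passing benchmarks therefore demonstrates
correctness of the machinery under the assumed data structure, not
clinical performance on real cohorts.

## Numerical choices and degenerate inputs

- Spearman matrices use average ranks; constant features yield flagged
  undefined entries, and candidates with undefined correlation to a kept
  lipid are rejected, not errors.
- NIPALS PLS1 components have a closed-form inner step, so fitting is
  exactly deterministic; a vanished weight vector (residual response
  orthogonal to X) raises with diagnostics.
- The CV grid derives per-repeat fold seeds from a single seed stream;
  a fold missing a class is skipped and refolded.
- Batch Cox Newton iterations clip steps to ±5 for stability; convergence
  is |step| < 1e-9 within 25 iterations, and non-converged lipids are
  excluded from the screen with a log entry.
- `choose_k` diagnostics always carry per-K CDF areas, delta-areas and
  PAC so the K decision can be audited.
- Problem sizes in the test-suite benchmarks (20 seeds for each
  end-to-end recovery check, 100–2000 replicates for the calibration
  checks, consensus at 1000 replicates) were chosen as the smallest sizes
  at which the Monte-Carlo noise is clearly below the acceptance margins.

## Known limitations

- Of the ten published candidate algorithms, six (the SVM variants, random
  forest, bayesglm) are not shipped natively; the grid accepts them via
  `ClassifierSpec` if the caller provides estimators. The selected model
  in the original analysis was LDA, which is native.
- No batch correction or drift correction; no missing-value handling
  beyond the half-minimum policy.
- The consensus-clustering configuration and the K-selection criterion are
  package choices (see above); with the published data they may select
  differently than the original analysis.
- Exact CI agreement with every printed table cell is not expected: the
  published table contains visible typographic errors, so only
  arithmetically forced cells are asserted.
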