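# Methods

## Model family

Every model in the package is a triangular system of linear Gaussian
regressions among observed scores.  The exogenous design — YGTSS total
tic severity, age, sex (0 = male, 1 = female) and comorbidity (0/1) —
is conditioned on, never modelled; endogenous scores (PUTS urge total,
BRIEF BRI/MI, or the GEC composite) appear as predictors only in later
equations, so the joint density factorizes stage by stage.  The BRI and
MI equations form one bivariate stage with residual correlation ρ,
reflecting shared parent-report variance that their common predictors
do not absorb.  All scores enter raw (uncentred, unstandardized): with
a 0/1 moderator this makes the conditional indirect effects exact
coefficient products, IE(C=0) = a1·b, IE(C=1) = (a1+a4)·b,
IMM = a4·b = IE(C=1) − IE(C=0), identities the code maintains per
posterior draw (tested to 1e-12).

A deliberate structural quirk of the simplified moderated model: the
mediator (PUTS) equation carries the severity×comorbidity product but
*no* comorbidity main effect and no sex term.  Interaction without main
effect is unconventional; it is retained because it is the specification
whose derived-effect algebra the package reproduces, and because the
full moderated variant (which does include the main effect, plus
moderation products on every stage) is available for sensitivity
analysis and nests it.

Assumptions worth naming: Gaussian residuals on raw score scales
(instrument floors/ceilings ignored by the likelihood), linearity in
all paths, missingness at random for endogenous scores, and no
measurement model — instrument totals are treated as error-free
observed variables.

## Priors

* Regression coefficients: Normal(0, 10), 10 = standard deviation.
  Weakly informative for path coefficients on these scales (all
  published-scale effects are well inside ±10).
* Intercepts: Normal(0, `intercept_scale`), default 100.  This is a
  deliberate departure from using scale 10 everywhere: outcome means
  run from ≈14 (PUTS) to ≈138 (GEC), so a zero-centred scale-10 prior
  on intercepts is *strongly* informative on raw scales.  In a
  100-replicate study at n = 1000 it pulled the MI intercept's 95% CI
  coverage down to 61%, and — because uncentred predictors couple the
  intercept to the slopes — dragged the age-path coverages to 77–84%.
  With scale 100 all parameters recover nominal coverage (90–99/100).
  A location-prior conflict of that size would also drive the
  posterior predictive p-value toward 0 for any well-fitting model on
  these scales, which is inconsistent with fits this family is known to
  produce; `PriorSpec(intercept_scale=10.0)` restores the uniform
  treatment if wanted.
* Residual SDs: Gamma(shape 1, rate 0.5) on σ (shape/rate convention,
  mean 2).  Deliberately light-tailed but diffuse; the likelihood
  dominates at any realistic n.
* Residual correlation: Beta(1, 1) on (ρ+1)/2, i.e. uniform on (−1, 1).

## Sampler

Blocked Gibbs, exploiting the stage structure:

* Coefficients + intercepts of a stage, given residual parameters:
  exact conjugate multivariate-Normal draw.  For the bivariate BRI/MI
  stage this is the seemingly-unrelated-regressions update with the
  2×2 residual precision entering a Kronecker-structured posterior
  precision.  Because the update needs only X'X, X'y and y'y, these
  sufficient statistics are cached when the data are complete, making
  iteration cost nearly independent of n.
* Residual SDs and ρ: univariate slice sampling (stepping-out with
  shrinkage, Neal-style) on their scalar conditionals, which depend on
  the data only through residual cross-products.  No tuning is needed;
  widths are 0.5σ+0.05 for SDs and 0.25 for ρ.
* Missing endogenous cells: data augmentation.  Each affected subject's
  endogenous vector is jointly Gaussian given the design (solved from
  the triangular system), and the missing coordinates are drawn from
  the exact conditional given the observed ones — the sampling
  counterpart of the full-information likelihood.  Subjects missing an
  exogenous value are dropped from the fit with a recorded count (no
  covariate model is assumed).

Initialization: coefficients near 0, intercepts at outcome means,
σ at outcome SDs, ρ near 0, all jittered per chain.  Chain c is seeded
deterministically from (seed, c); identical configurations reproduce
draws bit-for-bit.  Default schedule: 4 chains × 2,000 warmup + 12,500
kept draws (50,000 posterior samples).  Tests and the acceptance script
use reduced schedules — typically 2–4 chains × 200–500 warmup +
400–2,000 draws — which the near-independent conjugate/slice updates
mix well within; the configuration actually used is recorded in every
draws store and manifest.

Correctness anchors: on a known-σ regression the sampler matches the
closed-form Normal posterior mean and SD to <1% at 20k draws;
prior-only mode reproduces the prior moments (coefficient SD 10,
intercept SD 100, σ mean 2, ρ uniform by KS test); and a 100-replicate
recovery study at n = 1000 gives 95% CI coverage within the binomial
band for all 20 parameters.

## Convergence and model checking

**Split-Rhat.**  Each chain is halved; the potential scale reduction
factor is computed from within- and between-half-chain variances, with
the conventional threshold 1.05.  The implementation agrees with an
independent library computation (arviz, split method) to 10 decimal
places; parameters with zero variance everywhere (e.g. held fixed) are
reported as undefined rather than numeric.

**Posterior predictive p-value.**  For an evenly spaced subsample of
posterior draws θ (default 1,000), replicate endogenous data are
simulated on the observed exogenous design and the discrepancy
D(data, θ) = −2[logL(data|θ) − logL(data|saturated)] is compared
between replicate and observed data; PPP is the fraction of draws with
D(rep) ≥ D(obs).  "Saturated" is a package convention (many concrete
choices are defensible for a chi-square-like measure): per stage, an
OLS regression of the stage's outcomes on an enriched design — all
exogenous main effects, all earlier outcomes, plus, for each moderator
the model declares, its products with the other design columns — with
the empirical (MLE) residual covariance.  The moderator products give
the check power exactly where a moderated-mediation analysis needs it:
with a strong omitted severity×comorbidity effect the PPP collapses to
≈0.00 in every tested replicate, while under correct specification
50 seeded replicates at n = 300 give mean PPP 0.51 with 88% of values
inside (0.2, 0.8).  Keeping the enrichment lean matters: a variant with
all pairwise exogenous products added ~27 extra degrees of freedom and
made the correctly-specified PPP noticeably more dispersed.  Complete
cases only; rows are canonically sorted first so the value is invariant
to subject ordering; deterministic given seed and subsample size.

## Synthetic cohort generator

The generator emulates the study conditions of a school-age
tic-disorder clinic cohort: n = 154; sex ~ Bernoulli(0.1558 female);
comorbidity ~ Bernoulli(0.5325); age and YGTSS as truncated Normals on
[6, 16] years and [0, 50] points.  The configured mean/SD are the
*observed* (post-truncation) moments: underlying location/scale are
solved by moment matching, so e.g. age lands on 9.29 ± 1.95 exactly in
expectation.  For YGTSS the target pair (32.71, 13.17) is just outside
what any truncated Normal on [0, 50] can reach (the range caps the
spread at ≈13.0); the solver then matches the mean exactly and brings
the SD as close as the family allows (≈12.9), rejecting configurations
that cannot come within 10%.  One consequence: the generated
severity–urge correlation is ≈0.36–0.37, slightly below the 0.40 a
real cohort showed — partly this spread cap, partly the default
independence between severity and comorbidity (an optional
`ygtss_comorbidity_shift` introduces dependence; default 0).

Outcomes are generated from the structural truth — by default the
calibration coefficients in `ticmediation.calibration` — with the urge
drawn univariately, (BRI, MI) drawn jointly at residual correlation
0.707, and GEC = BRI + MI by construction.  Intercepts are solved, not
configured: at the covariate means each linear predictor hits the
calibrated outcome mean, reproducing the cohort's location without
inventing values.  The generated BRI/MI marginal SDs land on the
model-implied values (≈12.0 and ≈17.1), about 10% above the observed
cohort SDs (10.88, 15.38) — the calibration's standardized column is
internally consistent with the model-implied variances, not the sample
ones, and the generator follows the structural truth.

**Clipping.**  Real PUTS totals cannot leave [9, 36].  With the
calibrated truth the marginal PUTS is ≈ Normal(14.47, 4.5²), so the
floor censors ≈11% of draws.  Defaults therefore separate two uses:
`clip_outcomes=True` (default) clips PUTS after noise, flags the count
in provenance, and yields cohorts valid under the strict instrument
ranges — the right choice for file-level pipelines and descriptives;
recovery, calibration and acceptance simulations set
`clip_outcomes=False`, because an 11% censoring rate attenuates linear
coefficients by roughly one posterior SD and recovery of a Gaussian
path model is only well-defined for the uncensored family.  Unclipped
cohorts carry relaxed PUTS bounds and provenance saying so.  Scores
stay continuous by default (`round_scores` rounds to integers as real
instruments do; off so recovery tests are clean).

Missingness is MCAR: each of the four measurement cells (PUTS, BRI,
MI, GEC) is blanked independently at `missing_rate` (default 0.003,
leaving ≈152–154 analyzable cases of 154); exogenous design columns
are protected by default.  MCAR is the weakest mechanism under which
the full-information likelihood is valid, and no stronger mechanism is
known for the emulated setting.

What passing tests on these cohorts do **not** show about real data:
robustness to floor effects and integer scoring, to informative
missingness, to non-Gaussian (skewed) score distributions, or to
informant bias in parent-rated instruments — none of which the
generator produces.

## Descriptive layer

Pearson correlations are computed on listwise-complete cases across
the requested variables (pairwise deletion available behind a flag),
p-values from the exact t transform with n−2 degrees of freedom,
two-sided.  Holm's step-down correction treats the k(k−1)/2
lower-triangle p-values as one family; ties are processed in
original-index order, and the result is tie-order invariant because
tied values interact only through the running maximum.  Stars mark
adjusted p < 0.05 / 0.01 / 0.001.  Cross-checks: scipy's pearsonr for
the t-based p, an independent multiple-testing implementation and a
brute-force sequential-rejection oracle for Holm.

Cohort summaries use the n−1 denominator for SDs; a variable with a
single observation reports no SD; group percentages are of the full
cohort including missing-coded rows.

## Standardization

Fully standardized (std.all) coefficients are
β = coefficient × SD(predictor term) / SD(outcome), with SDs computed
from the listwise-complete analyzed cases; product terms use the SD of
the constructed product column.  Standardized defined parameters are
composed from standardized paths (e.g. std-IMM = β(a4)·β(b)).
Residual variances standardize to σ²/Var(outcome) with the sample
variance in the denominator; residual correlations are scale-free.
Because the sample variance, not the model-implied one, is used, the
standardized residual shares differ slightly from a convention based on
model-implied variances — the difference is a few percent at the
calibrated truth and is noted here so reports are comparable across
the package's own runs.

## Numerical choices and degenerate inputs

* Conjugate draws use Cholesky factors of the posterior precision; a
  numerically collinear stage design (condition number of X'X above
  1e12 on complete cases) is rejected up front with a conditioning
  error naming the block.
* The slice sampler truncates its interval at domain boundaries
  (σ > 0, |ρ| < 1) and falls back to the current point after 200
  shrinkage steps (never observed in testing).
* GEC additivity (GEC = BRI + MI within 1e-9) is a validation error,
  never auto-repaired; instrument-range violations list the offending
  rows.
* Equal-tailed credible intervals use linearly interpolated
  percentiles of the pooled draws (verified against a sort-based
  oracle); the significance star means the 95% interval excludes 0.
* Defined quantities are summarized from per-draw evaluation (the
  posterior of the product); a separate point-consistency helper
  evaluates the same algebra at posterior means, which differs by the
  covariance of the factors — reports label which is which.

## Problem sizes

Replicate studies in the test suite use n = 300–1000 with 2 chains ×
200–300 warmup + 400–700 draws (100 recovery replicates, 50 PPP
calibration replicates); the acceptance script fits n = 8000 cohorts
with 4 chains × 400 warmup + 1000 draws and a 400-draw PPP subsample.
These sizes give Monte Carlo error well inside the tolerances asserted
while keeping a full run in minutes on one CPU; the caching noted above
makes larger n nearly free per iteration when data are complete.

## Known limitations

Cross-sectional path models: no causal identification beyond the
assumed ordering.  No latent/measurement layer; instrument totals are
taken at face value.  Comorbidity is one binary flag — disorder-specific
moderation (ADHD vs OCD) is out of scope.  The exogenous covariates are
never modelled, so missingness in them costs the whole subject.  The
PPP's saturated reference is a convention; its absolute value is
comparable across this package's runs, not across other software's
discrepancy choices.
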