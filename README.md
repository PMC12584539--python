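# ticmediation

Bayesian moderated-mediation path analysis for pediatric tic disorders:
does tic severity impair executive function *through* the premonitory
urge, and does psychiatric comorbidity amplify that pathway?

The package is aimed at clinical researchers working with cohort tables
of the three standard instruments — YGTSS total tic severity (motor +
vocal, 0–50), the 9-item PUTS premonitory-urge total (9–36), and the
parent-rated BRIEF executive-function composites (BRI + MI = GEC) — who
want a fully reproducible, testable implementation of the analysis
chain: descriptives, correlation screening, Bayesian structural path
models with MCMC, and the derived mediation quantities.

## The models

All models are triangular Gaussian path systems over observed scores,
conditioning on the exogenous design (YGTSS, age, sex, comorbidity).

**Simple mediation** (`model="simple"`):

```
PUTS ~ a·YGTSS + Age + Sex + Comorbidity
GEC  ~ b·PUTS + c′·YGTSS + Age + Sex + Comorbidity
indirect := a·b        total := c′ + a·b
```

**Simplified moderated mediation** (`model="simplified"`, the primary
model) — comorbidity C ∈ {0,1} moderates only the severity→urge path,
and the two executive-function indices are modelled jointly with
correlated residuals:

```
PUTS ~ a1·YGTSS + a2·Age + a4·(YGTSS×C)
BRI  ~ b1·PUTS + b2·YGTSS + b3·Age + b4·Sex + b5·C
MI   ~ c1·PUTS + c2·YGTSS + c3·Age + c4·Sex + c5·C,   BRI ~~ MI (ρ)
```

With the raw 0/1 coding the conditional indirect effects and the index
of moderated mediation (IMM) are exact coefficient products, evaluated
per posterior draw:

```
IE(o | C=0) = a1·b_o      IE(o | C=1) = (a1 + a4)·b_o
IMM(o)      = a4·b_o      = IE(o|C=1) − IE(o|C=0)        (o ∈ {BRI, MI})
```

A **full moderated** variant (`model="full"`) adds comorbidity products
on every stage and nests the simplified model.

Inference is by a blocked Gibbs sampler: conjugate multivariate-Normal
updates for coefficients/intercepts (the seemingly-unrelated-regressions
update for the bivariate BRI/MI stage), slice sampling for residual SDs
(Gamma(1, 0.5) priors) and the residual correlation (uniform on (−1,1)),
data augmentation for missing scores (full-information under MAR), with
split-Rhat convergence checks and a posterior-predictive p-value (PPP)
based on a stage-wise likelihood-ratio discrepancy.

Because no subject-level data ship with the package, a calibrated
synthetic-cohort generator (`ticmediation.simulate`) reproduces the
marginal and structural statistics of a reference clinic cohort
(n = 154, 84% boys, 53% comorbid), so every stage is testable
end-to-end.

## Worked example

```python
from ticmediation import BayesianPathModel, GeneratorConfig, generate_cohort

cohort = generate_cohort(GeneratorConfig(n=1000, seed=7, clip_outcomes=False))
model = BayesianPathModel(cohort, model="simplified")
results = model.fit(n_chains=4, n_warmup=500, n_draws=2000, seed=7)
print(results.summary())
print(f"max split-Rhat: {results.max_rhat():.3f}")
print(f"PPP: {results.ppp(seed=7, n_subsample=300):.3f}")
```

prints (abridged):

```
Bayesian path model: simplified_moderated
chains=4, kept draws/chain=2000
Structural parameters
 parameter estimate post_sd ci_2.5% ci_97.5% sig std_all  rhat
        a1    0.081   0.011   0.060    0.103   *   0.230 1.000
        a4    0.065   0.007   0.050    0.079   *   0.270 1.000
        b1    0.530   0.085   0.362    0.694   *   0.196 1.000
        c1    1.124   0.117   0.897    1.352   *   0.297 1.000
  ...
Defined parameters
 parameter estimate post_sd ci_2.5% ci_97.5% sig std_all
 ie_bri_c0    0.043   0.009   0.027    0.062   *   0.045
 ie_bri_c1    0.077   0.014   0.051    0.105   *   0.098
   imm_bri    0.034   0.007   0.022    0.049   *   0.053
    imm_mi    0.073   0.011   0.052    0.096   *   0.080
max split-Rhat: 1.004
PPP: 0.373
```

Reading this: each standard-deviation-unit of tic severity transmits a
small but credibly non-zero indirect effect onto both executive indices
via the urge, and the starred `imm_*` rows say the mediated effect is
credibly *stronger* in the comorbid group (the interval excludes 0).
`a4` is the severity×comorbidity interaction on the urge; `rho` (≈0.69
here) is the residual correlation between the two BRIEF indices.  All
split-Rhats are below 1.05 (converged) and the PPP is in the
well-fitting range around 0.5.

The same pipeline is scriptable from a shell:

```sh
ticmediation simulate --n 154 --seed 1 --out cohort.csv
ticmediation describe cohort.csv
ticmediation fit cohort.csv --model simplified --out fit/ \
    --chains 4 --warmup 2000 --draws 12500
ticmediation recover --n 1000 --seed 3   # simulate → refit → truth table
```

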