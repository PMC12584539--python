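"""Posterior summaries, mediation algebra, standardization, and PPP.

Derived mediation quantities (conditional indirect effects, the index of
moderated mediation, totals) are evaluated per posterior draw, so their
summaries describe the posterior of the product — not the product of the
posterior means.  A separate point-consistency helper evaluates the same
algebra at a single parameter point, which is how published tables of
posterior means can be checked (the two differ by the covariance between
the factors).

Model fit is checked with a posterior predictive p-value: for a subsample
of draws theta, replicate endogenous data are simulated on the observed
exogenous design and the chi-square-like discrepancy

    D(data, theta) = -2 [ logL(data | theta) - logL(data | saturated) ]

is compared between replicate and observed data; PPP is the fraction of
draws with D(replicate) >= D(observed).  The saturated reference refits,
per dataset and per stage, an ordinary least-squares regression of the
stage's outcomes on an enriched design (all exogenous main effects, all
pairwise products of exogenous variables, earlier outcomes, and their
products with the exogenous variables) with the empirical residual
covariance.  The enrichment nests every shipped model and gives the check
power against omitted interactions; it is a package convention, since
"chi-square-like" admits many concrete choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .pathmodel import (
    ModelError,
    ParameterVector,
    PathModelSpec,
    block_sigma,
    evaluate_defined,
    get_model_spec,
    linear_predictor,
    log_likelihood,
    term_column,
)
from .sampler import PosteriorDraws, split_rhat

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# scalar summaries
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Summary of one scalar posterior quantity."""

    name: str
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    significant: bool
    std_all: float | None = None
    rhat: float | None = None

    def as_row(self) -> dict:
        return {
            "parameter": self.name,
            "estimate": self.mean,
            "post_sd": self.sd,
            "ci_2.5%": self.ci_low,
            "ci_97.5%": self.ci_high,
            "sig": "*" if self.significant else "",
            "std_all": self.std_all,
            "rhat": self.rhat,
        }


def summarize_posterior(
    draws: PosteriorDraws | np.ndarray,
    quantity: str | None = None,
    ci: float = 0.95,
) -> PosteriorSummary:
    """Mean, SD (n-1), equal-tailed CI and significance of pooled draws.

    ``quantity`` may name a sampled parameter or an expression over path
    labels (e.g. ``"a4*b1"``), evaluated per draw.
    """
    if isinstance(draws, PosteriorDraws):
        if quantity is None:
            raise ValueError("quantity label required")
        if quantity in draws.arrays:
            x = draws.pooled(quantity)
            rhat = split_rhat(draws, quantity)
        else:
            x = evaluate_expression(draws, quantity).reshape(-1)
            rhat = None
        name = quantity
    else:
        x = np.asarray(draws, dtype=float).reshape(-1)
        name = quantity or "quantity"
        rhat = None
    if x.size < 2:
        raise ValueError("need at least 2 pooled draws")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(x, [100 * alpha, 100 * (1 - alpha)])
    return PosteriorSummary(
        name=name,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        rhat=rhat,
    )


def evaluate_expression(draws: PosteriorDraws, expr: str) -> np.ndarray:
    """Evaluate an algebraic expression over path labels per draw."""
    env = {k: v for k, v in draws.arrays.items()}
    try:
        return np.asarray(eval(expr, {"__builtins__": {}}, env), dtype=float)  # noqa: S307
    except NameError as err:
        raise ModelError(f"expression {expr!r}: {err}") from None


def derived_effects(
    draws: PosteriorDraws, model: PathModelSpec | str | None = None
) -> dict[str, np.ndarray]:
    """Per-draw values of every defined parameter of the model.

    Evaluating per draw keeps the algebraic identities exact draw by draw
    (e.g. IMM = IE(C=1) - IE(C=0) for every sample) and makes the
    summaries posterior-correct for the products.
    """
    spec = get_model_spec(model) if model is not None else draws.spec
    return {
        name: evaluate_expression(draws, expr)
        for name, expr in spec.defined_parameters.items()
    }


def point_consistency(
    point: ParameterVector | Mapping[str, float], model: PathModelSpec | str
) -> dict[str, float]:
    """Defined-parameter algebra at a single parameter point.

    Used to check tables of posterior means: the product of means
    approximates the mean of the per-draw product up to the covariance of
    the factors.
    """
    spec = get_model_spec(model)
    coefs = point.coefficients if isinstance(point, ParameterVector) else dict(point)
    return evaluate_defined(spec, coefs)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def _analysis_sds(cohort, spec: PathModelSpec) -> tuple[dict, dict]:
    """Sample SDs of term columns and outcomes on listwise-complete cases."""
    df = cohort.df if hasattr(cohort, "df") else cohort
    cols = spec.exogenous + spec.outcomes
    data = df[cols].dropna()
    if len(data) < 3:
        raise ValueError("too few complete cases to standardize")
    term_sd: dict[str, float] = {}
    for eq in spec.equations:
        for lab, term in eq.terms:
            sd = float(np.std(term_column(data, term), ddof=1))
            if sd == 0.0:
                raise ValueError(f"zero variance for term {term} (label {lab})")
            term_sd[lab] = sd
    out_sd = {}
    for o in spec.outcomes:
        sd = float(data[o].std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"zero variance for outcome {o}")
        out_sd[o] = sd
    return term_sd, out_sd


def standardize(
    params: ParameterVector | PosteriorDraws,
    cohort,
    model: PathModelSpec | str | None = None,
) -> dict[str, float] | dict[str, np.ndarray]:
    """Fully standardized (std.all) coefficients and defined parameters.

    beta = coefficient x SD(predictor term) / SD(outcome), with SDs taken
    from the analyzed cases; product terms use the SD of the constructed
    product column.  Defined parameters are composed from the standardized
    paths.  Residual SDs standardize to sigma^2 / Var(outcome); residual
    correlations are already scale-free.

    Accepts a single point (returns floats) or posterior draws (returns
    per-draw arrays).
    """
    if isinstance(params, PosteriorDraws):
        spec = get_model_spec(model) if model is not None else params.spec
    else:
        spec = get_model_spec(model)
    term_sd, out_sd = _analysis_sds(cohort, spec)

    def label_outcome():
        return {lab: eq.outcome for eq in spec.equations for lab, _ in eq.terms}

    lab_out = label_outcome()
    if isinstance(params, ParameterVector):
        std = {
            lab: params.coefficients[lab] * term_sd[lab] / out_sd[lab_out[lab]]
            for lab in spec.path_labels
        }
        std.update(evaluate_defined(spec, std))
        for o in spec.outcomes:
            std[f"sigma_{o}"] = params.residual_sd[o] ** 2 / out_sd[o] ** 2
        for (a, b), r in params.residual_corr.items():
            std[f"rho_{a}_{b}"] = r
        return std

    draws = params
    std_arr: dict[str, np.ndarray] = {
        lab: draws[lab] * (term_sd[lab] / out_sd[lab_out[lab]])
        for lab in spec.path_labels
    }
    env = dict(std_arr)
    for name, expr in spec.defined_parameters.items():
        std_arr[name] = np.asarray(
            eval(expr, {"__builtins__": {}}, env), dtype=float  # noqa: S307
        )
    for o in spec.outcomes:
        std_arr[f"sigma_{o}"] = draws[f"sigma_{o}"] ** 2 / out_sd[o] ** 2
    for a, b in spec.residual_correlation_pairs:
        std_arr[f"rho_{a}_{b}"] = draws[f"rho_{a}_{b}"]
    return std_arr


# ---------------------------------------------------------------------------
# posterior predictive p-value
# ---------------------------------------------------------------------------

def _saturated_designs(spec: PathModelSpec, df: pd.DataFrame) -> list[np.ndarray]:
    """Enriched per-block design matrices for the saturated reference.

    Each stage regresses on: intercept, every exogenous main effect,
    every earlier outcome, and — for each declared moderator — the
    moderator's products with the other design columns.  This nests the
    shipped models (whose restrictions are omitted main effects and
    omitted moderation products) while keeping the reference's extra
    degrees of freedom small, so the null distribution of the
    discrepancy stays comparable between observed and replicated data.
    """
    exo = spec.exogenous
    n = len(df)

    def col(v):
        return df[v].to_numpy(dtype=float)

    designs = []
    earlier: list[str] = []
    for block in spec.blocks():
        stage_vars = exo + earlier
        cols = [np.ones(n)] + [col(v) for v in stage_vars]
        for mvar in spec.moderators:
            mcol = col(mvar)
            cols += [mcol * col(v) for v in stage_vars if v != mvar]
        designs.append(np.column_stack(cols))
        earlier.extend(block)
    return designs


def _saturated_loglike(spec: PathModelSpec, df: pd.DataFrame) -> float:
    """Stage-wise Gaussian log likelihood at the empirical moments."""
    n = len(df)
    total = 0.0
    for block, X in zip(spec.blocks(), _saturated_designs(spec, df)):
        Y = df[list(block)].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        E = Y - X @ coef
        k = len(block)
        S = (E.T @ E) / n
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("singular empirical residual covariance")
        total += -0.5 * n * (k * _LOG2PI + logdet + k)
    return float(total)


def _simulate_endogenous(
    spec: PathModelSpec,
    params: ParameterVector,
    df: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Replicate endogenous data on an observed exogenous design."""
    out = df.copy()
    n = len(out)
    for block in spec.blocks():
        S = block_sigma(spec, params, block)
        chol = np.linalg.cholesky(S)
        eps = rng.standard_normal((n, len(block))) @ chol.T
        for j, o in enumerate(block):
            out[o] = linear_predictor(out, spec.equation(o), params) + eps[:, j]
    return out


def ppp(
    draws: PosteriorDraws,
    model: PathModelSpec | str | None = None,
    cohort=None,
    seed: int = 0,
    n_subsample: int = 1000,
) -> float:
    """Posterior predictive p-value with the stage-wise LR discrepancy.

    Uses an evenly spaced subsample of pooled draws (default 1000) and
    complete cases; deterministic given ``seed`` and the subsample size.
    Values near 0.5 indicate that replicated cohorts are about as
    discrepant as the observed one (good fit); values near 0 or 1 flag
    systematic misfit.
    """
    spec = get_model_spec(model) if model is not None else draws.spec
    if cohort is None:
        raise ValueError("cohort required")
    df = cohort.df if hasattr(cohort, "df") else cohort
    cols = spec.exogenous + spec.outcomes
    # canonical row order: the check must not depend on how subjects are
    # listed, and replicate noise is assigned by row position
    data = df[cols].dropna().sort_values(cols, kind="stable").reset_index(drop=True)
    if len(data) < 10:
        raise ValueError("too few complete cases for a predictive check")

    pooled_n = draws.n_chains * draws.n_draws
    if pooled_n < 10:
        raise ValueError("too few draws for a predictive check")
    n_sub = min(n_subsample, pooled_n)
    idx = np.linspace(0, pooled_n - 1, n_sub).astype(int)

    rng = np.random.default_rng(seed)
    sat_obs = _saturated_loglike(spec, data)
    exceed = 0
    for t in idx:
        c, d = divmod(int(t), draws.n_draws)
        theta = draws.parameter_vector_at(c, d)
        ll_obs = log_likelihood(spec, theta, data)
        d_obs = -2.0 * (ll_obs - sat_obs)
        rep = _simulate_endogenous(spec, theta, data, rng)
        ll_rep = log_likelihood(spec, theta, rep)
        d_rep = -2.0 * (ll_rep - _saturated_loglike(spec, rep))
        if d_rep >= d_obs:
            exceed += 1
    return exceed / n_sub


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def summary_table(
    draws: PosteriorDraws,
    cohort=None,
    model: PathModelSpec | str | None = None,
    include_derived: bool = True,
) -> pd.DataFrame:
    """Path-analysis report: Estimate, Post.SD, 95% CI, Sig, Std.all, Rhat.

    Structural parameters are summarized from the sampled draws; defined
    mediation quantities (when ``include_derived``) from their per-draw
    values.  Std.all columns require a cohort for the SDs.
    """
    spec = get_model_spec(model) if model is not None else draws.spec
    std = standardize(draws, cohort, spec) if cohort is not None else {}

    rows = []
    for name in draws.param_names:
        s = summarize_posterior(draws, name)
        if name in std:
            s.std_all = float(np.mean(std[name]))
        row = s.as_row()
        row["kind"] = "structural"
        rows.append(row)
    if include_derived:
        for name, values in derived_effects(draws, spec).items():
            s = summarize_posterior(values, name)
            if name in std:
                s.std_all = float(np.mean(std[name]))
            row = s.as_row()
            row["kind"] = "derived"
            rows.append(row)
    return pd.DataFrame(rows)
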