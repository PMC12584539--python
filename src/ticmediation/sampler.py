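"""Posterior sampling for triangular Gaussian path models.

The sampler is a blocked Gibbs scheme exploiting the model's structure:

* regression coefficients and intercepts of each stage are drawn jointly
  from their exact conditional — a multivariate Normal, conjugate under
  the Normal(0, 10) prior given the stage's residual covariance (for the
  bivariate BRI/MI stage this is the seemingly-unrelated-regressions
  update with the 2x2 residual precision);
* residual standard deviations (Gamma(1, 0.5) prior, shape/rate, mean 2)
  and the residual correlation (Beta(1, 1) on (rho+1)/2, i.e. uniform on
  (-1, 1)) are updated by univariate slice sampling on their scalar
  conditionals, which depend on the data only through residual
  cross-products;
* missing endogenous cells are sampled by data augmentation from each
  subject's exact Gaussian conditional given its observed scores and the
  current parameters, satisfying the full-information contract under MAR.

The stationary distribution is likelihood x prior; the kernel is an
implementation choice.  Runs are fully reproducible: chain c uses the
generator seeded with (seed, c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .pathmodel import (
    ParameterVector,
    PathModelSpec,
    conditional_endogenous,
    get_model_spec,
)

_LOG2PI = math.log(2.0 * math.pi)


class ConditioningError(ValueError):
    """Numerically rank-deficient design in one of the stages."""


class SamplerError(RuntimeError):
    """Sampling could not start or proceed."""


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Weakly informative priors for all parameter classes.

    ``coef_scale`` is the standard deviation of the Normal(0, scale)
    prior on every regression coefficient.  Intercepts get their own
    ``intercept_scale``: on raw clinical scales (outcome means 14-138)
    a zero-centred scale-10 prior is *not* weak — it visibly shrinks
    location parameters at cohort sizes in the hundreds-to-thousands
    (and, through the uncentred design, biases the age paths with them)
    — so the default is a genuinely weak 100.  ``sd_shape``/``sd_rate``
    give the Gamma prior on each residual SD in the shape/rate
    convention (defaults: shape 1, rate 0.5, mean 2).  The residual
    correlation has a Beta(``corr_a``, ``corr_b``) prior on (rho+1)/2;
    the default Beta(1, 1) is uniform on (-1, 1).
    """

    coef_scale: float = 10.0
    intercept_scale: float = 100.0
    sd_shape: float = 1.0
    sd_rate: float = 0.5
    corr_a: float = 1.0
    corr_b: float = 1.0

    def log_normal(self, x: float, scale: float | None = None) -> float:
        s = self.coef_scale if scale is None else scale
        return -0.5 * (_LOG2PI + 2.0 * math.log(s)) - x * x / (2.0 * s * s)

    def log_sd(self, sigma: float) -> float:
        if sigma <= 0 or not math.isfinite(sigma):
            return -math.inf
        a, r = self.sd_shape, self.sd_rate
        return a * math.log(r) - math.lgamma(a) + (a - 1.0) * math.log(sigma) - r * sigma

    def log_corr(self, rho: float) -> float:
        if not (-1.0 < rho < 1.0):
            return -math.inf
        a, b = self.corr_a, self.corr_b
        u = 0.5 * (rho + 1.0)
        logbeta = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
        return (a - 1.0) * math.log(u) + (b - 1.0) * math.log1p(-u) - logbeta - math.log(2.0)


def log_prior(params: ParameterVector, prior: PriorSpec | None = None) -> float:
    """Joint log prior density of a parameter point (−inf off-support)."""
    prior = prior or PriorSpec()
    total = 0.0
    for v in params.coefficients.values():
        total += prior.log_normal(v)
    for v in params.intercepts.values():
        total += prior.log_normal(v, scale=prior.intercept_scale)
    for s in params.residual_sd.values():
        total += prior.log_sd(s)
        if not math.isfinite(total):
            return -math.inf
    for r in params.residual_corr.values():
        total += prior.log_corr(r)
        if not math.isfinite(total):
            return -math.inf
    return total


# ---------------------------------------------------------------------------
# configuration / draws containers
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """MCMC schedule.  Defaults mirror the published analysis settings
    (4 chains x 2,000 warmup + 12,500 kept draws = 50,000 posterior
    samples); reduced schedules are used for tests and quick runs.
    """

    n_chains: int = 4
    n_warmup: int = 2000
    n_draws: int = 12500
    seed: int = 0
    thin: int = 1
    prior_only: bool = False
    #: parameters (flat names, e.g. "sigma_gec_raw") held fixed at a value;
    #: only residual SDs / correlations may be fixed
    fixed: dict = field(default_factory=dict)
    max_init_retries: int = 20

    def validate(self) -> None:
        for name in ("n_chains", "n_warmup", "n_draws", "thin"):
            if getattr(self, name) < 1 and name != "n_warmup":
                raise ValueError(f"{name} must be >= 1")
        if self.n_warmup < 0:
            raise ValueError("n_warmup must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains,
            "n_warmup": self.n_warmup,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "thin": self.thin,
            "prior_only": self.prior_only,
            "fixed": dict(self.fixed),
        }


class PosteriorDraws:
    """Per-chain posterior draws plus sampler metadata.

    ``arrays`` maps each flat parameter name to a (n_chains, n_draws)
    array.  Derived per-draw quantities can be attached under new names.
    """

    def __init__(
        self,
        spec: PathModelSpec,
        arrays: dict[str, np.ndarray],
        config: SamplerConfig,
        n_dropped: int = 0,
        diagnostics: dict | None = None,
    ):
        self.spec = spec
        self.arrays = arrays
        self.config = config
        self.n_dropped = n_dropped
        self.diagnostics = diagnostics or {}
        shapes = {a.shape for a in arrays.values()}
        if len(shapes) != 1:
            raise ValueError("all parameter arrays must share (chains, draws) shape")
        self.n_chains, self.n_draws = shapes.pop()

    @property
    def param_names(self) -> list[str]:
        return list(self.arrays)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.arrays[name]
        except KeyError:
            raise KeyError(
                f"unknown parameter {name!r}; available: {self.param_names}"
            ) from None

    def pooled(self, name: str) -> np.ndarray:
        return self[name].reshape(-1)

    def parameter_vector_at(self, chain: int, draw: int) -> ParameterVector:
        flat = {k: float(v[chain, draw]) for k, v in self.arrays.items()}
        return _unflatten(self.spec, flat)

    def posterior_mean_vector(self) -> ParameterVector:
        flat = {k: float(v.mean()) for k, v in self.arrays.items()}
        return _unflatten(self.spec, flat)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"chain": np.repeat(np.arange(self.n_chains), self.n_draws)}
        cols["draw"] = np.tile(np.arange(self.n_draws), self.n_chains)
        for k, v in self.arrays.items():
            cols[k] = v.reshape(-1)
        return pd.DataFrame(cols)

    def to_arviz(self):
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.arrays.items()})


def _unflatten(spec: PathModelSpec, flat: Mapping[str, float]) -> ParameterVector:
    coefs = {lab: flat[lab] for lab in spec.path_labels}
    intercepts = {o: flat[f"intercept_{o}"] for o in spec.outcomes}
    sds = {o: flat[f"sigma_{o}"] for o in spec.outcomes}
    corr = {
        tuple(p): flat[f"rho_{p[0]}_{p[1]}"] for p in spec.residual_correlation_pairs
    }
    return ParameterVector(coefs, intercepts, sds, corr)


# ---------------------------------------------------------------------------
# slice sampler
# ---------------------------------------------------------------------------

def _slice_sample(x0, logf, rng, w, lo=-np.inf, hi=np.inf, max_steps=50):
    """Univariate slice sampling with stepping out and shrinkage."""
    f0 = logf(x0)
    if not np.isfinite(f0):
        raise SamplerError(f"slice sampler started at log-density {f0}")
    logy = f0 - rng.exponential()
    u = rng.random()
    left = max(x0 - u * w, lo)
    right = min(left + w, hi)
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and left > lo and logf(left) > logy:
        left = max(left - w, lo)
        j -= 1
    while k > 0 and right < hi and logf(right) > logy:
        right = min(right + w, hi)
        k -= 1
    for _ in range(200):
        x1 = left + rng.random() * (right - left)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pathological shrinkage; keep current point


# ---------------------------------------------------------------------------
# block machinery
# ---------------------------------------------------------------------------

class _Block:
    """One sampling stage: 1 or 2 equations with a common residual law."""

    def __init__(self, spec: PathModelSpec, outcomes: tuple[str, ...]):
        self.outcomes = outcomes
        self.eqs = [spec.equation(o) for o in outcomes]
        self.labels = [
            [f"intercept_{eq.outcome}"] + [lab for lab, _ in eq.terms]
            for eq in self.eqs
        ]
        self.pair = tuple(outcomes) if len(outcomes) == 2 else None

    def designs(self, cols: Mapping[str, np.ndarray], n: int) -> list[np.ndarray]:
        out = []
        for eq in self.eqs:
            mats = [np.ones(n)]
            for _, term in eq.terms:
                col = cols[term[0]]
                for v in term[1:]:
                    col = col * cols[v]
                mats.append(col)
            out.append(np.column_stack(mats))
        return out


def _bivariate_resid_loglike(n, S11, S22, S12, s1, s2, rho):
    om = 1.0 - rho * rho
    if om <= 0 or s1 <= 0 or s2 <= 0:
        return -math.inf
    quad = S11 / (s1 * s1) - 2.0 * rho * S12 / (s1 * s2) + S22 / (s2 * s2)
    return -n * (math.log(s1) + math.log(s2) + 0.5 * math.log(om)) - quad / (2.0 * om)


# ---------------------------------------------------------------------------
# main sampler
# ---------------------------------------------------------------------------

def sample_posterior(
    model: PathModelSpec | str,
    cohort,
    prior: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorDraws:
    """Draw from the posterior of a path model given a cohort.

    Subjects missing an exogenous design value are dropped with a count
    (``result.n_dropped``); missing endogenous cells are data-augmented.
    With ``config.prior_only`` the likelihood is switched off and i.i.d.
    prior draws are returned (for prior predictive/calibration checks).
    """
    spec = get_model_spec(model)
    prior = prior or PriorSpec()
    config = config or SamplerConfig()
    config.validate()

    for name in config.fixed:
        if not (name.startswith("sigma_") or name.startswith("rho_")):
            raise ValueError(
                "only residual SDs / correlations may be fixed "
                f"(got {name!r})"
            )

    df = cohort.df if hasattr(cohort, "df") else cohort
    exo = spec.exogenous
    outs = spec.outcomes
    keep = df[exo].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    data = df.loc[keep, exo + outs].reset_index(drop=True)
    n = len(data)
    if n == 0 and not config.prior_only:
        raise SamplerError("no subjects with complete exogenous design")

    blocks = [_Block(spec, b) for b in spec.blocks()]
    flat_names = (
        [f"intercept_{o}" for o in outs]
        + list(spec.path_labels)
        + [f"sigma_{o}" for o in outs]
        + [f"rho_{a}_{b}" for a, b in spec.residual_correlation_pairs]
    )

    total_kept = config.n_draws
    arrays = {
        k: np.empty((config.n_chains, total_kept)) for k in flat_names
    }

    if config.prior_only:
        for c in range(config.n_chains):
            rng = np.random.default_rng([config.seed, c])
            for k in flat_names:
                if k in config.fixed:
                    arrays[k][c] = config.fixed[k]
                elif k.startswith("sigma_"):
                    arrays[k][c] = rng.gamma(
                        prior.sd_shape, 1.0 / prior.sd_rate, total_kept
                    )
                elif k.startswith("rho_"):
                    arrays[k][c] = (
                        2.0 * rng.beta(prior.corr_a, prior.corr_b, total_kept) - 1.0
                    )
                elif k.startswith("intercept_"):
                    arrays[k][c] = rng.normal(0.0, prior.intercept_scale, total_kept)
                else:
                    arrays[k][c] = rng.normal(0.0, prior.coef_scale, total_kept)
        return PosteriorDraws(spec, arrays, config, n_dropped, {"prior_only": True})

    # subjects needing data augmentation
    endo_mask = data[outs].isna()
    partial_idx = np.where(endo_mask.any(axis=1).to_numpy())[0]
    partial_info = []
    for i in partial_idx:
        row = data.iloc[i]
        observed = {o: float(row[o]) for o in outs if not pd.isna(row[o])}
        partial_info.append((int(i), row, observed))
    static = len(partial_idx) == 0

    obs_mean = {o: float(data[o].mean()) for o in outs}
    obs_sd = {
        o: float(data[o].std(ddof=1)) if data[o].notna().sum() > 1 else 1.0
        for o in outs
    }
    for o in outs:
        if not math.isfinite(obs_mean[o]):
            obs_mean[o] = 0.0
        if not (obs_sd[o] > 0) or not math.isfinite(obs_sd[o]):
            obs_sd[o] = 1.0

    base_cols = {v: data[v].to_numpy(dtype=float).copy() for v in exo + outs}

    # design conditioning check on complete-endogenous subjects
    complete = data.dropna(subset=outs)
    if len(complete) > max(8, len(exo) + 2):
        ccols = {v: complete[v].to_numpy(dtype=float) for v in exo + outs}
        for blk in blocks:
            for X in blk.designs(ccols, len(complete)):
                if np.linalg.cond(X.T @ X) > 1e12:
                    raise ConditioningError(
                        f"design for block {blk.outcomes} is numerically "
                        "collinear; drop or recode redundant predictors"
                    )

    # per-block prior precision diagonals (intercept first in each equation)
    block_prior_prec = []
    for blk in blocks:
        diags = []
        for eq in blk.eqs:
            diags.append(
                np.array(
                    [1.0 / prior.intercept_scale**2]
                    + [1.0 / prior.coef_scale**2] * len(eq.terms)
                )
            )
        block_prior_prec.append(diags)

    n_iter = config.n_warmup + config.n_draws * config.thin
    slice_evals = 0

    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        cols = {k: v.copy() for k, v in base_cols.items()}
        # initialize: coefficients 0, intercepts/SDs at data moments, jittered
        state: dict[str, float] = {}
        for lab in spec.path_labels:
            state[lab] = 0.1 * rng.standard_normal()
        for o in outs:
            state[f"intercept_{o}"] = obs_mean[o] * (1.0 + 0.05 * rng.standard_normal())
            state[f"sigma_{o}"] = obs_sd[o] * math.exp(0.2 * rng.standard_normal())
        for a, b in spec.residual_correlation_pairs:
            state[f"rho_{a}_{b}"] = float(np.clip(0.2 * rng.standard_normal(), -0.9, 0.9))
        state.update(config.fixed)

        # start imputed cells at observed means
        for i, _, observed in partial_info:
            for o in outs:
                if o not in observed:
                    cols[o][i] = obs_mean[o]

        kept = 0
        stats_cache = None
        for it in range(n_iter):
            params = _unflatten(spec, state)

            # -- data augmentation ------------------------------------------
            if partial_info:
                for i, row, observed in partial_info:
                    miss, cmean, ccov = conditional_endogenous(
                        spec, params, row, observed
                    )
                    if len(miss) == 1:
                        val = cmean[0] + math.sqrt(max(ccov[0, 0], 0.0)) * rng.standard_normal()
                        cols[miss[0]][i] = val
                    else:
                        L = np.linalg.cholesky(ccov)
                        vals = cmean + L @ rng.standard_normal(len(miss))
                        for o, v in zip(miss, vals):
                            cols[o][i] = v
                stats_cache = None

            # -- per block: conjugate coefficients, slice residual params ---
            for bi, blk in enumerate(blocks):
                if stats_cache is None or not static:
                    Xs = blk.designs(cols, n)
                    ys = [cols[o] for o in blk.outcomes]
                    XtX = [[Xj.T @ Xk for Xk in Xs] for Xj in Xs]
                    Xty = [[Xj.T @ yk for yk in ys] for Xj in Xs]
                    yty = [[float(yj @ yk) for yk in ys] for yj in ys]
                    blk._stats = (XtX, Xty, yty)
                XtX, Xty, yty = blk._stats

                k = len(blk.outcomes)
                sds = [state[f"sigma_{o}"] for o in blk.outcomes]
                pdiags = block_prior_prec[bi]
                if k == 1:
                    prec = XtX[0][0] / sds[0] ** 2
                    prec = prec + np.diag(pdiags[0])
                    rhs = Xty[0][0] / sds[0] ** 2
                else:
                    rho = state[f"rho_{blk.pair[0]}_{blk.pair[1]}"]
                    det = sds[0] ** 2 * sds[1] ** 2 * (1.0 - rho**2)
                    W = (
                        np.array(
                            [
                                [sds[1] ** 2, -rho * sds[0] * sds[1]],
                                [-rho * sds[0] * sds[1], sds[0] ** 2],
                            ]
                        )
                        / det
                    )
                    prec = np.block(
                        [
                            [W[0, 0] * XtX[0][0], W[0, 1] * XtX[0][1]],
                            [W[1, 0] * XtX[1][0], W[1, 1] * XtX[1][1]],
                        ]
                    ) + np.diag(np.concatenate(pdiags))
                    rhs = np.concatenate(
                        [
                            W[0, 0] * Xty[0][0] + W[0, 1] * Xty[0][1],
                            W[1, 0] * Xty[1][0] + W[1, 1] * Xty[1][1],
                        ]
                    )
                try:
                    L = np.linalg.cholesky(prec)
                except np.linalg.LinAlgError as err:
                    raise ConditioningError(
                        f"singular conditional precision in block {blk.outcomes}"
                    ) from err
                mean = np.linalg.solve(prec, rhs)
                z = rng.standard_normal(len(rhs))
                beta = mean + np.linalg.solve(L.T, z)

                pos = 0
                for labels in blk.labels:
                    for lab in labels:
                        state[lab] = float(beta[pos])
                        pos += 1

                # residual cross-products at the new coefficients
                betas = []
                pos = 0
                for labels in blk.labels:
                    betas.append(beta[pos : pos + len(labels)])
                    pos += len(labels)
                S = np.empty((k, k))
                for j in range(k):
                    for m in range(j, k):
                        val = (
                            yty[j][m]
                            - betas[j] @ Xty[j][m]
                            - betas[m] @ Xty[m][j]
                            + betas[j] @ (XtX[j][m] @ betas[m])
                        )
                        S[j, m] = S[m, j] = val

                if k == 1:
                    name = f"sigma_{blk.outcomes[0]}"
                    if name not in config.fixed:
                        S00 = S[0, 0]

                        def logf(s, S00=S00):
                            if s <= 0:
                                return -math.inf
                            return (
                                -n * math.log(s)
                                - S00 / (2.0 * s * s)
                                + prior.log_sd(s)
                            )

                        state[name] = _slice_sample(
                            state[name], logf, rng, w=0.5 * state[name] + 0.05, lo=1e-9
                        )
                        slice_evals += 1
                else:
                    rname = f"rho_{blk.pair[0]}_{blk.pair[1]}"
                    S11, S22, S12 = S[0, 0], S[1, 1], S[0, 1]
                    for j, o in enumerate(blk.outcomes):
                        name = f"sigma_{o}"
                        if name in config.fixed:
                            continue
                        other = state[f"sigma_{blk.outcomes[1 - j]}"]
                        rho = state[rname]

                        def logf(s, j=j, other=other, rho=rho):
                            if s <= 0:
                                return -math.inf
                            s1, s2 = (s, other) if j == 0 else (other, s)
                            return (
                                _bivariate_resid_loglike(n, S11, S22, S12, s1, s2, rho)
                                + prior.log_sd(s)
                            )

                        state[name] = _slice_sample(
                            state[name], logf, rng, w=0.5 * state[name] + 0.05, lo=1e-9
                        )
                        slice_evals += 1
                    if rname not in config.fixed:
                        s1 = state[f"sigma_{blk.outcomes[0]}"]
                        s2 = state[f"sigma_{blk.outcomes[1]}"]

                        def logr(r):
                            return (
                                _bivariate_resid_loglike(n, S11, S22, S12, s1, s2, r)
                                + prior.log_corr(r)
                            )

                        state[rname] = _slice_sample(
                            state[rname],
                            logr,
                            rng,
                            w=0.25,
                            lo=-1.0 + 1e-9,
                            hi=1.0 - 1e-9,
                        )
                        slice_evals += 1
            stats_cache = True

            if it >= config.n_warmup and (it - config.n_warmup) % config.thin == 0:
                for name in flat_names:
                    arrays[name][c, kept] = state[name]
                kept += 1

    diagnostics = {
        "n_partial_subjects": len(partial_info),
        "slice_updates": slice_evals,
    }
    return PosteriorDraws(spec, arrays, config, n_dropped, diagnostics)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def split_rhat(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> float:
    """Split-chain potential scale reduction factor.

    Each chain is halved, within- (W) and between-half-chain (B) variances
    are combined into the pooled variance estimate, and the square root of
    their ratio is returned.  Chains with zero variance everywhere give
    ``nan`` (undefined, e.g. a parameter held fixed).
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter label required")
        arr = draws[parameter]
    else:
        arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise ValueError("draws must have shape (chains, draws)")
    m, n = arr.shape
    if m < 2 or n < 4:
        raise ValueError("need at least 2 chains of at least 4 draws")
    half = n // 2
    halves = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    within = halves.var(axis=1, ddof=1)
    W = float(within.mean())
    B = half * float(halves.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return math.nan
    var_hat = (half - 1) / half * W + B / half
    return math.sqrt(var_hat / W)


@dataclass
class ConvergenceReport:
    """Per-parameter split-Rhat table with an overall verdict."""

    table: pd.DataFrame
    threshold: float
    passed: bool
    failing: list[str]
    undefined: list[str]

    def __str__(self) -> str:
        verdict = "PASS" if self.passed else f"FAIL ({', '.join(self.failing)})"
        lines = [f"Convergence (split-Rhat < {self.threshold:g}): {verdict}"]
        lines.append(self.table.to_string(index=False))
        if self.undefined:
            lines.append(f"undefined (zero-variance) parameters: {self.undefined}")
        return "\n".join(lines)


def check_convergence(
    draws: PosteriorDraws, threshold: float = 1.05
) -> ConvergenceReport:
    """Split-Rhat for every sampled parameter against a threshold."""
    rows = []
    failing, undefined = [], []
    for name in draws.param_names:
        r = split_rhat(draws, name)
        rows.append({"parameter": name, "rhat": r})
        if math.isnan(r):
            undefined.append(name)
        elif not r < threshold:
            failing.append(name)
    table = pd.DataFrame(rows)
    return ConvergenceReport(
        table=table,
        threshold=threshold,
        passed=not failing,
        failing=failing,
        undefined=undefined,
    )
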