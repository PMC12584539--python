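"""Synthetic cohort generation for the tic-severity mediation models.

Emulates the statistical structure the analysis assumes: exogenous
covariates drawn from the calibrated marginals (sex and comorbidity as
Bernoulli flags, age and YGTSS total tic severity as truncated Normals),
endogenous scores generated from a :class:`PathModelSpec` at a known
``ParameterVector`` truth (urge from its linear predictor, BRI and MI
jointly with correlated residuals, GEC = BRI + MI), and optional MCAR
missingness in the measurement cells.

Intercepts are solved rather than configured: at the covariate means the
linear predictor of each equation hits the configured marginal mean of
its outcome, so the generated cohort has the calibrated locations without
inventing intercept values.

What the generator does *not* emulate: integer item-level scoring (scores
stay continuous unless ``round_scores``), instrument floor/ceiling
effects (off unless ``clip_outcomes`` — at the default truth the PUTS
floor would censor ≈11% of draws and bias linear-model recovery), and any
covariate-dependent missingness mechanism (MCAR only).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import calibration
from .cohort import CohortTable, COLUMNS
from .pathmodel import (
    ModelError,
    ParameterVector,
    PathModelSpec,
    block_sigma,
    get_model_spec,
    linear_predictor,
)

#: columns eligible for MCAR blanking when exogenous columns are protected
MEASUREMENT_CELLS = ["puts_total", "bri_raw", "mi_raw", "gec_raw"]

#: marginal mean targets used when solving intercepts
OUTCOME_MEAN_TARGETS = {
    "puts_total": calibration.COHORT_MARGINALS["puts_mean"],
    "bri_raw": calibration.COHORT_MARGINALS["bri_mean"],
    "mi_raw": calibration.COHORT_MARGINALS["mi_mean"],
    "gec_raw": calibration.COHORT_MARGINALS["gec_mean"],
}


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Study-condition knobs for one synthetic cohort.

    Defaults reproduce the calibrated clinic cohort: n = 154, 84.4% boys,
    53.25% with a comorbid diagnosis, age 9.29 ± 1.95 y truncated to
    [6, 16], YGTSS 32.71 ± 13.17 truncated to [0, 50], structural truth
    from :mod:`ticmediation.calibration`, and a 0.3% per-cell MCAR rate
    that leaves ≈152-154 analyzable cases out of 154.
    """

    n: int = calibration.COHORT_MARGINALS["n"]
    seed: int = 0
    prevalence_comorbidity: float = calibration.COHORT_MARGINALS["prevalence_comorbidity"]
    prevalence_female: float = calibration.COHORT_MARGINALS["prevalence_female"]
    age_mean: float = calibration.COHORT_MARGINALS["age_mean"]
    age_sd: float = calibration.COHORT_MARGINALS["age_sd"]
    age_bounds: tuple[float, float] = (6.0, 16.0)
    ygtss_mean: float = calibration.COHORT_MARGINALS["ygtss_mean"]
    ygtss_sd: float = calibration.COHORT_MARGINALS["ygtss_sd"]
    ygtss_bounds: tuple[float, float] = (0.0, 50.0)
    #: shift (score units) of the comorbid group's YGTSS mean relative to
    #: the non-comorbid group, keeping the overall mean fixed; 0 keeps
    #: severity independent of comorbidity
    ygtss_comorbidity_shift: float = 0.0
    model: str = "simplified"
    truth: ParameterVector | None = None
    missing_rate: float = 0.003
    protect_exogenous: bool = True
    #: clip PUTS to the instrument range after adding noise (the clip count
    #: is flagged in provenance).  At the default truth the floor censors
    #: ≈11% of draws, which attenuates linear-model recovery — recovery
    #: and calibration studies should set this to False (scores then stay
    #: continuous and the cohort carries relaxed PUTS bounds).
    clip_outcomes: bool = True
    puts_bounds: tuple[float, float] = (9.0, 36.0)
    round_scores: bool = False

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        for name in ("prevalence_comorbidity", "prevalence_female", "missing_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.missing_rate >= 1.0:
            raise ConfigurationError("missing_rate must be < 1")
        for name in ("age_sd", "ygtss_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("age_bounds", "ygtss_bounds", "puts_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"{name} must be an increasing pair")
        if self.truth is not None:
            self.truth.validate()

    def resolve_truth(self) -> ParameterVector:
        if self.truth is not None:
            return self.truth.copy()
        if self.model == "simple":
            return calibration.simple_truth()
        return calibration.simplified_truth()

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if self.truth is not None:
            d["truth"] = {
                "coefficients": dict(self.truth.coefficients),
                "intercepts": dict(self.truth.intercepts),
                "residual_sd": dict(self.truth.residual_sd),
                "residual_corr": {
                    " ".join(k): v for k, v in self.truth.residual_corr.items()
                },
            }
        for key in ("age_bounds", "ygtss_bounds", "puts_bounds"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        truth = d.pop("truth", None)
        if truth is not None and not isinstance(truth, ParameterVector):
            truth = ParameterVector(
                coefficients=dict(truth.get("coefficients", {})),
                intercepts=dict(truth.get("intercepts", {})),
                residual_sd=dict(truth.get("residual_sd", {})),
                residual_corr={
                    tuple(k.split()): v
                    for k, v in truth.get("residual_corr", {}).items()
                },
            )
        for key in ("age_bounds", "ygtss_bounds", "puts_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(truth=truth, **d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "GeneratorConfig":
        try:
            with open(path_or_text) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(path_or_text)
        return cls.from_dict(d)


def truncnorm_underlying(
    mean: float, sd: float, bounds: tuple[float, float]
) -> tuple[float, float]:
    """Location/scale of a truncated Normal with given *observed* moments.

    The configured mean/SD describe the cohort as measured, i.e. after
    truncation to the instrument/inclusion range; this solves for the
    underlying Normal parameters whose truncation reproduces them, so the
    generated marginals match the targets exactly in expectation.
    """
    lo, hi = bounds
    if not (lo < mean < hi):
        raise ConfigurationError(f"target mean {mean} outside bounds {bounds}")

    def moments(loc, scale):
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return float(m), math.sqrt(float(v))

    def residual(x):
        m, s = moments(x[0], x[1])
        # weight the mean heavily: it must match even when the SD cannot
        return [10.0 * (m - mean), s - sd]

    span = hi - lo
    sol = optimize.least_squares(
        residual,
        x0=[mean, sd],
        bounds=([lo - 3.0 * span, sd / 3.0], [hi + 3.0 * span, 3.0 * sd]),
    )
    loc, scale = float(sol.x[0]), float(sol.x[1])
    m, s = moments(loc, scale)
    if abs(m - mean) > 0.05:
        raise ConfigurationError(
            f"no truncated Normal on {bounds} attains mean {mean} (got {m:.3f})"
        )
    # the SD may be unattainable inside a bounded range (the range caps the
    # achievable spread); the closest value is accepted silently if within
    # 10%, otherwise the configuration is rejected as inconsistent
    if abs(s - sd) > 0.1 * sd:
        raise ConfigurationError(
            f"truncated Normal on {bounds} cannot approach sd {sd} (best {s:.3f})"
        )
    return loc, scale


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean, dtype=float)
    loc, scale = truncnorm_underlying(mean, sd, bounds)
    lo, hi = bounds
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_covariates(config: GeneratorConfig) -> CohortTable:
    """Draw the exogenous design: sex, comorbidity, age, YGTSS severity."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    sex = (rng.random(n) < config.prevalence_female).astype(float)
    comorbidity = (rng.random(n) < config.prevalence_comorbidity).astype(float)
    age = _truncated_normal(rng, config.age_mean, config.age_sd, config.age_bounds, n)

    shift = config.ygtss_comorbidity_shift
    p = config.prevalence_comorbidity
    ygtss = np.empty(n)
    if shift == 0.0:
        ygtss[:] = _truncated_normal(
            rng, config.ygtss_mean, config.ygtss_sd, config.ygtss_bounds, n
        )
    else:
        # group means chosen so the overall mean stays at ygtss_mean
        group_mean = {
            1.0: config.ygtss_mean + shift * (1.0 - p),
            0.0: config.ygtss_mean - shift * p,
        }
        for code, gm in group_mean.items():
            idx = np.where(comorbidity == code)[0]
            ygtss[idx] = _truncated_normal(
                rng, gm, config.ygtss_sd, config.ygtss_bounds, len(idx)
            )

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "comorbidity": comorbidity,
            "ygtss_total": ygtss,
        }
    )
    for col in MEASUREMENT_CELLS:
        df[col] = np.nan
    return CohortTable(
        df[COLUMNS], provenance=f"synthetic covariates (seed={config.seed})"
    )


def covariate_means(config: GeneratorConfig) -> dict[str, float]:
    """Population means of the exogenous variables implied by the config.

    Because the truncated Normals are moment-matched to the configured
    means, these are exact; intercept solving uses them.
    """
    return {
        "age": config.age_mean,
        "sex": config.prevalence_female,
        "comorbidity": config.prevalence_comorbidity,
        "ygtss_total": config.ygtss_mean,
    }


def solve_intercepts(
    spec: PathModelSpec,
    truth: ParameterVector,
    means: Mapping[str, float],
    targets: Mapping[str, float] = OUTCOME_MEAN_TARGETS,
) -> ParameterVector:
    """Solve equation intercepts so linear predictors hit target means.

    Expected term values are evaluated at the covariate means (products as
    products of means, i.e. assuming independence between the factors);
    earlier endogenous variables enter at their own target means.
    """
    out = truth.copy()
    env = dict(means)
    for eq in spec.equations:
        target = targets[eq.outcome]
        acc = 0.0
        for lab, term in eq.terms:
            val = 1.0
            for v in term:
                if v not in env:
                    raise ModelError(f"no mean available for variable {v!r}")
                val *= env[v]
            acc += out.coefficients[lab] * val
        out.intercepts[eq.outcome] = target - acc
        env[eq.outcome] = target
    return out


def generate_outcomes(
    covariates: CohortTable,
    truth: ParameterVector,
    model: PathModelSpec | str,
    seed: int,
    config: GeneratorConfig | None = None,
) -> CohortTable:
    """Generate endogenous scores at a known truth, stage by stage.

    The urge (PUTS) equation gets a univariate Normal residual; paired
    outcomes (BRI, MI) are drawn jointly with the truth's residual
    correlation; GEC is set to BRI + MI whenever both are generated and
    GEC is not itself an outcome.  Deterministic given ``seed``.
    """
    spec = get_model_spec(model)
    truth.validate(spec)
    rng = np.random.default_rng(seed)
    df = covariates.df.copy()
    if df[spec.exogenous].isna().any().any():
        raise ModelError("covariates must be complete for exogenous fields")

    clip = config is not None and config.clip_outcomes
    clipped = 0
    for block in spec.blocks():
        S = block_sigma(spec, truth, block)
        chol = np.linalg.cholesky(S) if np.any(S) else np.zeros_like(S)
        eps = rng.standard_normal((len(df), len(block))) @ chol.T
        for j, outcome in enumerate(block):
            eq = spec.equation(outcome)
            vals = linear_predictor(df, eq, truth) + eps[:, j]
            if clip and outcome == "puts_total":
                lo, hi = config.puts_bounds
                clipped += int(((vals < lo) | (vals > hi)).sum())
                vals = np.clip(vals, lo, hi)
            if config is not None and config.round_scores:
                vals = np.round(vals)
            df[outcome] = vals

    if "gec_raw" not in spec.outcomes and {"bri_raw", "mi_raw"} <= set(spec.outcomes):
        df["gec_raw"] = df["bri_raw"] + df["mi_raw"]

    note = f"synthetic outcomes (model={spec.name}, seed={seed})"
    if clip:
        note += f"; {clipped} PUTS values clipped to instrument range"
    else:
        note += "; continuous unclipped scores"
    return CohortTable(
        df[COLUMNS],
        provenance=f"{covariates.provenance}; {note}",
        puts_bounds=(config.puts_bounds if clip else None)
        if config is not None
        else None,
    )


def apply_missingness(
    cohort: CohortTable,
    missing_rate: float,
    seed: int,
    protected: Sequence[str] = ("age", "sex", "comorbidity", "ygtss_total"),
) -> CohortTable:
    """Blank measurement cells independently with the given MCAR rate."""
    if not (0.0 <= missing_rate < 1.0):
        raise ConfigurationError("missing_rate must be in [0, 1)")
    if missing_rate == 0.0:
        return cohort.with_df(cohort.df.copy())
    rng = np.random.default_rng(seed)
    df = cohort.df.copy()
    cols = [c for c in COLUMNS[1:] if c not in protected]
    mask = rng.random((len(df), len(cols))) < missing_rate
    for j, col in enumerate(cols):
        df.loc[mask[:, j], col] = np.nan
    return cohort.with_df(
        df, provenance=f"{cohort.provenance}; MCAR missingness rate={missing_rate}"
    )


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Full pipeline: covariates -> solved intercepts -> outcomes -> MCAR.

    Byte-identical output for identical configs (stage seeds are derived
    from ``config.seed``).
    """
    config.validate()
    spec = get_model_spec(config.model)
    covariates = generate_covariates(config)
    truth = solve_intercepts(spec, config.resolve_truth(), covariate_means(config))
    full = generate_outcomes(covariates, truth, spec, config.seed + 1, config=config)
    protected = (
        ("age", "sex", "comorbidity", "ygtss_total")
        if config.protect_exogenous
        else ()
    )
    return apply_missingness(full, config.missing_rate, config.seed + 2, protected)
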