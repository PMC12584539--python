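"""Triangular Gaussian path models: declarative specs and exact likelihood.

A path model is an ordered system of linear regressions among observed
variables.  An outcome may appear as a predictor only in later equations
(triangularity), so the joint density of the endogenous variables given the
exogenous design factorizes stage by stage.  Equations may share residual
correlation in declared pairs (here: the two BRIEF indices BRI and MI given
their common predictors), giving a bivariate-Normal stage.

Three model variants are shipped:

``simple_mediation_spec``
    tic severity -> premonitory urge -> global executive composite, with
    age, sex and comorbidity as covariates in both equations; defined
    quantities ``indirect = a*b`` and ``total = c_prime + a*b``.

``simplified_moderated_spec``
    comorbidity moderates only the severity->urge ('a') path; BRI and MI
    are modelled jointly with correlated residuals; defined quantities are
    the conditional indirect effects at comorbidity 0/1 and the index of
    moderated mediation (IMM) per outcome.

``full_moderated_spec``
    moderation tested on the 'a', 'b' and direct paths (products with
    comorbidity on every stage), nesting the simplified model.

Missing endogenous values are handled by the full-information contract:
each subject contributes the Gaussian density of its *observed* endogenous
components, obtained by marginalizing the subject's joint endogenous
Normal distribution.  Missing exogenous values are not modelled; such
subjects are excluded (with a count) from the affected factors.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

# variables the models condition on (never modelled)
EXOGENOUS = ["ygtss_total", "age", "sex", "comorbidity"]

Term = tuple[str, ...]  # a variable, or a product of two variables


class ModelError(ValueError):
    """Malformed model specification or parameter/model mismatch."""


@dataclass(frozen=True)
class Equation:
    outcome: str
    terms: tuple[tuple[str, Term], ...]  # (path label, term)


@dataclass
class PathModelSpec:
    """Declarative description of a triangular Gaussian path system."""

    name: str
    equations: list[Equation]
    residual_correlation_pairs: list[tuple[str, str]] = field(default_factory=list)
    defined_parameters: dict[str, str] = field(default_factory=dict)
    #: exogenous variables whose moderation the analysis is about; the
    #: posterior predictive check enriches its saturated reference with
    #: their products so misfit from omitted moderation is detectable
    moderators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check()

    # -- structure ----------------------------------------------------------
    @property
    def outcomes(self) -> list[str]:
        return [eq.outcome for eq in self.equations]

    @property
    def path_labels(self) -> list[str]:
        return [lab for eq in self.equations for lab, _ in eq.terms]

    @property
    def exogenous(self) -> list[str]:
        outs = set(self.outcomes)
        seen: list[str] = []
        for eq in self.equations:
            for _, term in eq.terms:
                for v in term:
                    if v not in outs and v not in seen:
                        seen.append(v)
        return seen

    @property
    def variables(self) -> list[str]:
        return self.exogenous + self.outcomes

    def blocks(self) -> list[tuple[str, ...]]:
        """Equations grouped into sampling/likelihood stages.

        Outcomes joined by a residual-correlation pair form one bivariate
        block; every other equation is its own univariate block, in
        equation order.
        """
        paired = {o for pair in self.residual_correlation_pairs for o in pair}
        out: list[tuple[str, ...]] = []
        done: set[str] = set()
        for eq in self.equations:
            o = eq.outcome
            if o in done:
                continue
            if o in paired:
                pair = next(p for p in self.residual_correlation_pairs if o in p)
                out.append(tuple(pair))
                done.update(pair)
            else:
                out.append((o,))
                done.add(o)
        return out

    def equation(self, outcome: str) -> Equation:
        for eq in self.equations:
            if eq.outcome == outcome:
                return eq
        raise ModelError(f"no equation for outcome {outcome!r}")

    def _check(self) -> None:
        outs = self.outcomes
        if len(set(outs)) != len(outs):
            raise ModelError("duplicate outcome equations")
        labels = self.path_labels
        if len(set(labels)) != len(labels):
            raise ModelError("path labels must be unique")
        # triangularity: an outcome may only predict later outcomes
        for i, eq in enumerate(self.equations):
            earlier = set(outs[:i])
            for _, term in eq.terms:
                for v in term:
                    if v in outs and v not in earlier:
                        raise ModelError(
                            f"{v!r} predicts {eq.outcome!r} but is not an "
                            "earlier outcome (triangularity violated)"
                        )
        for a, b in self.residual_correlation_pairs:
            if a not in outs or b not in outs:
                raise ModelError(f"correlation pair ({a}, {b}) names a non-outcome")
            # correlated outcomes must form one stage: neither may regress
            # on the other
            vars_a = {v for _, t in self.equation(a).terms for v in t}
            vars_b = {v for _, t in self.equation(b).terms for v in t}
            if b in vars_a or a in vars_b:
                raise ModelError(
                    f"correlated outcomes ({a}, {b}) may not predict each other"
                )
        for expr in self.defined_parameters.values():
            for tok in _expr_labels(expr):
                if tok not in labels:
                    raise ModelError(
                        f"defined parameter references unknown label {tok!r}"
                    )
        exo = set(self.exogenous)
        for mvar in self.moderators:
            if mvar not in exo:
                raise ModelError(f"moderator {mvar!r} is not an exogenous variable")

    # -- text grammar -------------------------------------------------------
    def to_text(self) -> str:
        lines = [f"# model {self.name}"]
        for eq in self.equations:
            rhs = " + ".join(f"{lab}*{':'.join(term)}" for lab, term in eq.terms)
            lines.append(f"{eq.outcome} ~ {rhs}")
        for a, b in self.residual_correlation_pairs:
            lines.append(f"{a} ~~ {b}")
        for mvar in self.moderators:
            lines.append(f"moderator: {mvar}")
        for name, expr in self.defined_parameters.items():
            lines.append(f"{name} := {expr}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, name: str = "custom") -> "PathModelSpec":
        equations: list[Equation] = []
        pairs: list[tuple[str, str]] = []
        defined: dict[str, str] = {}
        moderators: list[str] = []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("moderator:"):
                moderators.append(line.split(":", 1)[1].strip())
            elif ":=" in line:
                key, expr = (s.strip() for s in line.split(":=", 1))
                defined[key] = expr
            elif "~~" in line:
                a, b = (s.strip() for s in line.split("~~", 1))
                pairs.append((a, b))
            elif "~" in line:
                lhs, rhs = (s.strip() for s in line.split("~", 1))
                terms = []
                for piece in rhs.split("+"):
                    piece = piece.strip()
                    if "*" not in piece:
                        raise ModelError(f"term {piece!r} lacks a 'label*term' form")
                    lab, term = (s.strip() for s in piece.split("*", 1))
                    terms.append((lab, tuple(term.split(":"))))
                equations.append(Equation(lhs, tuple(terms)))
            else:
                raise ModelError(f"unparseable model line: {raw!r}")
        return cls(name, equations, pairs, defined, moderators)


def _expr_labels(expr: str) -> list[str]:
    return [t for t in re.findall(r"[A-Za-z_]\w*", expr)]


def evaluate_defined(spec: PathModelSpec, coefs: Mapping[str, float]) -> dict[str, float]:
    """Evaluate every defined parameter expression at given path values."""
    env = {k: float(v) for k, v in coefs.items()}
    out = {}
    for name, expr in spec.defined_parameters.items():
        out[name] = float(eval(expr, {"__builtins__": {}}, env))  # noqa: S307 - label algebra only
    return out


# ---------------------------------------------------------------------------
# parameter vector
# ---------------------------------------------------------------------------

@dataclass
class ParameterVector:
    """One point in parameter space for a :class:`PathModelSpec`."""

    coefficients: dict[str, float]
    intercepts: dict[str, float]
    residual_sd: dict[str, float]
    residual_corr: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self, spec: PathModelSpec | None = None) -> None:
        for o, s in self.residual_sd.items():
            if not (s > 0) or not math.isfinite(s):
                raise ModelError(f"residual SD for {o!r} must be > 0 (got {s})")
        for pair, r in self.residual_corr.items():
            if not (-1.0 < r < 1.0):
                raise ModelError(f"residual correlation for {pair} outside (-1, 1)")
        if spec is not None:
            missing = set(spec.path_labels) - set(self.coefficients)
            if missing:
                raise ModelError(f"missing coefficients for labels {sorted(missing)}")
            for o in spec.outcomes:
                if o not in self.intercepts or o not in self.residual_sd:
                    raise ModelError(f"missing intercept/SD for outcome {o!r}")
            for pair in spec.residual_correlation_pairs:
                if tuple(pair) not in self.residual_corr:
                    raise ModelError(f"missing residual correlation for {pair}")

    def copy(self) -> "ParameterVector":
        return ParameterVector(
            dict(self.coefficients),
            dict(self.intercepts),
            dict(self.residual_sd),
            dict(self.residual_corr),
        )

    # flat name <-> value view used by samplers and summaries
    def flat(self) -> dict[str, float]:
        out = dict(self.coefficients)
        out.update({f"intercept_{o}": v for o, v in self.intercepts.items()})
        out.update({f"sigma_{o}": v for o, v in self.residual_sd.items()})
        out.update(
            {f"rho_{a}_{b}": v for (a, b), v in self.residual_corr.items()}
        )
        return out


# ---------------------------------------------------------------------------
# shipped model variants
# ---------------------------------------------------------------------------

def simple_mediation_spec() -> PathModelSpec:
    """Urge mediates severity -> executive composite, covariate-adjusted."""
    eqs = [
        Equation(
            "puts_total",
            (
                ("a", ("ygtss_total",)),
                ("a_age", ("age",)),
                ("a_sex", ("sex",)),
                ("a_comorbidity", ("comorbidity",)),
            ),
        ),
        Equation(
            "gec_raw",
            (
                ("b", ("puts_total",)),
                ("c_prime", ("ygtss_total",)),
                ("b_age", ("age",)),
                ("b_sex", ("sex",)),
                ("b_comorbidity", ("comorbidity",)),
            ),
        ),
    ]
    defined = {
        "indirect": "a*b",
        "direct": "c_prime",
        "total": "c_prime + a*b",
    }
    return PathModelSpec("simple_mediation", eqs, [], defined)


def simplified_moderated_spec() -> PathModelSpec:
    """Moderated mediation with the interaction on the 'a' path only.

    The mediator equation deliberately carries no comorbidity main effect
    and no sex term (the published simplified model retains only severity,
    age and the severity x comorbidity product) — unconventional for a
    model with an interaction term, but it is the specification being
    reproduced and the conditional-indirect-effect algebra
    ``IE(C=0) = a1*b`` / ``IE(C=1) = (a1+a4)*b`` relies on the raw 0/1
    comorbidity coding used here.
    """
    eqs = [
        Equation(
            "puts_total",
            (
                ("a1", ("ygtss_total",)),
                ("a2", ("age",)),
                ("a4", ("ygtss_total", "comorbidity")),
            ),
        ),
        Equation(
            "bri_raw",
            (
                ("b1", ("puts_total",)),
                ("b2", ("ygtss_total",)),
                ("b3", ("age",)),
                ("b4", ("sex",)),
                ("b5", ("comorbidity",)),
            ),
        ),
        Equation(
            "mi_raw",
            (
                ("c1", ("puts_total",)),
                ("c2", ("ygtss_total",)),
                ("c3", ("age",)),
                ("c4", ("sex",)),
                ("c5", ("comorbidity",)),
            ),
        ),
    ]
    defined = {
        "ie_bri_c0": "a1*b1",
        "ie_bri_c1": "(a1 + a4)*b1",
        "imm_bri": "a4*b1",
        "ie_mi_c0": "a1*c1",
        "ie_mi_c1": "(a1 + a4)*c1",
        "imm_mi": "a4*c1",
    }
    return PathModelSpec(
        "simplified_moderated",
        eqs,
        [("bri_raw", "mi_raw")],
        defined,
        moderators=["comorbidity"],
    )


def full_moderated_spec() -> PathModelSpec:
    """Moderation tested on the 'a', 'b' and direct paths simultaneously."""
    base = simplified_moderated_spec()
    eqs = [
        Equation(
            "puts_total",
            base.equation("puts_total").terms + (("a3", ("comorbidity",)),),
        ),
        Equation(
            "bri_raw",
            base.equation("bri_raw").terms
            + (
                ("b6", ("puts_total", "comorbidity")),
                ("b7", ("ygtss_total", "comorbidity")),
            ),
        ),
        Equation(
            "mi_raw",
            base.equation("mi_raw").terms
            + (
                ("c6", ("puts_total", "comorbidity")),
                ("c7", ("ygtss_total", "comorbidity")),
            ),
        ),
    ]
    return PathModelSpec(
        "full_moderated",
        eqs,
        [("bri_raw", "mi_raw")],
        dict(base.defined_parameters),
        moderators=["comorbidity"],
    )


MODEL_FACTORIES = {
    "simple": simple_mediation_spec,
    "simplified": simplified_moderated_spec,
    "full": full_moderated_spec,
}


def get_model_spec(name_or_spec) -> PathModelSpec:
    if isinstance(name_or_spec, PathModelSpec):
        return name_or_spec
    try:
        return MODEL_FACTORIES[name_or_spec]()
    except KeyError:
        raise ModelError(
            f"unknown model {name_or_spec!r}; choose from {sorted(MODEL_FACTORIES)}"
        ) from None


# ---------------------------------------------------------------------------
# design construction and likelihood
# ---------------------------------------------------------------------------

def term_column(df: pd.DataFrame, term: Term) -> np.ndarray:
    col = df[term[0]].to_numpy(dtype=float)
    for v in term[1:]:
        col = col * df[v].to_numpy(dtype=float)
    return col


def design_matrix(df: pd.DataFrame, eq: Equation) -> np.ndarray:
    """Intercept column followed by the equation's term columns."""
    cols = [np.ones(len(df))] + [term_column(df, term) for _, term in eq.terms]
    return np.column_stack(cols)


def _coef_vector(eq: Equation, params: ParameterVector) -> np.ndarray:
    return np.array(
        [params.intercepts[eq.outcome]]
        + [params.coefficients[lab] for lab, _ in eq.terms]
    )


def linear_predictor(df: pd.DataFrame, eq: Equation, params: ParameterVector) -> np.ndarray:
    return design_matrix(df, eq) @ _coef_vector(eq, params)


def block_sigma(spec: PathModelSpec, params: ParameterVector, block: tuple[str, ...]) -> np.ndarray:
    """Residual covariance matrix of one block."""
    sds = np.array([params.residual_sd[o] for o in block])
    S = np.diag(sds**2)
    if len(block) == 2:
        pair = tuple(block)
        rho = params.residual_corr.get(pair, params.residual_corr.get(pair[::-1], 0.0))
        S[0, 1] = S[1, 0] = rho * sds[0] * sds[1]
    return S


def subject_joint_mvn(
    spec: PathModelSpec, params: ParameterVector, exo_row: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Joint Normal of all endogenous variables for one subject.

    Solves the triangular system ``e = c(x) + L(x) e + eps``: coefficients
    on an earlier endogenous variable (possibly modified by a product with
    an exogenous variable) populate ``L``; everything exogenous goes into
    the constant ``c``.  Products of two endogenous variables are not
    representable in a linear-Gaussian system and raise.
    """
    outs = spec.outcomes
    idx = {o: i for i, o in enumerate(outs)}
    k = len(outs)
    L = np.zeros((k, k))
    c = np.zeros(k)
    for eq in spec.equations:
        i = idx[eq.outcome]
        c[i] = params.intercepts[eq.outcome]
        for lab, term in eq.terms:
            beta = params.coefficients[lab]
            endo = [v for v in term if v in idx]
            exo = [v for v in term if v not in idx]
            if len(endo) == 0:
                val = 1.0
                for v in exo:
                    val *= float(exo_row[v])
                c[i] += beta * val
            elif len(endo) == 1:
                mult = 1.0
                for v in exo:
                    mult *= float(exo_row[v])
                L[i, idx[endo[0]]] += beta * mult
            else:
                raise ModelError(
                    f"term {term} multiplies two endogenous variables"
                )
    # residual covariance over all outcomes
    S = np.zeros((k, k))
    for o in outs:
        S[idx[o], idx[o]] = params.residual_sd[o] ** 2
    for (a, b) in spec.residual_correlation_pairs:
        pair = (a, b)
        rho = params.residual_corr.get(pair, params.residual_corr.get(pair[::-1], 0.0))
        cov = rho * params.residual_sd[a] * params.residual_sd[b]
        S[idx[a], idx[b]] = S[idx[b], idx[a]] = cov
    A = np.linalg.inv(np.eye(k) - L)
    mean = A @ c
    cov = A @ S @ A.T
    return mean, cov


_LOG2PI = math.log(2.0 * math.pi)


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    d = x - mean
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return -np.inf
    sol = np.linalg.solve(cov, d)
    return float(-0.5 * (len(x) * _LOG2PI + logdet + d @ sol))


def log_likelihood(
    spec: PathModelSpec,
    params: ParameterVector,
    cohort,
    return_dropped: bool = False,
):
    """Exact log likelihood of a cohort under the path model.

    Complete-endogenous subjects are evaluated through the vectorized
    stage-wise factorization; subjects with missing endogenous values
    contribute the marginal density of their observed endogenous
    components (full-information contract).  Subjects missing an
    exogenous design value are dropped (count available via
    ``return_dropped``).
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    params.validate(spec)

    exo = spec.exogenous
    outs = spec.outcomes
    exo_ok = df[exo].notna().all(axis=1)
    n_dropped = int((~exo_ok).sum())
    data = df.loc[exo_ok, exo + outs]

    endo_complete = data[outs].notna().all(axis=1)
    complete = data.loc[endo_complete]
    partial = data.loc[~endo_complete]

    total = 0.0
    if len(complete):
        for block in spec.blocks():
            S = block_sigma(spec, params, block)
            resid = np.column_stack(
                [
                    complete[o].to_numpy(dtype=float)
                    - linear_predictor(complete, spec.equation(o), params)
                    for o in block
                ]
            )
            k = len(block)
            sign, logdet = np.linalg.slogdet(S)
            if sign <= 0:
                return (-np.inf, n_dropped) if return_dropped else -np.inf
            sol = np.linalg.solve(S, resid.T)
            quad = np.einsum("ij,ji->i", resid, sol)
            total += float(
                -0.5 * (len(complete) * (k * _LOG2PI + logdet) + quad.sum())
            )

    for _, row in partial.iterrows():
        obs = [o for o in outs if not pd.isna(row[o])]
        if not obs:
            continue
        mean, cov = subject_joint_mvn(spec, params, row)
        sel = [outs.index(o) for o in obs]
        x = row[obs].to_numpy(dtype=float)
        total += _mvn_logpdf(x, mean[sel], cov[np.ix_(sel, sel)])

    if return_dropped:
        return total, n_dropped
    return total


def conditional_endogenous(
    spec: PathModelSpec,
    params: ParameterVector,
    row: Mapping[str, float],
    observed: Mapping[str, float],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Distribution of a subject's missing endogenous values given the rest.

    Returns (names of missing outcomes, conditional mean, conditional
    covariance) by Gaussian conditioning on the observed endogenous
    components; used both by the sampler's data-augmentation step and by
    single-subject imputation diagnostics.
    """
    outs = spec.outcomes
    mean, cov = subject_joint_mvn(spec, params, row)
    miss = [o for o in outs if o not in observed]
    obs = [o for o in outs if o in observed]
    mi = [outs.index(o) for o in miss]
    oi = [outs.index(o) for o in obs]
    if not obs:
        return miss, mean[mi], cov[np.ix_(mi, mi)]
    d = np.array([observed[o] for o in obs]) - mean[oi]
    Koo = cov[np.ix_(oi, oi)]
    Kmo = cov[np.ix_(mi, oi)]
    sol = np.linalg.solve(Koo, d)
    cmean = mean[mi] + Kmo @ sol
    ccov = cov[np.ix_(mi, mi)] - Kmo @ np.linalg.solve(Koo, Kmo.T)
    return miss, cmean, ccov
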