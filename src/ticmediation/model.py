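"""Model / Results surface tying the pieces together.

Usage mirrors the fit-then-inspect style of mainstream statistical
packages::

    from ticmediation import BayesianPathModel, simulate

    cohort = simulate.generate_cohort(simulate.GeneratorConfig(seed=7))
    model = BayesianPathModel(cohort, model="simplified")
    res = model.fit(n_chains=4, n_warmup=500, n_draws=2000, seed=7)
    print(res.summary())
    res.ppp(seed=7)

``fit`` runs the blocked Gibbs sampler; the returned results object holds
the draws and exposes summaries, convergence diagnostics, mediation
algebra, standardized coefficients and the posterior predictive check.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .cohort import CohortTable
from .pathmodel import (
    ParameterVector,
    PathModelSpec,
    get_model_spec,
    log_likelihood,
)
from .sampler import (
    ConvergenceReport,
    PosteriorDraws,
    PriorSpec,
    SamplerConfig,
    check_convergence,
    sample_posterior,
)


class BayesianPathModel:
    """A triangular Gaussian path model bound to a cohort.

    Parameters
    ----------
    cohort : CohortTable or pandas.DataFrame
        Per-subject table with the canonical cohort columns.
    model : str or PathModelSpec
        ``"simple"`` (urge mediates severity -> GEC), ``"simplified"``
        (moderation on the 'a' path, BRI/MI joint outcomes; default), or
        ``"full"`` (moderation on all paths), or a custom spec.
    prior : PriorSpec, optional
        Defaults to Normal(0, 10) coefficients, Gamma(1, 0.5) residual
        SDs, uniform residual correlation.
    """

    def __init__(self, cohort, model: str | PathModelSpec = "simplified", prior=None):
        self.cohort = cohort
        self.spec = get_model_spec(model)
        self.prior = prior or PriorSpec()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model="simplified", prior=None):
        return cls(CohortTable(df), model=model, prior=prior)

    def loglike(self, params: ParameterVector) -> float:
        """Exact log likelihood (full-information over missing scores)."""
        return log_likelihood(self.spec, params, self.cohort)

    def fit(
        self,
        n_chains: int = 4,
        n_warmup: int = 2000,
        n_draws: int = 12500,
        seed: int = 0,
        thin: int = 1,
        config: SamplerConfig | None = None,
    ) -> "BayesianPathResults":
        cfg = config or SamplerConfig(
            n_chains=n_chains,
            n_warmup=n_warmup,
            n_draws=n_draws,
            seed=seed,
            thin=thin,
        )
        draws = sample_posterior(self.spec, self.cohort, self.prior, cfg)
        return BayesianPathResults(self, draws)


class BayesianPathResults:
    """Posterior draws plus everything computed from them."""

    def __init__(self, model: BayesianPathModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self.spec = draws.spec

    # -- point estimates ----------------------------------------------------
    @property
    def params(self) -> ParameterVector:
        """Posterior-mean parameter vector."""
        return self.draws.posterior_mean_vector()

    # -- tables -------------------------------------------------------------
    def summary(self, include_derived: bool = True) -> "PathSummary":
        table = analysis.summary_table(
            self.draws, self.model.cohort, self.spec, include_derived
        )
        return PathSummary(self.spec.name, table, self.draws)

    def derived_effects(self) -> dict[str, np.ndarray]:
        return analysis.derived_effects(self.draws, self.spec)

    def derived_summary(self) -> pd.DataFrame:
        tab = self.summary(include_derived=True).table
        return tab[tab["kind"] == "derived"].drop(columns="kind").reset_index(drop=True)

    def standardized(self):
        return analysis.standardize(self.draws, self.model.cohort, self.spec)

    def point_consistency(self) -> dict[str, float]:
        """Mediation algebra at the posterior means (table-checking view)."""
        return analysis.point_consistency(self.params, self.spec)

    # -- diagnostics --------------------------------------------------------
    def convergence(self, threshold: float = 1.05) -> ConvergenceReport:
        return check_convergence(self.draws, threshold)

    def max_rhat(self) -> float:
        vals = self.convergence().table["rhat"].dropna()
        return float(vals.max()) if len(vals) else float("nan")

    def ppp(self, seed: int = 0, n_subsample: int = 1000) -> float:
        return analysis.ppp(
            self.draws, self.spec, self.model.cohort, seed=seed, n_subsample=n_subsample
        )

    # -- persistence --------------------------------------------------------
    def save(self, directory) -> None:
        """Persist draws + manifest so reports can be regenerated."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.draws.to_dataframe().to_csv(directory / "draws.csv", index=False)
        manifest = {
            "model": self.spec.name,
            "model_text": self.spec.to_text(),
            "sampler": self.draws.config.to_dict(),
            "n_dropped_exogenous": self.draws.n_dropped,
            "diagnostics": self.draws.diagnostics,
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory, cohort) -> "BayesianPathResults":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        spec = PathModelSpec.from_text(manifest["model_text"], manifest["model"])
        tab = pd.read_csv(directory / "draws.csv")
        n_chains = int(tab["chain"].max()) + 1
        n_draws = int(tab["draw"].max()) + 1
        arrays = {
            k: tab[k].to_numpy().reshape(n_chains, n_draws)
            for k in tab.columns
            if k not in ("chain", "draw")
        }
        cfg = SamplerConfig(**{
            k: v for k, v in manifest["sampler"].items()
            if k in SamplerConfig.__dataclass_fields__
        })
        draws = PosteriorDraws(
            spec, arrays, cfg, manifest.get("n_dropped_exogenous", 0),
            manifest.get("diagnostics"),
        )
        model = BayesianPathModel(cohort, model=spec)
        return cls(model, draws)


class PathSummary:
    """Printable report table in the path-analysis house style."""

    def __init__(self, name: str, table: pd.DataFrame, draws: PosteriorDraws):
        self.name = name
        self.table = table
        self.draws = draws

    def __str__(self) -> str:
        fmt = self.table.copy()
        for col in ("estimate", "post_sd", "ci_2.5%", "ci_97.5%", "std_all", "rhat"):
            fmt[col] = fmt[col].map(
                lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.3f}"
            )
        lines = [
            f"Bayesian path model: {self.name}",
            f"chains={self.draws.n_chains}, kept draws/chain={self.draws.n_draws}",
        ]
        for kind, title in (("structural", "Structural parameters"), ("derived", "Defined parameters")):
            sub = fmt[fmt["kind"] == kind].drop(columns="kind")
            if len(sub):
                lines.append(title)
                lines.append(sub.to_string(index=False))
        lines.append("Sig (*): 95% equal-tailed credible interval excludes 0")
        return "\n".join(lines)

    def _repr_html_(self) -> str:
        return self.table.to_html()
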