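"""Pearson correlation matrix on complete cases with Holm-adjusted p-values.

The correlation layer of the descriptive analysis: product-moment
correlations among the continuous study variables computed on listwise-
complete cases, two-sided p-values from the t transform with n-2 degrees
of freedom, and step-down Holm correction applied to the lower-triangle
p-values as one family of m = k(k-1)/2 comparisons.  Significance stars
use adjusted p at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_VARIABLES = [
    "age",
    "ygtss_total",
    "puts_total",
    "bri_raw",
    "mi_raw",
    "gec_raw",
]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class DegenerateVariableError(ValueError):
    """A requested variable has zero variance among complete cases."""


class SampleSizeError(ValueError):
    """Too few listwise-complete cases for a correlation."""


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment, returned in the original order.

    Sort ascending, multiply the i-th smallest (0-based) by (m - i),
    enforce a running maximum so adjusted values are monotone in the raw
    ordering, cap at 1.  Ties are processed in original-index order; the
    result does not depend on how ties are broken because tied values get
    equal products up to the running maximum.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def _stars(p: float) -> str:
    for cut, mark in STAR_THRESHOLDS:
        if p < cut:
            return mark
    return ""


@dataclass
class CorrelationReport:
    """Correlation matrix with raw and Holm-adjusted p-values."""

    variables: list[str]
    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n_complete: int

    @property
    def stars(self) -> pd.DataFrame:
        s = self.p_adjusted.map(_stars)
        np.fill_diagonal(s.values, "")
        return s

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "n_complete": self.n_complete,
            "r": self.r.round(10).to_dict(),
            "p_raw": self.p_raw.to_dict(),
            "p_adjusted": self.p_adjusted.to_dict(),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def __str__(self) -> str:
        lines = [f"Pearson correlations (listwise complete N = {self.n_complete})"]
        annotated = self.r.round(2).astype(str) + self.stars
        lines.append(annotated.to_string())
        lines.append("stars: Holm-adjusted p < 0.05 (*), < 0.01 (**), < 0.001 (***)")
        return "\n".join(lines)

    def heatmap(self, ax=None):
        """Correlation heatmap with r values annotated (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        k = len(self.variables)
        im = ax.imshow(self.r.values, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(k), self.variables, rotation=45, ha="right")
        ax.set_yticks(range(k), self.variables)
        for i in range(k):
            for j in range(k):
                ax.text(
                    j,
                    i,
                    f"{self.r.iat[i, j]:.2f}{self.stars.iat[i, j]}",
                    ha="center",
                    va="center",
                    fontsize=8,
                )
        ax.figure.colorbar(im, ax=ax, label="Pearson r")
        return ax


def pearson_matrix(
    cohort,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    listwise: bool = True,
) -> CorrelationReport:
    """Correlation matrix, t-based p-values, and Holm adjustment.

    ``listwise=True`` (default) restricts to cases complete on all
    requested variables jointly; ``listwise=False`` uses pairwise-complete
    cases (each pair's p then uses its own n).
    """
    df = (cohort.df if hasattr(cohort, "df") else cohort)[list(variables)]
    k = len(variables)

    if listwise:
        data = df.dropna()
        n = len(data)
        if n < 3:
            raise SampleSizeError(
                f"only {n} listwise-complete cases; need at least 3"
            )
        sd = data.std(ddof=1)
        degenerate = sd.index[sd == 0].tolist()
        if degenerate:
            raise DegenerateVariableError(
                f"zero variance among complete cases: {degenerate}"
            )

    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if listwise:
                x = data.iloc[:, i].to_numpy()
                y = data.iloc[:, j].to_numpy()
            else:
                sub = df.iloc[:, [i, j]].dropna()
                if len(sub) < 3:
                    raise SampleSizeError(
                        f"only {len(sub)} complete cases for "
                        f"({variables[i]}, {variables[j]})"
                    )
                if sub.std(ddof=1).min() == 0:
                    raise DegenerateVariableError(
                        f"zero variance in pair ({variables[i]}, {variables[j]})"
                    )
                x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            nij = len(x)
            rij = float(np.corrcoef(x, y)[0, 1])
            rij = float(np.clip(rij, -1.0, 1.0))
            # two-sided p from the exact t transform with n-2 df
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((nij - 2) / (1.0 - rij**2))
                pij = float(2.0 * stats.t.sf(abs(t), df=nij - 2))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij

    tri = np.tril_indices(k, -1)
    adj_flat = holm_adjust(p[tri])
    p_adj = np.zeros((k, k))
    p_adj[tri] = adj_flat
    p_adj = p_adj + p_adj.T

    idx = list(variables)
    return CorrelationReport(
        variables=idx,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p_raw=pd.DataFrame(p, index=idx, columns=idx),
        p_adjusted=pd.DataFrame(p_adj, index=idx, columns=idx),
        n_complete=int(n) if listwise else int(df.dropna().shape[0]),
    )
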