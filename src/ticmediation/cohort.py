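"""Clinical cohort table: schema, validation, I/O, and descriptive summary.

The unit of analysis is one child/adolescent with a tic disorder, described
by demographic covariates (age, sex, comorbidity status) and instrument
totals: YGTSS total tic severity (motor + vocal, 0-50), PUTS premonitory-urge
total (9 items, 9-36), and the three BRIEF executive-function composites
(BRI, MI, and their sum GEC). Any measurement field may be missing; missing
cells are encoded as empty strings in delimited files.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical column order for cohort files
COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "comorbidity",
    "ygtss_total",
    "puts_total",
    "bri_raw",
    "mi_raw",
    "gec_raw",
]

#: columns holding numeric measurements (everything except the id)
MEASUREMENT_COLUMNS = COLUMNS[1:]

#: instrument floor/ceiling for the PUTS 9-item total
PUTS_BOUNDS = (9.0, 36.0)

#: default YGTSS total tic severity range (motor 0-25 + vocal 0-25);
#: sites using the 0-100 global score can raise the ceiling
YGTSS_BOUNDS = (0.0, 50.0)

GEC_ADDITIVITY_TOL = 1e-9


class CohortError(ValueError):
    """Base class for cohort schema/validation problems."""


class SchemaError(CohortError):
    """A required column is missing or unmappable."""


class ParseError(CohortError):
    """A cell could not be parsed as a number."""


class ValidationError(CohortError):
    """One or more rows violate a typed invariant."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


@dataclass
class SubjectRecord:
    """One subject; ``None`` marks a missing measurement."""

    subject_id: str
    age: float | None = None
    sex: float | None = None
    comorbidity: float | None = None
    ygtss_total: float | None = None
    puts_total: float | None = None
    bri_raw: float | None = None
    mi_raw: float | None = None
    gec_raw: float | None = None


@dataclass
class CohortTable:
    """An ordered, validated collection of subject records.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; missing
    measurements are ``NaN``.  Construction validates the typed invariants
    and raises :class:`ValidationError` listing the offending rows.
    """

    df: pd.DataFrame
    provenance: str = ""
    ygtss_bounds: tuple[float, float] = YGTSS_BOUNDS
    #: ``None`` disables the PUTS range check (continuous synthetic scores)
    puts_bounds: tuple[float, float] | None = PUTS_BOUNDS

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing_cols = [c for c in COLUMNS if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing required columns: {missing_cols}")
        df = df[COLUMNS].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        for col in MEASUREMENT_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        self.df = df
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield SubjectRecord(
                subject_id=row.subject_id,
                **{
                    c: (None if pd.isna(getattr(row, c)) else float(getattr(row, c)))
                    for c in MEASUREMENT_COLUMNS
                },
            )

    @property
    def records(self) -> list[SubjectRecord]:
        return list(self)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            raise ValidationError("cohort must contain at least one record")
        if df["subject_id"].duplicated().any():
            dups = df.index[df["subject_id"].duplicated(keep=False)].tolist()
            raise ValidationError(f"duplicate subject_id in rows {dups}", dups)

        problems: list[tuple[int, str]] = []

        def flag(mask: pd.Series, msg: str) -> None:
            for i in df.index[mask.fillna(False)]:
                problems.append((int(i), msg))

        flag(df["age"].notna() & (df["age"] <= 0), "age must be > 0")
        for col in ("sex", "comorbidity"):
            flag(df[col].notna() & ~df[col].isin([0.0, 1.0]), f"{col} must be 0 or 1")
        if self.puts_bounds is not None:
            lo, hi = self.puts_bounds
            flag(
                df["puts_total"].notna()
                & ((df["puts_total"] < lo) | (df["puts_total"] > hi)),
                f"puts_total outside [{lo:g}, {hi:g}]",
            )
        ylo, yhi = self.ygtss_bounds
        flag(
            df["ygtss_total"].notna()
            & ((df["ygtss_total"] < ylo) | (df["ygtss_total"] > yhi)),
            f"ygtss_total outside [{ylo:g}, {yhi:g}]",
        )
        all_brief = df["bri_raw"].notna() & df["mi_raw"].notna() & df["gec_raw"].notna()
        bad_gec = all_brief & (
            (df["gec_raw"] - df["bri_raw"] - df["mi_raw"]).abs() > GEC_ADDITIVITY_TOL
        )
        flag(bad_gec, "gec_raw must equal bri_raw + mi_raw")

        if problems:
            rows = sorted({r for r, _ in problems})
            detail = "; ".join(f"row {r}: {m}" for r, m in problems[:20])
            raise ValidationError(
                f"{len(problems)} invariant violation(s): {detail}", rows
            )

    def with_df(self, df: pd.DataFrame, provenance: str | None = None) -> "CohortTable":
        """New table with the same validation settings (bounds) preserved."""
        return CohortTable(
            df,
            provenance=self.provenance if provenance is None else provenance,
            ygtss_bounds=self.ygtss_bounds,
            puts_bounds=self.puts_bounds,
        )


def read_cohort(
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str = ",",
    provenance: str | None = None,
    ygtss_bounds: tuple[float, float] = YGTSS_BOUNDS,
    puts_bounds: tuple[float, float] | None = PUTS_BOUNDS,
) -> CohortTable:
    """Read a delimited cohort file into a validated :class:`CohortTable`.

    Parameters
    ----------
    path : str or path-like or file-like
    dialect : mapping, optional
        Maps canonical column names to the names used in the file, e.g.
        ``{"ygtss_total": "YGTSS"}``.  Unmapped columns use canonical names.
    sep : str
        Field delimiter (``","`` default, ``"\\t"`` for TSV).
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]

    dialect = dict(dialect or {})
    rename = {dialect.get(c, c): c for c in COLUMNS}
    missing = [dialect.get(c, c) for c in COLUMNS if dialect.get(c, c) not in raw.columns]
    if missing:
        raise SchemaError(f"required columns not found in file: {missing}")
    df = raw.rename(columns=rename)[COLUMNS].copy()

    for col in MEASUREMENT_COLUMNS:
        cells = df[col].str.strip()
        blank = cells == ""
        converted = pd.to_numeric(cells.where(~blank, np.nan), errors="coerce")
        bad = converted.isna() & ~blank
        if bad.any():
            r = int(df.index[bad][0])
            raise ParseError(
                f"non-numeric value {cells[r]!r} in column {col!r}, row {r}"
            )
        df[col] = converted.astype(float)

    src = provenance if provenance is not None else f"read from {path}"
    return CohortTable(
        df, provenance=src, ygtss_bounds=ygtss_bounds, puts_bounds=puts_bounds
    )


def write_cohort(cohort: CohortTable, path, sep: str = ",") -> None:
    """Write a cohort as delimited text; missing cells are written empty.

    ``read_cohort(write_cohort(x))`` reproduces ``x`` field for field.
    """
    cohort.validate()
    cohort.df.to_csv(path, sep=sep, index=False, na_rep="")


@dataclass
class CohortSummary:
    """Descriptive summary of a cohort (counts, means, SDs, missingness)."""

    n_total: int
    n_by_sex: dict = field(default_factory=dict)
    n_by_comorbidity: dict = field(default_factory=dict)
    variables: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_by_sex": self.n_by_sex,
            "n_by_comorbidity": self.n_by_comorbidity,
            "variables": self.variables,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def __str__(self) -> str:
        out = io.StringIO()
        out.write(f"Cohort summary (n = {self.n_total})\n")
        for name, groups in (
            ("Sex", self.n_by_sex),
            ("Comorbidity", self.n_by_comorbidity),
        ):
            out.write(f"{name}:\n")
            for level, d in groups.items():
                out.write(f"  {level:<12} {d['n']:>5}  ({d['percent']:.2f}%)\n")
        out.write(f"{'Variable':<14}{'Mean':>10}{'SD':>10}{'Missing':>9}\n")
        for var, d in self.variables.items():
            mean = "—" if d["mean"] is None else f"{d['mean']:.2f}"
            sd = "—" if d["sd"] is None else f"{d['sd']:.2f}"
            out.write(f"{var:<14}{mean:>10}{sd:>10}{d['n_missing']:>9}\n")
        return out.getvalue()


def summarize_cohort(cohort: CohortTable) -> CohortSummary:
    """Descriptive table: n (%) for sex/comorbidity, mean (SD) otherwise.

    Means and SDs use non-missing values per variable; the SD uses the
    n-1 denominator.  A variable with no observed values is reported with
    ``None`` mean/SD rather than raising.
    """
    df = cohort.df
    n = len(df)

    def group_counts(col: str, labels: Mapping[float, str]) -> dict:
        out = {}
        for code, label in labels.items():
            k = int((df[col] == code).sum())
            out[label] = {"n": k, "percent": 100.0 * k / n}
        k_miss = int(df[col].isna().sum())
        if k_miss:
            out["missing"] = {"n": k_miss, "percent": 100.0 * k_miss / n}
        return out

    variables = {}
    for col in ("age", "ygtss_total", "puts_total", "bri_raw", "mi_raw", "gec_raw"):
        x = df[col].dropna().to_numpy()
        variables[col] = {
            "mean": float(np.mean(x)) if x.size else None,
            # a single observation carries no spread information
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else None,
            "n_present": int(x.size),
            "n_missing": int(n - x.size),
        }

    return CohortSummary(
        n_total=n,
        n_by_sex=group_counts("sex", {0.0: "male", 1.0: "female"}),
        n_by_comorbidity=group_counts("comorbidity", {1.0: "yes", 0.0: "no"}),
        variables=variables,
    )
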