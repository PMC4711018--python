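"""Indicator schema, table I/O, and packaged correlation fixtures.

The pipeline operates on county-by-indicator tables: one row per county,
ten percentage-valued demographic/socioeconomic indicators, one table per
population stratum (urban or rural). Indicators are coded so that higher
values mean higher susceptibility to extreme heat.

Two 10x10 Spearman correlation matrices (one per stratum, transcribed from
the published summary tables for the 73 Tibetan study counties) ship as
package data together with a per-cell transcription manifest and the
per-variable marginals (mean, SD, min, max).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical indicator order. All tables, matrices and loading reports use it.
VARIABLES: tuple[str, ...] = (
    "age_ge60",
    "loss_labor_ability",
    "illiterate",
    "living_alone",
    "age_ge60_living_alone",
    "low_income",
    "low_income_seniors",
    "low_income_households",
    "households_one_room",
    "households_le8m2",
)

STRATA: tuple[str, ...] = ("urban", "rural")

#: Decimal precision of the published correlation tables (two decimals; one
#: cell carries a third digit). Used to derive a rounding-aware eigenvalue
#: tolerance for factor retention on transcribed matrices.
FIXTURE_PRINT_PRECISION = 0.01


class SchemaError(ValueError):
    """A table does not conform to the indicator schema."""


class ValidationError(ValueError):
    """A table conforms structurally but contains invalid values."""


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture fails its own consistency checks."""


@dataclass(frozen=True)
class IndicatorSchema:
    """Ordered set of ten percentage indicators for one population stratum."""

    stratum: str
    variables: tuple[str, ...] = VARIABLES

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise SchemaError(
                f"stratum must be one of {STRATA}, got {self.stratum!r}"
            )
        if len(self.variables) != 10 or len(set(self.variables)) != 10:
            raise SchemaError("schema requires exactly 10 uniquely named variables")


@dataclass
class IndicatorTable:
    """Counties x indicators matrix of percentages for one stratum.

    ``values`` is an (n, 10) float array in schema column order; ``area_ids``
    optionally groups counties into prefecture-level areas.
    """

    county_ids: list[str]
    values: np.ndarray
    schema: IndicatorSchema
    area_ids: list[str] | None = None
    #: Unclipped synthetic tables (recovery benchmarks only) may exceed [0, 100];
    #: every table read from disk is range-checked.
    enforce_range: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.county_ids)
        if self.values.shape != (n, len(self.schema.variables)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{n} counties x {len(self.schema.variables)} variables"
            )
        if len(set(self.county_ids)) != n:
            dupes = sorted(
                {c for c in self.county_ids if self.county_ids.count(c) > 1}
            )
            raise ValidationError(f"duplicate county ids: {dupes}")
        if self.area_ids is not None and len(self.area_ids) != n:
            raise ValidationError("area_ids length does not match county count")
        bad = ~np.isfinite(self.values)
        if self.enforce_range:
            bad |= (self.values < 0.0) | (self.values > 100.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"value {self.values[i, j]!r} out of [0, 100] for county "
                f"{self.county_ids[i]!r}, variable {self.schema.variables[j]!r}"
            )

    @property
    def n(self) -> int:
        return len(self.county_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=list(self.schema.variables), copy=True
        )
        df.insert(0, "county_id", self.county_ids)
        if self.area_ids is not None:
            df.insert(1, "area_id", self.area_ids)
        return df


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix over the indicator set.

    ``print_precision`` is set when the matrix was transcribed from a rounded
    printed table; downstream eigen-analysis may use it to bound the
    rounding-induced eigenvalue perturbation.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    method: str  # "spearman" | "pearson"
    print_precision: float | None = None

    SYMMETRY_TOL = 1e-12

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.labels)
        if self.values.shape != (p, p):
            raise ValidationError("correlation matrix shape does not match labels")
        if self.method not in ("spearman", "pearson"):
            raise ValidationError(f"unknown correlation method {self.method!r}")
        if not np.allclose(self.values, self.values.T, atol=self.SYMMETRY_TOL):
            raise FixtureIntegrityError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=self.SYMMETRY_TOL):
            raise FixtureIntegrityError("correlation matrix diagonal is not 1")
        if np.any(np.abs(self.values) > 1.0 + self.SYMMETRY_TOL):
            raise FixtureIntegrityError("correlation entries outside [-1, 1]")

    @property
    def p(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.labels), columns=list(self.labels)
        )


def _coerce_percent(raw: object, county: str, variable: str) -> float:
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"non-numeric value {raw!r} for county {county!r}, variable {variable!r}"
        ) from None
    if not np.isfinite(v) or v < 0.0 or v > 100.0:
        raise ValidationError(
            f"value {v!r} out of [0, 100] for county {county!r}, variable {variable!r}"
        )
    return v


def load_indicator_table(
    path: str | Path,
    schema: IndicatorSchema,
    *,
    delimiter: str = ",",
) -> IndicatorTable:
    """Read a delimited county-indicator file and validate it against the schema.

    The header must name all schema variables (any column order) plus
    ``county_id`` and optionally ``area_id``. Columns are reordered to schema
    order. Missing cells are an error: the upstream census extract is complete
    and missingness is never imputed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if "county_id" not in df.columns:
        raise SchemaError("missing required column 'county_id'")
    missing = [v for v in schema.variables if v not in df.columns]
    if missing:
        raise SchemaError(f"missing indicator column(s): {missing}")
    county_ids = df["county_id"].astype(str).tolist()
    if df[list(schema.variables)].isna().any().any():
        na_var = df[list(schema.variables)].isna().any().idxmax()
        raise ValidationError(f"missing value in column {na_var!r}; imputation is not supported")
    values = np.empty((len(df), len(schema.variables)))
    for j, var in enumerate(schema.variables):
        for i, raw in enumerate(df[var]):
            values[i, j] = _coerce_percent(raw, county_ids[i], var)
    area_ids = (
        df["area_id"].astype(str).tolist() if "area_id" in df.columns else None
    )
    return IndicatorTable(county_ids, values, schema, area_ids)


def write_indicator_table(
    table: IndicatorTable, path: str | Path, *, delimiter: str = ",", precision: int = 6
) -> None:
    """Write a table in the same delimited layout ``load_indicator_table`` reads."""
    table.to_frame().to_csv(
        path, sep=delimiter, index=False, float_format=f"%.{precision}f"
    )


def _fixture_path(name: str):
    return importlib.resources.files("heatvuln.data").joinpath(name)


def load_fixture_correlation(stratum: str) -> CorrelationMatrix:
    """Load the packaged 10x10 Spearman matrix transcribed for one stratum."""
    if stratum not in STRATA:
        raise SchemaError(f"stratum must be one of {STRATA}, got {stratum!r}")
    with importlib.resources.as_file(_fixture_path(f"{stratum}_spearman.csv")) as p:
        df = pd.read_csv(p, index_col=0)
    labels = tuple(df.columns)
    if labels != VARIABLES or tuple(df.index) != VARIABLES:
        raise FixtureIntegrityError("fixture variable labels do not match schema")
    return CorrelationMatrix(
        labels=labels,
        values=df.to_numpy(dtype=float),
        method="spearman",
        print_precision=FIXTURE_PRINT_PRECISION,
    )


def load_fixture_marginals(stratum: str) -> pd.DataFrame:
    """Per-variable mean/SD/min/max as published, indexed by variable."""
    if stratum not in STRATA:
        raise SchemaError(f"stratum must be one of {STRATA}, got {stratum!r}")
    with importlib.resources.as_file(_fixture_path("marginals.csv")) as p:
        df = pd.read_csv(p)
    out = df[df["stratum"] == stratum].set_index("variable")[
        ["mean", "sd", "min", "max"]
    ]
    if tuple(out.index) != VARIABLES:
        raise FixtureIntegrityError("marginals fixture does not cover the schema")
    return out


def load_transcription_manifest() -> pd.DataFrame:
    """Audit trail: every transcribed correlation cell with its printed token."""
    with importlib.resources.as_file(
        _fixture_path("transcription_manifest.csv")
    ) as p:
        return pd.read_csv(p).fillna({"note": ""})


def summarize_indicators(table: IndicatorTable) -> pd.DataFrame:
    """Mean, SD (sample, n-1), min and max per indicator."""
    v = table.values
    return pd.DataFrame(
        {
            "mean": v.mean(axis=0),
            "sd": v.std(axis=0, ddof=1),
            "min": v.min(axis=0),
            "max": v.max(axis=0),
        },
        index=list(table.schema.variables),
    )


def write_correlation(
    corr: CorrelationMatrix, path: str | Path, *, delimiter: str = ","
) -> None:
    """Write a matrix in the fixture layout (label header row and column)."""
    corr.to_frame().to_csv(path, sep=delimiter, index_label="variable")
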