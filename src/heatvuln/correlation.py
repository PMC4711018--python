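"""Correlation matrices over indicator tables.

Spearman (tie-aware, mid-rank) matrices are computed for reporting and for
comparison against the published tables; Pearson matrices of the standardized
indicators feed the regression factor-scoring step.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .io_model import CorrelationMatrix, IndicatorTable


class DegenerateVariableError(ValueError):
    """A constant column has no defined rank or product-moment correlation."""


def _check_table(table: IndicatorTable) -> None:
    if table.n < 3:
        raise ValueError(f"need at least 3 counties, got {table.n}")
    spans = table.values.max(axis=0) - table.values.min(axis=0)
    if np.any(spans == 0.0):
        j = int(np.argmax(spans == 0.0))
        raise DegenerateVariableError(
            f"variable {table.schema.variables[j]!r} is constant; "
            "its correlation is undefined"
        )


def spearman_matrix(table: IndicatorTable) -> CorrelationMatrix:
    """Spearman rank correlation matrix with mid-rank tie handling.

    Entry (i, j) is the Pearson correlation of the average-ranked columns,
    so the matrix is invariant under strictly increasing per-column
    transforms of the data.
    """
    _check_table(table)
    rho = stats.spearmanr(table.values, axis=0).statistic
    rho = np.asarray(rho, dtype=float)
    # enforce exact symmetry/diagonal against floating-point asymmetry
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(table.schema.variables, rho, method="spearman")


def pearson_matrix(table: IndicatorTable) -> CorrelationMatrix:
    """Product-moment correlation matrix of the indicator columns."""
    _check_table(table)
    r = np.corrcoef(table.values, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(table.schema.variables, r, method="pearson")
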