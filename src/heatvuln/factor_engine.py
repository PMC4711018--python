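"""Principal components, Kaiser-rule retention, varimax rotation, factor scores.

The extraction path is eigendecomposition of a correlation matrix: component
loadings are eigenvectors scaled by the square root of their eigenvalues, so
the sum of squared loadings in a column equals that component's eigenvalue and
the full spectrum sums to p (the trace of a unit-diagonal matrix). Retained
components (eigenvalue > 1) are varimax-rotated toward simple structure and
counties receive regression (Thurstone) factor scores, re-standardized to
mean 0 and sample SD 1 per factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_model import CorrelationMatrix, IndicatorTable

logger = logging.getLogger(__name__)

#: Loadings with absolute value above this mark the variables that define a factor.
SALIENCE_THRESHOLD = 0.5

#: Condition-number cap for the scoring correlation matrix.
MAX_SCORING_CONDITION = 1e8

NEGATIVE_EIGENVALUE_TOL = 1e-6


class NonPositiveSemidefiniteError(ValueError):
    """The input matrix has an eigenvalue materially below zero."""


class RetentionError(ValueError):
    """No component satisfies the retention rule."""


class DegenerateRowError(ValueError):
    """A zero-communality row cannot be Kaiser-normalized."""


class ConditioningError(ValueError):
    """The scoring correlation matrix is too ill-conditioned to invert."""


@dataclass
class PcaResult:
    """Full eigendecomposition of a correlation matrix.

    ``loadings[:, j]`` is eigenvector j scaled by sqrt(eigenvalue j); a
    column's sum of squares therefore equals its eigenvalue.
    """

    labels: tuple[str, ...]
    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # p x p
    variance_shares: np.ndarray  # eigenvalues / p, negatives clipped to 0

    @property
    def p(self) -> int:
        return len(self.labels)


@dataclass
class FactorSolution:
    """Varimax-rotated loadings for the retained components."""

    labels: tuple[str, ...]
    k: int
    rotated_loadings: np.ndarray  # p x k
    rotation: np.ndarray  # k x k orthogonal
    explained_total: float  # sum of retained eigenvalues / p
    per_factor_variance: np.ndarray  # column SS of rotated loadings / p
    salient_mask: np.ndarray  # |loading| > SALIENCE_THRESHOLD
    converged: bool
    n_iter: int
    criterion_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def communalities(self) -> np.ndarray:
        return (self.rotated_loadings**2).sum(axis=1)


@dataclass
class FactorScores:
    """Per-county standardized factor scores (mean 0, sample SD 1 per column)."""

    county_ids: list[str]
    scores: np.ndarray  # n x k
    standardized: bool = True


def _orient_columns(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    All indicators are coded so that higher values mean higher vulnerability,
    so positive orientation makes higher factor scores mean higher
    vulnerability, matching the additive index.
    """
    signs = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            signs[j] = -1.0
            logger.info("factor %d sign-flipped for positive orientation", j + 1)
    return signs


def pca_from_correlation(corr: CorrelationMatrix) -> PcaResult:
    """Eigendecompose a correlation matrix into scaled component loadings.

    Eigenvalues are returned in descending order. Tiny negative eigenvalues
    (down to -1e-6, an artifact of transcribing rounded printed correlations)
    are accepted and clipped to zero for loadings and variance shares; anything
    more negative is rejected as an invalid correlation matrix.
    """
    eigenvalues, eigenvectors = np.linalg.eigh(corr.values)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    if eigenvalues[-1] < -NEGATIVE_EIGENVALUE_TOL:
        raise NonPositiveSemidefiniteError(
            f"eigenvalue {eigenvalues[-1]:.3e} below -{NEGATIVE_EIGENVALUE_TOL}; "
            "input is not a valid correlation matrix"
        )
    if eigenvalues[-1] < 0:
        logger.warning(
            "clipping %d tiny negative eigenvalue(s) (min %.2e) to zero; "
            "expected for matrices transcribed from rounded print",
            int((eigenvalues < 0).sum()),
            eigenvalues[-1],
        )
    clipped = np.clip(eigenvalues, 0.0, None)
    signs = _orient_columns(eigenvectors)
    loadings = eigenvectors * signs * np.sqrt(clipped)
    return PcaResult(
        labels=corr.labels,
        eigenvalues=eigenvalues,
        loadings=loadings,
        variance_shares=clipped / corr.p,
    )


def retention_tolerance(corr: CorrelationMatrix) -> float:
    """Eigenvalue slack induced by print rounding of a transcribed matrix.

    Entrywise rounding to precision d perturbs each off-diagonal entry by at
    most d/2; by Weyl's inequality the eigenvalues of the symmetric
    perturbation move by at most its spectral norm, bounded by the maximum
    absolute row sum (p-1)*d/2. Zero for matrices computed from data.
    """
    if corr.print_precision is None:
        return 0.0
    return (corr.p - 1) * corr.print_precision / 2.0


def retain_factors(pca: PcaResult, *, eigenvalue_tol: float = 0.0) -> int:
    """Kaiser rule: count components with eigenvalue strictly above 1.

    ``eigenvalue_tol`` lowers the threshold to 1 - tol; pass
    ``retention_tolerance(corr)`` when the input spectrum comes from a rounded
    printed transcription, so that a component whose true eigenvalue exceeds 1
    is not dropped for rounding alone.
    """
    if eigenvalue_tol < 0:
        raise ValueError("eigenvalue_tol must be non-negative")
    k = int(np.sum(pca.eigenvalues > 1.0 - eigenvalue_tol))
    if k == 0:
        raise RetentionError("no component has eigenvalue above the Kaiser threshold")
    if eigenvalue_tol > 0:
        strict = int(np.sum(pca.eigenvalues > 1.0))
        if strict != k:
            logger.info(
                "retention used rounding tolerance %.4g: k=%d (strict rule: %d)",
                eigenvalue_tol, k, strict,
            )
    return k


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax criterion: sum over factors of the variance of squared loadings."""
    p = loadings.shape[0]
    sq = loadings**2
    return float(np.sum(sq**2).sum() / p - ((sq.sum(axis=0) / p) ** 2).sum())


def _pairwise_angle(x: np.ndarray, y: np.ndarray) -> float:
    # Kaiser's closed-form planar optimum for one column pair
    p = x.shape[0]
    u = x**2 - y**2
    v = 2.0 * x * y
    a = u.sum()
    b = v.sum()
    c = (u**2 - v**2).sum()
    d = (2.0 * u * v).sum()
    num = d - 2.0 * a * b / p
    den = c - (a**2 - b**2) / p
    return 0.25 * np.arctan2(num, den)


def varimax(
    loadings: np.ndarray,
    *,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> FactorSolution:
    """Orthogonally rotate a p x k loading matrix to maximize the varimax criterion.

    Uses Kaiser's pairwise planar rotations: each column pair is rotated by
    the closed-form angle that exactly maximizes the two-column criterion, so
    the criterion is non-decreasing at every step; sweeps stop when one full
    sweep improves the criterion by less than ``tol``. With
    ``kaiser_normalize`` rows are scaled to unit communality before
    optimization (each variable then weighs equally in the criterion) and
    rescaled after. Rotated columns are sign-oriented (largest-|loading| entry
    positive) and reordered by descending explained variance.
    """
    loadings = np.asarray(loadings, dtype=float)
    p, k = loadings.shape
    if not (p > k >= 1):
        raise ValueError(f"need p > k >= 1, got p={p}, k={k}")
    labels = tuple(f"v{i+1}" for i in range(p))

    comm = np.sqrt((loadings**2).sum(axis=1))
    if kaiser_normalize:
        if np.any(comm == 0.0):
            raise DegenerateRowError(
                "row(s) with zero communality cannot be Kaiser-normalized: "
                f"{np.where(comm == 0.0)[0].tolist()}"
            )
        work = loadings / comm[:, None]
    else:
        work = loadings.copy()

    rotation = np.eye(k)
    history = [varimax_criterion(work)]
    converged = k == 1
    n_iter = 0
    for sweep in range(max_iter if k > 1 else 0):
        n_iter = sweep + 1
        for i in range(k - 1):
            for j in range(i + 1, k):
                theta = _pairwise_angle(work[:, i], work[:, j])
                c, s = np.cos(theta), np.sin(theta)
                g = np.array([[c, -s], [s, c]])
                work[:, [i, j]] = work[:, [i, j]] @ g
                rotation[:, [i, j]] = rotation[:, [i, j]] @ g
        history.append(varimax_criterion(work))
        if history[-1] - history[-2] < tol:
            converged = True
            break
    if not converged:
        logger.warning("varimax did not converge in %d sweeps", max_iter)

    rotated = loadings @ rotation  # rescaling by comm commutes with the rotation

    # deterministic presentation: positive orientation, variance-ordered columns
    signs = _orient_columns(rotated)
    order = np.argsort(-(rotated**2).sum(axis=0))
    rotated = (rotated * signs)[:, order]
    rotation = (rotation * signs)[:, order]

    per_factor = (rotated**2).sum(axis=0) / p
    return FactorSolution(
        labels=labels,
        k=k,
        rotated_loadings=rotated,
        rotation=rotation,
        explained_total=float((loadings**2).sum() / p),
        per_factor_variance=per_factor,
        salient_mask=np.abs(rotated) > SALIENCE_THRESHOLD,
        converged=converged,
        n_iter=n_iter,
        criterion_history=np.asarray(history),
    )


def rotate_retained(
    pca: PcaResult,
    k: int,
    *,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> FactorSolution:
    """Varimax-rotate the first k components of a PCA result."""
    solution = varimax(
        pca.loadings[:, :k],
        kaiser_normalize=kaiser_normalize,
        tol=tol,
        max_iter=max_iter,
    )
    solution.labels = pca.labels
    return solution


def factor_scores(
    table: IndicatorTable,
    solution: FactorSolution,
    scoring_corr: CorrelationMatrix,
) -> FactorScores:
    """Regression (Thurstone) factor scores, re-standardized per column.

    The weight matrix is W = R^-1 L for the scoring (Pearson) correlation R of
    the same table and the rotated loadings L; raw scores are ZW for the
    column-standardized data Z. Each score column is then re-standardized to
    mean 0 and sample SD exactly 1, the scale on which SD-based categories are
    defined.
    """
    if scoring_corr.labels != table.schema.variables:
        raise ValueError("scoring correlation labels do not match the table schema")
    if solution.rotated_loadings.shape[0] != len(table.schema.variables):
        raise ValueError("factor solution does not match the table's variable set")
    cond = np.linalg.cond(scoring_corr.values)
    if not np.isfinite(cond) or cond > MAX_SCORING_CONDITION:
        raise ConditioningError(
            f"scoring correlation condition number {cond:.3g} exceeds "
            f"{MAX_SCORING_CONDITION:.0e}; inspect near-collinear variables"
        )
    weights = np.linalg.solve(scoring_corr.values, solution.rotated_loadings)
    z = table.values - table.values.mean(axis=0)
    z /= table.values.std(axis=0, ddof=1)
    raw = z @ weights
    raw -= raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        raise ConditioningError("degenerate factor score column with zero variance")
    return FactorScores(list(table.county_ids), raw / sd, standardized=True)


def loading_report(solution: FactorSolution):
    """Loading table in presentation layout: variables x factors, salience-flagged."""
    import pandas as pd

    cols = [f"factor_{j+1}" for j in range(solution.k)]
    df = pd.DataFrame(
        np.round(solution.rotated_loadings, 3), index=list(solution.labels), columns=cols
    )
    for j, c in enumerate(cols):
        df[c + "_salient"] = solution.salient_mask[:, j]
    return df


def eigenvalue_table(pca: PcaResult):
    """Eigenvalues with individual and cumulative variance shares."""
    import pandas as pd

    return pd.DataFrame(
        {
            "eigenvalue": pca.eigenvalues,
            "variance_share": pca.variance_shares,
            "cumulative_share": np.cumsum(pca.variance_shares),
        },
        index=[f"component_{i+1}" for i in range(pca.p)],
    )
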