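"""Analytic Hierarchy Process engine.

Judgment matrices are positive reciprocal pairwise-comparison matrices
(Saaty 1-9 scale when expert-entered). Priority weights are the normalized
principal eigenvector, computed here by power iteration; the consistency
diagnostics are

.. math::

    CI = \\frac{\\lambda_{max} - n}{n - 1}, \\qquad CR = \\frac{CI}{RI(n)},

with the random index ``RI`` taken from a configurable table and ``CR < 0.1``
the conventional acceptance threshold. Group judgments are aggregated by the
element-wise geometric mean, the standard reciprocity-preserving choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ConvergenceError, MatrixError

__all__ = [
    "JudgmentMatrix",
    "AHPResult",
    "MatrixValidation",
    "RI_TABLES",
    "SAATY_VALUES",
    "validate_matrix",
    "principal_weights",
    "geometric_mean_weights",
    "consistency",
    "evaluate_matrix",
    "matrix_from_weights",
    "matrix_from_mean_ratings",
    "aggregate_matrices",
]

_RECIPROCITY_RTOL = 1e-9

#: Random consistency index tables by matrix order (1-indexed).
#: ``RI_52`` (RI(3) = 0.52) is the table used by common AHP software in this
#: application area and is the default; ``RI_SAATY`` is Saaty's classical
#: table (RI(3) = 0.58).
RI_TABLES: Mapping[str, Mapping[int, float]] = {
    "RI_52": {1: 0.0, 2: 0.0, 3: 0.52, 4: 0.89, 5: 1.12, 6: 1.26, 7: 1.36, 8: 1.41, 9: 1.46},
    "RI_SAATY": {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45},
}

#: Admissible Saaty-scale entries (integers 1..9 and their reciprocals).
SAATY_VALUES: tuple[float, ...] = tuple(
    sorted({float(k) for k in range(1, 10)} | {1.0 / k for k in range(1, 10)})
)


@dataclass(frozen=True)
class JudgmentMatrix:
    """A labelled pairwise-comparison matrix."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise MatrixError(f"judgment matrix must be square, got shape {values.shape}")
        if len(self.labels) != values.shape[0]:
            raise MatrixError(
                f"{len(self.labels)} labels for a {values.shape[0]}x{values.shape[0]} matrix"
            )
        if len(set(self.labels)) != len(self.labels):
            raise MatrixError("labels must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def require_valid(self) -> None:
        report = validate_matrix(self)
        if not report.valid:
            raise MatrixError("; ".join(report.violations))


@dataclass(frozen=True)
class MatrixValidation:
    """Structural validation report for a judgment matrix."""

    valid: bool
    violations: tuple[str, ...]


@dataclass(frozen=True)
class AHPResult:
    """Weights and consistency diagnostics of one judgment matrix."""

    labels: tuple[str, ...]
    weights: np.ndarray
    lambda_max: float
    ci: float
    cr: float
    ri_used: float
    converged: bool
    iterations: int

    def weight(self, label: str) -> float:
        return float(self.weights[self.labels.index(label)])


def validate_matrix(matrix: JudgmentMatrix) -> MatrixValidation:
    """Report violations of positivity, unit diagonal and reciprocity."""
    a = matrix.values
    violations: list[str] = []
    if not np.all(np.isfinite(a)):
        violations.append("non-finite entries present")
    nonpos = np.argwhere(~(a > 0))
    for i, j in nonpos[:5]:
        violations.append(f"nonpositive entry at ({i + 1},{j + 1}): {a[i, j]!r}")
    if nonpos.size == 0:
        diag = np.diag(a)
        if not np.allclose(diag, 1.0, rtol=_RECIPROCITY_RTOL, atol=0):
            violations.append(f"diagonal not all 1: {diag.tolist()}")
        for i in range(matrix.n):
            for j in range(i + 1, matrix.n):
                if not np.isclose(a[j, i], 1.0 / a[i, j], rtol=_RECIPROCITY_RTOL, atol=0):
                    violations.append(
                        f"reciprocity violation at ({j + 1},{i + 1}): "
                        f"{a[j, i]!r} != 1/{a[i, j]!r}"
                    )
    return MatrixValidation(valid=not violations, violations=tuple(violations))


def principal_weights(
    matrix: JudgmentMatrix,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    ri_table: str | Mapping[int, float] = "RI_52",
) -> AHPResult:
    """Principal-eigenvector weights by power iteration, plus diagnostics.

    Iterates ``w <- A w / ||A w||_1`` from the uniform vector until the
    max-norm change drops below ``tol``; ``lambda_max`` is the mean of the
    component-wise Rayleigh ratios ``(A w)_i / w_i`` at convergence. By
    Perron-Frobenius the limit is strictly positive for any valid matrix.
    """
    matrix.require_valid()
    a = matrix.values
    n = matrix.n
    w = np.full(n, 1.0 / n)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        v = a @ w
        w_new = v / v.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            converged = True
            break
        w = w_new
    if not converged:
        raise ConvergenceError(
            f"power iteration did not converge in {max_iter} iterations", last_iterate=w
        )
    lambda_max = float(np.mean((a @ w) / w))
    ci, cr, ri = _diagnostics(lambda_max, n, ri_table)
    return AHPResult(
        labels=matrix.labels,
        weights=w,
        lambda_max=lambda_max,
        ci=ci,
        cr=cr,
        ri_used=ri,
        converged=converged,
        iterations=iterations,
    )


def evaluate_matrix(
    matrix: JudgmentMatrix,
    ri_table: str | Mapping[int, float] = "RI_52",
    method: str = "eigenvector",
) -> AHPResult:
    """Weights plus full consistency diagnostics for one matrix.

    ``method`` is ``"eigenvector"`` (power iteration, the default) or
    ``"geometric_mean"`` (row geometric means; lambda_max is then evaluated
    at those weights).
    """
    if method == "eigenvector":
        return principal_weights(matrix, ri_table=ri_table)
    if method != "geometric_mean":
        raise ValueError(f"unknown method {method!r}")
    w = geometric_mean_weights(matrix)
    lambda_max = float(np.mean((matrix.values @ w) / w))
    ci, cr, ri = _diagnostics(lambda_max, matrix.n, ri_table)
    return AHPResult(
        labels=matrix.labels,
        weights=w,
        lambda_max=lambda_max,
        ci=ci,
        cr=cr,
        ri_used=ri,
        converged=True,
        iterations=0,
    )


def geometric_mean_weights(matrix: JudgmentMatrix) -> np.ndarray:
    """Row geometric-mean weights (exact on consistent matrices).

    Provided as the cross-check alternative to the eigenvector method; the
    two agree exactly whenever the matrix is consistent.
    """
    matrix.require_valid()
    g = np.exp(np.mean(np.log(matrix.values), axis=1))
    return g / g.sum()


def _resolve_ri(ri_table: str | Mapping[int, float]) -> Mapping[int, float]:
    if isinstance(ri_table, str):
        try:
            return RI_TABLES[ri_table]
        except KeyError as exc:
            raise ConfigurationError(
                f"unknown RI table {ri_table!r}; known: {sorted(RI_TABLES)}"
            ) from exc
    return ri_table


def consistency(
    lambda_max: float, n: int, ri_table: str | Mapping[int, float] = "RI_52"
) -> tuple[float, float]:
    """Consistency index and ratio ``(CI, CR)`` for a matrix of order ``n``.

    For ``n <= 2`` reciprocal matrices are always consistent and both are 0
    by convention.
    """
    if n < 1:
        raise ValueError(f"matrix order must be >= 1, got {n}")
    if lambda_max < n - 1e-6:
        raise ValueError(f"lambda_max ({lambda_max}) below matrix order {n}")
    ci, cr, _ = _diagnostics(lambda_max, n, ri_table)
    return ci, cr


def _diagnostics(
    lambda_max: float, n: int, ri_table: str | Mapping[int, float]
) -> tuple[float, float, float]:
    if n <= 2:
        return 0.0, 0.0, 0.0
    table = _resolve_ri(ri_table)
    if n not in table:
        raise ConfigurationError(f"RI table has no entry for order n={n}")
    ri = float(table[n])
    ci = max((lambda_max - n) / (n - 1), 0.0)
    return ci, ci / ri, ri


def matrix_from_weights(
    weights: Sequence[float],
    perturbation_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    labels: Sequence[str] | None = None,
) -> JudgmentMatrix:
    """Ratio matrix ``a_ij = (w_i / w_j) exp(eps_ij)`` with known truth.

    ``perturbation_sd = 0`` yields the exactly consistent ratio matrix whose
    principal weights are the (normalized) inputs; positive values inject
    log-normal antisymmetric noise (``eps_ji = -eps_ij``) for controlled
    inconsistency.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if perturbation_sd < 0:
        raise ValueError("perturbation_sd must be nonnegative")
    n = w.size
    a = np.outer(w, 1.0 / w)
    if perturbation_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        eps = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        eps[iu] = rng.normal(0.0, perturbation_sd, size=len(iu[0]))
        eps = eps - eps.T
        a = a * np.exp(eps)
    labels = tuple(labels) if labels is not None else tuple(f"c{i + 1}" for i in range(n))
    return JudgmentMatrix(labels=labels, values=a)


def matrix_from_mean_ratings(
    means: Sequence[float],
    labels: Sequence[str] | None = None,
    snap_to_saaty: bool = False,
) -> JudgmentMatrix:
    """Consistent ratio matrix built from a mean-importance vector.

    A pragmatic constructor for panels that report only average Likert
    ratings per criterion: entries are ratios of normalized means,
    optionally snapped to the nearest admissible Saaty value (which can
    introduce mild inconsistency).
    """
    m = np.asarray(means, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mean ratings must be strictly positive")
    a = np.outer(m, 1.0 / m)
    if snap_to_saaty:
        grid = np.asarray(SAATY_VALUES)
        snapped = grid[np.argmin(np.abs(np.log(a[..., None]) - np.log(grid)), axis=-1)]
        iu = np.triu_indices(m.size, k=1)
        a[iu] = snapped[iu]
        a[(iu[1], iu[0])] = 1.0 / snapped[iu]
        np.fill_diagonal(a, 1.0)
    labels = tuple(labels) if labels is not None else tuple(f"c{i + 1}" for i in range(m.size))
    return JudgmentMatrix(labels=labels, values=a)


def aggregate_matrices(matrices: Iterable[JudgmentMatrix]) -> JudgmentMatrix:
    """Element-wise geometric mean of expert matrices (reciprocal-preserving)."""
    mats = list(matrices)
    if not mats:
        raise ValueError("no matrices to aggregate")
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise MatrixError(f"label mismatch: {m.labels} != {labels}")
    for m in mats:
        m.require_valid()
    stack = np.stack([m.values for m in mats])
    agg = np.exp(np.mean(np.log(stack), axis=0))
    return JudgmentMatrix(labels=labels, values=agg)
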