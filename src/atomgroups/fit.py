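"""Re-derivation of group contributions from experimental data.

The additive model is linear in its parameters, so fitting is ordinary
least squares on the sparse count matrix.  The normal equations
``X'X a = X'y`` are solved with Gauss-Seidel iteration (zero start,
coordinate sweeps until the largest relative coordinate change falls
below tolerance); on well-conditioned problems the fixed point coincides
with a direct dense solve to well below 1e-8.

Residual statistics follow the conventions used throughout the package:
R^2 is the squared Pearson correlation of experimental versus fitted
values, the *average deviation* is the mean absolute residual and the
*standard deviation* the root-mean-square residual.

Outlier handling wraps the whole machinery: compounds whose residual
exceeds three times the cross-validated standard error are excluded and
the fit repeated until no further exclusions occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solve_triangular

from .groups import SPECIAL_KEYS, GroupCountVector, GroupSignature
from .tables import (
    CONST,
    MIN_MOLECULES_VALID,
    EntryKey,
    ParameterTable,
    TableEntry,
    molecules_per_group,
)


@dataclass(frozen=True)
class TrainingCompound:
    id: str
    counts: GroupCountVector
    value: float
    weight: float = 1.0


@dataclass
class TrainingSet:
    compounds: list[TrainingCompound]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dupes}")
        if not all(np.isfinite(c.value) for c in self.compounds):
            raise ValueError("experimental values must be finite")

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def subset(self, keep: Iterable[str]) -> "TrainingSet":
        keep = set(keep)
        return TrainingSet([c for c in self.compounds if c.id in keep])

    def drop(self, remove: Iterable[str]) -> "TrainingSet":
        remove = set(remove)
        return TrainingSet([c for c in self.compounds if c.id not in remove])

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    @property
    def values(self) -> np.ndarray:
        return np.array([c.value for c in self.compounds], dtype=float)


@dataclass
class DesignMatrix:
    """Sparse count matrix with its column keys (CONST column last)."""

    X: sp.csr_matrix
    y: np.ndarray
    columns: list[EntryKey]

    @property
    def n_parameters(self) -> int:
        return len(self.columns)


def _compound_keys(c: TrainingCompound, uses_special: bool) -> list[EntryKey]:
    keys: list[EntryKey] = list(c.counts.counts)
    if uses_special:
        keys += [k for k, n in c.counts.special_counts.items() if n]
    return keys


def build_design(
    training: TrainingSet, *, uses_constant: bool, uses_special: bool
) -> DesignMatrix:
    """Assemble the sparse design matrix of group counts.

    Columns are the union of the signatures occurring in the training set
    (sorted for determinism), followed by any active special groups and —
    iff ``uses_constant`` — an all-ones constant column.  Groups supported
    by fewer than three molecules are still fitted; they are merely
    flagged invalid for prediction afterwards.
    """
    if not len(training):
        raise ValueError("empty training set")
    sigs = sorted({s for c in training for s in c.counts.counts})
    specials = [
        k for k in SPECIAL_KEYS
        if uses_special and any(c.counts.special_counts.get(k, 0) for c in training)
    ]
    columns: list[EntryKey] = list(sigs) + specials
    col_of = {k: j for j, k in enumerate(columns)}
    rows, cols, vals = [], [], []
    for i, c in enumerate(training):
        for sig, n in c.counts.counts.items():
            rows.append(i)
            cols.append(col_of[sig])
            vals.append(float(n))
        if uses_special:
            for k in specials:
                n = c.counts.special_counts.get(k, 0)
                if n:
                    rows.append(i)
                    cols.append(col_of[k])
                    vals.append(float(n))
    n_cols = len(columns) + (1 if uses_constant else 0)
    if uses_constant:
        for i in range(len(training)):
            rows.append(i)
            cols.append(len(columns))
            vals.append(1.0)
        columns = columns + [CONST]
    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(training), n_cols), dtype=float
    )
    return DesignMatrix(X=X, y=training.values, columns=columns)


class GaussSeidelError(RuntimeError):
    def __init__(self, message: str, last_iterate: np.ndarray, residual_norm: float):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.residual_norm = residual_norm


def gauss_seidel_solve(
    X: np.ndarray | sp.spmatrix,
    y: Sequence[float],
    *,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Least-squares solution of ``X a ~ y`` via Gauss-Seidel iteration.

    Iterates on the normal equations ``X'X a = X'y`` from a zero start.
    One sweep updates every coordinate in order, which is equivalent to
    the triangular solve ``(D + L) a_new = b - U a``.  Convergence is
    declared when the largest coordinate change, relative to the largest
    coordinate magnitude, drops below ``tol``.

    Raises
    ------
    GaussSeidelError
        If the iteration has not converged after ``max_iter`` sweeps; the
        exception carries the last iterate and its residual norm.
    ValueError
        If a column of X is identically zero (zero normal-matrix
        diagonal), i.e., a parameter without any supporting data.
    """
    X = sp.csr_matrix(X, dtype=float) if not sp.issparse(X) else X.tocsr().astype(float)
    y = np.asarray(y, dtype=float)
    A = np.asarray((X.T @ X).todense(), dtype=float)
    b = np.asarray(X.T @ y).ravel()
    diag = np.diag(A)
    if np.any(diag == 0.0):
        empty = np.nonzero(diag == 0.0)[0]
        raise ValueError(f"zero diagonal in normal equations (columns {empty.tolist()})")
    lower = np.tril(A)
    upper = A - lower
    x = np.zeros_like(b)
    for _ in range(max_iter):
        x_new = solve_triangular(lower, b - upper @ x, lower=True)
        delta = np.max(np.abs(x_new - x))
        scale = max(np.max(np.abs(x_new)), 1e-300)
        x = x_new
        if delta / scale < tol:
            return x
    resid = float(np.linalg.norm(X @ x - y))
    raise GaussSeidelError(
        f"Gauss-Seidel did not converge in {max_iter} iterations", x, resid
    )


@dataclass(frozen=True)
class FitStatistics:
    r2: float
    avg_dev: float
    std_dev: float


def fit_statistics(y: Sequence[float], predictions: Sequence[float]) -> FitStatistics:
    """R^2 (squared Pearson correlation), mean-|residual| and RMS residual.

    Degenerate conventions: zero variance in ``y`` is an error (R^2 is
    undefined); zero variance in the predictions yields R^2 = 0.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and predictions must have equal length")
    if y.size < 2:
        raise ValueError("need at least two points")
    if np.var(y) == 0.0:
        raise ValueError("zero variance in experimental values: R^2 undefined")
    if np.var(p) == 0.0:
        r2 = 0.0
    else:
        r = np.corrcoef(y, p)[0, 1]
        r2 = float(r * r)
    resid = y - p
    return FitStatistics(
        r2=r2,
        avg_dev=float(np.mean(np.abs(resid))),
        std_dev=float(np.sqrt(np.mean(resid ** 2))),
    )


@dataclass
class FitResult:
    table: ParameterTable
    coefficients: dict[EntryKey, float]
    n_used: int
    statistics: FitStatistics
    residuals: dict[str, float]
    outliers: list[tuple[str, float, float]] = field(default_factory=list)
    converged: bool = True
    rounds: int = 1

    @property
    def r2(self) -> float:
        return self.statistics.r2


def _fitted_table(
    descriptor: str,
    columns: list[EntryKey],
    coef: np.ndarray,
    training: TrainingSet,
    *,
    uses_constant: bool,
    uses_special: bool,
) -> ParameterTable:
    support = molecules_per_group(c.counts for c in training)
    occurrences: dict[EntryKey, int] = {}
    for c in training:
        for sig, n in c.counts.counts.items():
            occurrences[sig] = occurrences.get(sig, 0) + n
        for k, n in c.counts.special_counts.items():
            if n:
                occurrences[k] = occurrences.get(k, 0) + n
    entries: list[TableEntry] = []
    number = 1
    coef_map = dict(zip(columns, coef))
    if uses_constant:
        entries.append(
            TableEntry(number, CONST, float(coef_map[CONST]),
                       len(training), len(training), True)
        )
        number += 1
    for key in columns:
        if key == CONST:
            continue
        n_mol = support.get(key, 0)
        entries.append(
            TableEntry(number, key, float(coef_map[key]),
                       occurrences.get(key, 0), n_mol,
                       n_mol >= MIN_MOLECULES_VALID)
        )
        number += 1
    return ParameterTable(
        descriptor=descriptor,
        entries=entries,
        constant=float(coef_map.get(CONST, 0.0)),
        uses_constant=uses_constant,
        uses_special_groups=uses_special,
    )


def fit(
    training: TrainingSet,
    *,
    descriptor: str = "fitted",
    uses_constant: bool = False,
    uses_special: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> FitResult:
    """Single-pass least-squares fit of the group contributions."""
    design = build_design(
        training, uses_constant=uses_constant, uses_special=uses_special
    )
    coef = gauss_seidel_solve(design.X, design.y, tol=tol, max_iter=max_iter)
    fitted = np.asarray(design.X @ coef).ravel()
    stats = fit_statistics(design.y, fitted)
    residuals = dict(zip(training.ids, (design.y - fitted).tolist()))
    table = _fitted_table(
        descriptor, design.columns, coef, training,
        uses_constant=uses_constant, uses_special=uses_special,
    )
    return FitResult(
        table=table,
        coefficients=dict(zip(design.columns, coef.tolist())),
        n_used=len(training),
        statistics=stats,
        residuals=residuals,
    )


def fit_with_outlier_removal(
    training: TrainingSet,
    *,
    descriptor: str = "fitted",
    uses_constant: bool = False,
    uses_special: bool = False,
    k: int = 10,
    seed: int | None = None,
    threshold: float = 3.0,
    max_rounds: int = 10,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> FitResult:
    """Fit with the iterated three-sigma outlier exclusion rule.

    Each round runs a K-fold cross-validation on the current compound set
    to obtain the cross-validated standard error sigma_cv, then excludes
    every compound whose training residual exceeds ``threshold * sigma_cv``
    and refits.  The loop stops when a round excludes nothing, or flags
    the result as not converged once ``max_rounds`` is reached.
    """
    from .crossval import cross_validate  # deferred: crossval builds on fit

    current = training
    outliers: list[tuple[str, float, float]] = []
    result: FitResult | None = None
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        if not len(current):
            raise ValueError("outlier exclusion emptied the training set")
        result = fit(
            current, descriptor=descriptor, uses_constant=uses_constant,
            uses_special=uses_special, tol=tol, max_iter=max_iter,
        )
        cv = cross_validate(
            current, k=min(k, len(current)), seed=seed,
            uses_constant=uses_constant, uses_special=uses_special,
            tol=tol, max_iter=max_iter,
        )
        sigma_cv = cv.std_dev
        if sigma_cv is None:
            raise ValueError("cross-validation produced no predictable compounds")
        excluded = [
            (cid, resid, sigma_cv)
            for cid, resid in result.residuals.items()
            if abs(resid) > threshold * sigma_cv
        ]
        if not excluded:
            converged = True
            break
        outliers.extend(excluded)
        current = current.drop(cid for cid, _, _ in excluded)
    assert result is not None
    result.outliers = outliers
    result.converged = converged
    result.rounds = rounds
    return result
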