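"""K-fold cross-validation with per-fold validity recomputation.

Each compound is held out exactly once.  For every fold the model is
refitted on the complement and — crucially — group validity is
recomputed *on that complement*: a group supported by fewer than three
molecules once part of its carriers moved into the test fold renders the
held-out compounds that contain it unpredictable.  This gating is what
makes the number of cross-validation predictions smaller than the number
of training predictions on real data.

Q^2 is the squared Pearson correlation between experimental values and
out-of-fold predictions over the predictable compounds; the CV average
and standard deviations are the mean-absolute and RMS out-of-fold
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fit import TrainingSet, build_design, fit_statistics, gauss_seidel_solve
from .groups import GroupCountVector
from .tables import CONST, MIN_MOLECULES_VALID, EntryKey, molecules_per_group

#: Default fold-shuffling seed (fold construction is a free choice; fixing
#: one makes every reported CV number reproducible).
DEFAULT_SEED = 20171221


def kfold_split(ids: list[str], k: int = 10, seed: int | None = None) -> dict[str, int]:
    """Assign ids to ``k`` near-equal random folds (deterministic per seed)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of compounds ({len(ids)})")
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    order = rng.permutation(len(ids))
    assignment: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for pos in chunk:
            assignment[ids[pos]] = fold
    return assignment


@dataclass
class CVResult:
    k: int
    seed: int
    assignment: dict[str, int]
    predictions: dict[str, float | None]
    reasons: dict[str, str] = field(default_factory=dict)
    n_predictable: int = 0
    q2: float | None = None
    avg_dev: float | None = None
    std_dev: float | None = None


class FoldFitError(RuntimeError):
    def __init__(self, fold: int, message: str):
        super().__init__(f"fold {fold}: {message}")
        self.fold = fold


def _compound_keys(c, uses_special: bool) -> list[EntryKey]:
    keys: list[EntryKey] = list(c.counts.counts)
    if uses_special:
        keys += [k for k, n in c.counts.special_counts.items() if n]
    return keys


def cross_validate(
    training: TrainingSet,
    k: int = 10,
    seed: int | None = None,
    *,
    uses_constant: bool = False,
    uses_special: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> CVResult:
    """K-fold cross-validation of the group-contribution fit."""
    used_seed = DEFAULT_SEED if seed is None else seed
    assignment = kfold_split(training.ids, k=k, seed=used_seed)
    predictions: dict[str, float | None] = {}
    reasons: dict[str, str] = {}

    for fold in range(k):
        test = [c for c in training if assignment[c.id] == fold]
        train = TrainingSet([c for c in training if assignment[c.id] != fold])
        if len(train) < 2:
            raise FoldFitError(fold, "training complement too small to fit")
        try:
            design = build_design(
                train, uses_constant=uses_constant, uses_special=uses_special
            )
            coef = gauss_seidel_solve(design.X, design.y, tol=tol, max_iter=max_iter)
        except Exception as exc:
            raise FoldFitError(fold, f"complement could not be fitted: {exc}") from exc
        coef_map = dict(zip(design.columns, coef.tolist()))
        support = molecules_per_group(c.counts for c in train)

        for c in test:
            keys = _compound_keys(c, uses_special)
            missing = [key for key in keys if key not in coef_map]
            if missing:
                predictions[c.id] = None
                reasons[c.id] = f"missing in training complement: {missing}"
                continue
            invalid = [
                key for key in keys
                if support.get(key, 0) < MIN_MOLECULES_VALID
            ]
            if invalid:
                predictions[c.id] = None
                reasons[c.id] = f"invalid in training complement: {invalid}"
                continue
            value = sum(
                n * coef_map[sig] for sig, n in c.counts.counts.items()
            )
            if uses_special:
                value += sum(
                    n * coef_map[key]
                    for key, n in c.counts.special_counts.items()
                    if n
                )
            if uses_constant:
                value += coef_map[CONST]
            predictions[c.id] = float(value)

    pairs = [
        (c.value, predictions[c.id])
        for c in training
        if predictions[c.id] is not None
    ]
    result = CVResult(
        k=k, seed=used_seed, assignment=assignment,
        predictions=predictions, reasons=reasons, n_predictable=len(pairs),
    )
    if len(pairs) >= 2:
        y = np.array([p[0] for p in pairs])
        p = np.array([p[1] for p in pairs])
        stats = fit_statistics(y, p)
        result.q2 = stats.r2
        result.avg_dev = stats.avg_dev
        result.std_dev = stats.std_dev
    return result
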