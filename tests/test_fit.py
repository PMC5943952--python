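"""Least-squares machinery: design, Gauss-Seidel solver, statistics, outliers."""

import numpy as np
import pytest

from atomgroups.fit import (
    GaussSeidelError,
    TrainingCompound,
    TrainingSet,
    build_design,
    fit,
    fit_statistics,
    fit_with_outlier_removal,
    gauss_seidel_solve,
)
from atomgroups.groups import perceive
from atomgroups.molgraph import read_smiles
from atomgroups.synthetic import SyntheticSpec, training_set
from atomgroups.tables import CONST


def compound(cid, smiles, value):
    return TrainingCompound(cid, perceive(read_smiles(smiles)), value)


class TestBuildDesign:
    def test_shape_without_constant(self):
        ts = TrainingSet([
            compound("a", "CCO", 0.1),
            compound("b", "CCCO", 0.2),
            compound("c", "CO", 0.3),
        ])
        d = build_design(ts, uses_constant=False, uses_special=False)
        assert d.X.shape == (3, len(d.columns))
        assert CONST not in d.columns

    def test_ethanol_row_counts(self):
        ts = TrainingSet([compound("ethanol", "CCO", 0.0)])
        d = build_design(ts, uses_constant=True, uses_special=False)
        row = d.X.toarray()[0]
        by_col = dict(zip(d.columns, row))
        from atomgroups.groups import GroupSignature
        assert by_col[GroupSignature("C sp3", "H3C")] == 1
        assert by_col[GroupSignature("C sp3", "H2CO")] == 1
        assert by_col[GroupSignature("O", "HC")] == 1
        assert by_col[CONST] == 1

    def test_empty_training_set_rejected(self):
        ts = TrainingSet([compound("a", "CCO", 0.1)])
        with pytest.raises(ValueError, match="empty"):
            build_design(ts.drop(["a"]), uses_constant=False, uses_special=False)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TrainingSet([compound("a", "CCO", 0.1), compound("a", "CO", 0.2)])


class TestGaussSeidel:
    def test_identity_system(self):
        a = gauss_seidel_solve(np.eye(3), [1.0, 2.0, 3.0])
        assert a == pytest.approx([1.0, 2.0, 3.0], abs=1e-10)

    def test_hand_solved_overdetermined(self):
        # normal equations [[2,1],[1,2]] a = [3,3] -> a = (1,1)
        X = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        a = gauss_seidel_solve(X, [1.0, 2.0, 1.0])
        assert a == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_noise_free_recovery(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 4, size=(30, 6)).astype(float)
        a_true = rng.uniform(-1, 1, 6)
        a = gauss_seidel_solve(X, X @ a_true)
        assert np.max(np.abs(a - a_true)) < 1e-8

    def test_matches_direct_solver_on_random_systems(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(40, 120))
            p = int(rng.integers(3, 30))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            gs = gauss_seidel_solve(X, y)
            direct = np.linalg.lstsq(X, y, rcond=None)[0]
            assert np.max(np.abs(gs - direct)) < 1e-8

    def test_zero_column_is_error(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="zero diagonal"):
            gauss_seidel_solve(X, [1.0, 2.0])

    def test_non_convergence_carries_iterate(self):
        X = np.array([[1.0, 0.999999], [0.999999, 1.0]])
        with pytest.raises(GaussSeidelError) as exc:
            gauss_seidel_solve(X, [1.0, -1.0], max_iter=5)
        assert exc.value.last_iterate.shape == (2,)
        assert np.isfinite(exc.value.residual_norm)


class TestFitStatistics:
    def test_perfect_fit(self):
        s = fit_statistics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.r2 == pytest.approx(1.0)
        assert s.avg_dev == 0.0 and s.std_dev == 0.0

    def test_constant_predictions_convention(self):
        s = fit_statistics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert s.r2 == 0.0

    def test_zero_variance_y_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_statistics([1.0, 1.0], [1.0, 2.0])

    def test_hand_computed_four_point_example(self):
        y = np.array([1.0, 2.0, 4.0, 5.0])
        p = np.array([1.5, 1.5, 4.5, 4.5])
        # brute-force formulas
        r = np.sum((y - y.mean()) * (p - p.mean())) / np.sqrt(
            np.sum((y - y.mean()) ** 2) * np.sum((p - p.mean()) ** 2)
        )
        s = fit_statistics(y, p)
        assert s.r2 == pytest.approx(r * r, abs=1e-14)
        assert s.avg_dev == pytest.approx(0.5, abs=1e-14)
        assert s.std_dev == pytest.approx(0.5, abs=1e-14)


class TestParameterRecovery:
    def test_synthetic_recovery_with_noise(self):
        spec = SyntheticSpec(n_compounds=500, n_groups=40, noise_sigma=0.10, seed=123)
        ts, a_true = training_set(spec)
        result = fit(ts, uses_constant=False, uses_special=False)
        a_hat = np.array([
            result.coefficients[k]
            for k in sorted(result.coefficients, key=lambda s: int(s.atom_type[1:]))
        ])
        # independent oracle: direct least squares on the same data
        from atomgroups.fit import build_design
        d = build_design(ts, uses_constant=False, uses_special=False)
        direct = np.linalg.lstsq(d.X.toarray(), d.y, rcond=None)[0]
        order = np.argsort([int(s.atom_type[1:]) for s in d.columns])
        assert np.max(np.abs(a_hat - direct[order])) < 1e-8
        assert np.max(np.abs(a_hat - a_true)) < 0.1
        assert np.sqrt(np.mean((a_hat - a_true) ** 2)) < 0.04

    def test_noise_free_refit_r2_is_one(self):
        spec = SyntheticSpec(n_compounds=200, n_groups=20, noise_sigma=0.0, seed=5)
        ts, _ = training_set(spec)
        result = fit(ts, uses_constant=False, uses_special=False)
        assert result.statistics.r2 == pytest.approx(1.0, abs=1e-9)

    def test_fitted_constant_recovered(self):
        spec = SyntheticSpec(n_compounds=300, n_groups=10, constant=-0.7,
                             noise_sigma=0.0, seed=9)
        ts, _ = training_set(spec)
        result = fit(ts, uses_constant=True, uses_special=False)
        assert result.table.constant == pytest.approx(-0.7, abs=1e-7)


class TestOutlierLoop:
    @staticmethod
    def shifted_set(shift, seed=31):
        spec = SyntheticSpec(n_compounds=80, n_groups=8, noise_sigma=0.05, seed=seed)
        ts, _ = training_set(spec)
        target = ts.compounds[17]
        compounds = [
            TrainingCompound(c.id, c.counts, c.value + (shift if c is target else 0.0))
            for c in ts.compounds
        ]
        return TrainingSet(compounds), target.id

    def test_single_shifted_compound_is_unique_exclusion(self):
        ts, shifted_id = self.shifted_set(shift=10 * 0.05)
        result = fit_with_outlier_removal(
            ts, uses_constant=False, uses_special=False, seed=3,
        )
        assert [cid for cid, *_ in result.outliers] == [shifted_id]
        assert result.converged

    def test_clean_set_has_no_outliers(self):
        ts, _ = self.shifted_set(shift=0.0)
        result = fit_with_outlier_removal(
            ts, uses_constant=False, uses_special=False, seed=3,
        )
        assert result.outliers == []
        assert result.converged and result.rounds == 1

    def test_iteration_cap_flags_not_converged(self):
        ts, _ = self.shifted_set(shift=10 * 0.05)
        result = fit_with_outlier_removal(
            ts, uses_constant=False, uses_special=False, seed=3, max_rounds=1,
        )
        assert not result.converged
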