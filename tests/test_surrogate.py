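import numpy as np
import pytest

from gpcuq.spaces import ParameterSpace, ParameterSpec
from gpcuq.surrogate import (
    MultiIndexBasis,
    SampleSet,
    Surrogate,
    basis_count,
    cross_validate,
    design_matrix,
    fit_l1,
    fit_least_squares,
    fit_surrogates,
    legendre_eval,
)


class TestBasis:
    @pytest.mark.parametrize(
        "n, d, expected", [(35, 5, 658_008), (8, 5, 1287), (2, 10, 66), (4, 0, 1)]
    )
    def test_counts(self, n, d, expected):
        assert basis_count(n, d) == expected

    @pytest.mark.parametrize("n, d", [(1, 6), (2, 5), (3, 4), (5, 3), (15, 2)])
    def test_enumeration_matches_count(self, n, d):
        basis = MultiIndexBasis(n, d)
        assert len(basis) == basis_count(n, d)
        # unique, all within the total-degree budget
        assert len({tuple(a) for a in basis.indices}) == len(basis)
        assert basis.indices.sum(axis=1).max() == d

    def test_graded_lexicographic_order(self):
        basis = MultiIndexBasis(3, 3)
        degrees = basis.indices.sum(axis=1)
        assert np.all(np.diff(degrees) >= 0)  # graded
        np.testing.assert_array_equal(basis.indices[0], [0, 0, 0])
        # within a degree block, lexicographically descending leading entry
        block = basis.indices[degrees == 1]
        np.testing.assert_array_equal(block, [[1, 0, 0], [0, 1, 0], [0, 0, 1]])


class TestLegendre:
    def test_p2_at_zero(self):
        assert legendre_eval(2, 0.0) == pytest.approx(-0.5)

    @pytest.mark.parametrize("m", range(11))
    def test_unit_normalization_at_one(self, m):
        assert legendre_eval(m, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonality_under_gauss_quadrature(self):
        """Gram matrix of P_0..P_10 under the uniform measure on [-1,1] is
        diagonal to 1e-10 (Gauss-Legendre quadrature as the oracle)."""
        x, w = np.polynomial.legendre.leggauss(24)
        P = np.array([legendre_eval(m, x) for m in range(11)])
        gram = 0.5 * (P * w) @ P.T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-10
        np.testing.assert_allclose(np.diag(gram), 1.0 / (2 * np.arange(11) + 1),
                                   rtol=1e-10)

    def test_matches_numpy_legendre(self):
        x = np.linspace(-1, 1, 7)
        for m in range(8):
            ref = np.polynomial.legendre.Legendre.basis(m)(x)
            np.testing.assert_allclose(legendre_eval(m, x), ref, atol=1e-12)


class TestDesignMatrix:
    def test_constant_column_and_unit_corner_row(self):
        basis = MultiIndexBasis(3, 2)
        Y = np.vstack([np.ones(3), np.random.default_rng(0).uniform(-1, 1, (4, 3))])
        A = design_matrix(Y, basis)
        np.testing.assert_allclose(A[:, 0], 1.0)  # alpha = 0 term
        np.testing.assert_allclose(A[0], 1.0)  # P_m(1) = 1 for all m

    def test_against_per_factor_oracle(self):
        rng = np.random.default_rng(1)
        basis = MultiIndexBasis(2, 4)
        Y = rng.uniform(-1, 1, (5, 2))
        A = design_matrix(Y, basis)
        for j, alpha in enumerate(basis.indices):
            expected = np.ones(5)
            for k, m in enumerate(alpha):
                expected *= np.polynomial.legendre.Legendre.basis(m)(Y[:, k])
            np.testing.assert_allclose(A[:, j], expected, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            design_matrix(np.zeros((3, 4)), MultiIndexBasis(3, 2))


class TestLeastSquares:
    def test_recovers_exact_polynomial(self):
        rng = np.random.default_rng(2)
        basis = MultiIndexBasis(3, 3)
        Y = rng.uniform(-1, 1, (4 * len(basis), 3))
        A = design_matrix(Y, basis)
        c_true = rng.normal(0, 1, len(basis))
        c = fit_least_squares(A, A @ c_true)
        np.testing.assert_allclose(c, c_true, atol=1e-8)

    def test_zero_rhs(self):
        A = design_matrix(np.random.default_rng(3).uniform(-1, 1, (30, 2)),
                          MultiIndexBasis(2, 2))
        np.testing.assert_allclose(fit_least_squares(A, np.zeros(30)), 0.0)

    def test_residual_orthogonal_to_columns(self):
        rng = np.random.default_rng(4)
        A = design_matrix(rng.uniform(-1, 1, (50, 2)), MultiIndexBasis(2, 3))
        b = rng.normal(0, 1, 50)
        x = fit_least_squares(A, b)
        assert np.abs(A.T @ (A @ x - b)).max() < 1e-8

    def test_undersampled_rejected(self):
        with pytest.raises(ValueError, match="fit_l1"):
            fit_least_squares(np.ones((3, 5)), np.ones(3))

    def test_rank_deficiency_warns(self):
        A = np.ones((6, 2))  # duplicate columns
        with pytest.warns(UserWarning, match="rank"):
            fit_least_squares(A, np.ones(6))


class TestL1:
    def _planted(self, seed=0, n=15, d=2, rows=80, sparsity=10):
        rng = np.random.default_rng(seed)
        basis = MultiIndexBasis(n, d)
        Y = rng.uniform(-1, 1, (rows, n))
        A = design_matrix(Y, basis)
        c = np.zeros(len(basis))
        support = rng.choice(len(basis), sparsity, replace=False)
        c[support] = rng.normal(0, 1, sparsity)
        return A, c, support

    def test_huge_epsilon_gives_zero(self):
        A, c, _ = self._planted()
        assert np.abs(fit_l1(A, A @ c, 1e9)).max() == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_sparse_recovery_from_undersampled_design(self, seed):
        """An undersampled design (80 rows, 136 columns) must exactly
        recover a planted 10-sparse coefficient vector."""
        A, c, support = self._planted(seed=seed)
        x = fit_l1(A, A @ c, 1e-8)
        np.testing.assert_allclose(x, c, atol=1e-4)
        recovered = set(np.flatnonzero(np.abs(x) > 1e-4))
        assert recovered == set(support[np.abs(c[support]) > 1e-4])

    def test_quadratic_constraint_always_satisfied(self):
        A, c, _ = self._planted(seed=3)
        rng = np.random.default_rng(9)
        b = A @ c + rng.normal(0, 0.02, A.shape[0])
        for eps in (0.05 * np.linalg.norm(b), 0.2 * np.linalg.norm(b)):
            x = fit_l1(A, b, eps)
            assert np.linalg.norm(A @ x - b) <= eps * (1 + 1e-6)

    def test_l1_no_worse_than_truth_when_truth_feasible(self):
        A, c, _ = self._planted(seed=4)
        b = A @ c
        x = fit_l1(A, b, 0.1 * np.linalg.norm(b))
        assert np.abs(x).sum() <= np.abs(c).sum() * (1 + 1e-6)

    def test_infeasible_epsilon_rejected(self):
        # overdetermined inconsistent system: no point reaches epsilon = 0-ish
        rng = np.random.default_rng(5)
        A = rng.normal(0, 1, (30, 3))
        b = rng.normal(0, 1, 30)
        with pytest.raises(RuntimeError):
            fit_l1(A, b, 1e-10)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            fit_l1(np.ones((2, 2)), np.ones(2), -1.0)


class TestEvaluate:
    def test_constant_surrogate(self):
        basis = MultiIndexBasis(2, 2)
        c = np.zeros(len(basis))
        c[0] = 3.0
        s = Surrogate(basis, c)
        assert s.evaluate(np.array([0.3, -0.7])) == pytest.approx(3.0)

    def test_linear_coordinate_surrogate(self):
        basis = MultiIndexBasis(2, 1)  # [00, 10, 01]
        s = Surrogate(basis, np.array([0.0, 1.0, 0.0]))
        assert s.evaluate(np.array([0.3, 0.9])) == pytest.approx(0.3)

    def test_matches_naive_summation(self):
        rng = np.random.default_rng(6)
        basis = MultiIndexBasis(3, 4)
        c = rng.normal(0, 1, len(basis))
        s = Surrogate(basis, c)
        for y in rng.uniform(-1, 1, (5, 3)):
            naive = sum(
                ci * np.prod([legendre_eval(m, y[k]) for k, m in enumerate(alpha)])
                for ci, alpha in zip(c, basis.indices)
            )
            assert s.evaluate(y) == pytest.approx(naive, abs=1e-12)

    def test_extrapolation_warns(self):
        s = Surrogate(MultiIndexBasis(1, 1), np.array([0.0, 1.0]))
        with pytest.warns(UserWarning, match="extrapolation"):
            s.evaluate(np.array([1.5]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        basis = MultiIndexBasis(3, 4)
        s = Surrogate(basis, rng.normal(0, 1, len(basis)))
        y = rng.uniform(-0.9, 0.9, 3)
        g = s.gradient(y)
        for j in range(3):
            e = np.eye(3)[j] * 1e-6
            fd = (s.evaluate(y + e) - s.evaluate(y - e)) / 2e-6
            assert g[j] == pytest.approx(fd, abs=1e-7)


class TestCrossValidation:
    def test_realizable_response_has_tiny_error(self):
        rng = np.random.default_rng(8)
        basis = MultiIndexBasis(2, 3)
        Y = rng.uniform(-1, 1, (120, 2))
        c = rng.normal(0, 1, len(basis))
        Z = design_matrix(Y, basis) @ c
        rep = cross_validate(SampleSet(Y=Y, Z=Z), basis, k=5)
        assert rep.mean_abs_error[0] < 1e-8

    def test_pure_noise_statistics(self):
        """Fitting noise: held-out error has mean ~0 and sd ~ the noise sd."""
        rng = np.random.default_rng(9)
        basis = MultiIndexBasis(2, 1)
        Y = rng.uniform(-1, 1, (4000, 2))
        Z = rng.normal(0.0, 0.1, 4000)
        rep = cross_validate(SampleSet(Y=Y, Z=Z), basis, k=10)
        assert abs(rep.mean_error[0]) < 0.01
        assert rep.sd_error[0] == pytest.approx(0.1, rel=0.1)

    def test_undersampled_ls_fold_suggests_l1(self):
        rng = np.random.default_rng(10)
        basis = MultiIndexBasis(4, 3)  # 35 terms
        Y = rng.uniform(-1, 1, (20, 4))
        with pytest.raises(ValueError, match="l1"):
            cross_validate(SampleSet(Y=Y, Z=np.zeros(20)), basis, k=4)

    def test_ls_error_nonincreasing_with_degree(self):
        """With a large sample, higher polynomial degree cannot worsen the
        cross-validated absolute error of a smooth response."""
        rng = np.random.default_rng(11)
        Y = rng.uniform(-1, 1, (1500, 2))
        Z = np.exp(0.8 * Y[:, 0]) * np.sin(1.3 * Y[:, 1] + 0.4)
        maes = []
        for d in (1, 3, 5, 7):
            rep = cross_validate(SampleSet(Y=Y, Z=Z), MultiIndexBasis(2, d), k=5)
            maes.append(rep.mean_abs_error[0])
        assert np.all(np.diff(maes) < 0)


class TestSerialization:
    def test_sampleset_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        ss = SampleSet(Y=rng.uniform(-1, 1, (10, 3)), Z=rng.normal(0, 1, (10, 2)),
                       seed=77, labels=["a", "b"])
        path = tmp_path / "s.csv"
        ss.to_csv(path)
        back = SampleSet.from_csv(path)
        assert back.seed == 77
        assert back.labels == ["a", "b"]
        np.testing.assert_array_equal(back.Y, ss.Y)
        np.testing.assert_array_equal(back.Z, ss.Z)

    def test_surrogate_json_round_trip(self, tmp_path):
        space = ParameterSpace([ParameterSpec("kGa", 1e-7, 1e-3, "log10"),
                                ParameterSpec("q", 1.0, 8.0, "linear")])
        rng = np.random.default_rng(13)
        basis = MultiIndexBasis(2, 3)
        s = Surrogate(basis, rng.normal(0, 1, len(basis)), response_label="pf",
                      space=space)
        path = tmp_path / "s.json"
        s.to_json(path)
        back = Surrogate.from_json(path)
        np.testing.assert_array_equal(back.coeffs, s.coeffs)
        np.testing.assert_array_equal(back.basis.indices, basis.indices)
        assert back.response_label == "pf"
        assert back.space.names == ["kGa", "q"]

    def test_fit_surrogates_convenience(self):
        rng = np.random.default_rng(14)
        basis = MultiIndexBasis(2, 2)
        Y = rng.uniform(-1, 1, (60, 2))
        c = rng.normal(0, 1, len(basis))
        ss = SampleSet(Y=Y, Z=design_matrix(Y, basis) @ c, labels=["resp"])
        (s,) = fit_surrogates(ss, degree=2)
        np.testing.assert_allclose(s.coeffs, c, atol=1e-9)
        assert s.response_label == "resp"
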