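import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from longreg.core import (
    CoefficientTensor,
    GenotypeMatrix,
    ModelHyperparameters,
    PhenotypeTensor,
    fold_mode1,
    longitudinal_loss,
    objective_j2,
    tensor_l21_norm,
    trace_norm,
    unfold_mode1,
)

from conftest import make_problem


def random_tensor(rng, d, c, T):
    return CoefficientTensor(rng.standard_normal((d, c, T)))


class TestTypes:
    def test_phenotype_invariants(self):
        with pytest.raises(ValueError, match="two subjects"):
            PhenotypeTensor(np.zeros((3, 1, 2)))
        with pytest.raises(ValueError, match="non-finite"):
            PhenotypeTensor(np.full((2, 3, 1), np.nan))
        with pytest.raises(ValueError, match="duplicates"):
            PhenotypeTensor(np.zeros((2, 3, 1)), feature_ids=["a", "a"])

    def test_genotype_invariants(self):
        with pytest.raises(ValueError, match="non-finite"):
            GenotypeMatrix(np.array([[np.inf, 0.0]]))
        G = GenotypeMatrix(np.zeros((3, 2)))
        assert G.n_subjects == 3 and G.n_snps == 2

    def test_hyperparameter_invariants(self):
        with pytest.raises(ValueError):
            ModelHyperparameters(gamma1=-1.0)
        with pytest.raises(ValueError):
            ModelHyperparameters(epsilon=0.0)
        with pytest.raises(ValueError):
            ModelHyperparameters(max_iter=0)


class TestUnfold:
    def test_tiny_example(self):
        # B_1 = [1 2], B_2 = [3 4] -> single row [1 2 3 4]
        B = CoefficientTensor(np.array([[[1.0, 3.0], [2.0, 4.0]]]))
        np.testing.assert_array_equal(unfold_mode1(B), [[1.0, 2.0, 3.0, 4.0]])

    def test_zero_tensor(self):
        B = CoefficientTensor(np.zeros((3, 2, 4)))
        np.testing.assert_array_equal(unfold_mode1(B), np.zeros((3, 8)))

    def test_index_oracle(self, rng):
        d, c, T = 4, 3, 2
        B = random_tensor(rng, d, c, T)
        M = unfold_mode1(B)
        for k in range(d):
            for j in range(c):
                for t in range(T):
                    assert M[k, t * c + j] == B.values[k, j, t]

    def test_roundtrip(self, rng):
        B = random_tensor(rng, 5, 3, 4)
        back = fold_mode1(unfold_mode1(B), n_snps=3, n_times=4)
        np.testing.assert_array_equal(back.values, B.values)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(1, 5), st.integers(1, 4), st.integers(1, 4),
           st.integers(0, 10_000))
    def test_roundtrip_property(self, d, c, T, seed):
        B = random_tensor(np.random.default_rng(seed), d, c, T)
        back = fold_mode1(unfold_mode1(B), n_snps=c, n_times=T)
        np.testing.assert_array_equal(back.values, B.values)


class TestTensorL21:
    def test_zero(self):
        assert tensor_l21_norm(CoefficientTensor(np.zeros((3, 2, 2)))) == 0.0

    def test_pythagorean_rows(self):
        B = np.zeros((2, 1, 2))
        B[0, 0] = [3.0, 4.0]
        assert tensor_l21_norm(CoefficientTensor(B)) == pytest.approx(5.0)

    def test_brute_force_oracle(self, rng):
        B = random_tensor(rng, 5, 3, 4)
        expected = 0.0
        for k in range(5):
            s = 0.0
            for j in range(3):
                for t in range(4):
                    s += B.values[k, j, t] ** 2
            expected += s ** 0.5
        assert tensor_l21_norm(B) == pytest.approx(expected, rel=1e-12)

    def test_permutation_within_rows_invariant(self, rng):
        B = random_tensor(rng, 4, 3, 2)
        M = unfold_mode1(B)
        Mp = np.take_along_axis(M, rng.permuted(
            np.tile(np.arange(6), (4, 1)), axis=1), axis=1)
        Bp = fold_mode1(Mp, 3, 2)
        assert tensor_l21_norm(Bp) == pytest.approx(tensor_l21_norm(B))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000),
           st.floats(-100, 100, allow_nan=False))
    def test_homogeneity(self, seed, alpha):
        B = random_tensor(np.random.default_rng(seed), 3, 2, 2)
        scaled = CoefficientTensor(alpha * B.values)
        assert tensor_l21_norm(scaled) == pytest.approx(
            abs(alpha) * tensor_l21_norm(B), abs=1e-9)

    def test_triangle_inequality(self, rng):
        for _ in range(20):
            A = random_tensor(rng, 4, 3, 2)
            B = random_tensor(rng, 4, 3, 2)
            S = CoefficientTensor(A.values + B.values)
            assert tensor_l21_norm(S) <= \
                tensor_l21_norm(A) + tensor_l21_norm(B) + 1e-10


class TestTraceNorm:
    def test_identity(self):
        assert trace_norm(np.eye(3)) == pytest.approx(3.0)

    def test_diagonal(self):
        assert trace_norm(np.diag([3.0, 4.0])) == pytest.approx(7.0)

    def test_spectral_oracle(self, rng):
        M = rng.standard_normal((5, 8))
        evals = np.linalg.eigvalsh(M @ M.T)
        expected = np.sqrt(np.clip(evals, 0, None)).sum()
        assert trace_norm(M) == pytest.approx(expected, rel=1e-10)

    def test_transpose_invariance(self, rng):
        M = rng.standard_normal((4, 7))
        assert trace_norm(M) == pytest.approx(trace_norm(M.T), rel=1e-12)

    def test_homogeneity_and_triangle(self, rng):
        A = rng.standard_normal((4, 6))
        B = rng.standard_normal((4, 6))
        assert trace_norm(2.5 * A) == pytest.approx(2.5 * trace_norm(A), rel=1e-10)
        assert trace_norm(-3.0 * A) == pytest.approx(3.0 * trace_norm(A), rel=1e-10)
        assert trace_norm(A + B) <= trace_norm(A) + trace_norm(B) + 1e-10

    def test_dominates_frobenius(self, rng):
        for _ in range(10):
            M = rng.standard_normal((5, 7))
            assert trace_norm(M) >= np.linalg.norm(M) - 1e-12
        # equality iff rank one
        u, v = rng.standard_normal(5), rng.standard_normal(7)
        R1 = np.outer(u, v)
        assert trace_norm(R1) == pytest.approx(np.linalg.norm(R1), rel=1e-10)


class TestLongitudinalLoss:
    def test_zero_coefficients(self, rng):
        prob = make_problem(seed=1, d=6, n=8, c=3, T=3, k_active=3, rank_r=2)
        B0 = CoefficientTensor(np.zeros((6, 3, 3)))
        expected = 3 * (prob.Y.values ** 2).sum()
        assert longitudinal_loss(prob.X, B0, prob.Y) == pytest.approx(expected)

    def test_exact_interpolation(self, rng):
        d = n = 5
        X = PhenotypeTensor(rng.standard_normal((d, n, 1)))
        Y = GenotypeMatrix(rng.standard_normal((n, 3)))
        B1 = np.linalg.solve(X.slice_at(0).T, Y.values)
        B = CoefficientTensor(B1[:, :, None])
        assert longitudinal_loss(X, B, Y) == pytest.approx(0.0, abs=1e-16)

    def test_brute_force_oracle(self, rng):
        prob = make_problem(seed=2, d=4, n=6, c=3, T=2, k_active=2, rank_r=1)
        B = random_tensor(rng, 4, 3, 2)
        expected = 0.0
        for t in range(2):
            for i in range(6):
                for j in range(3):
                    pred = sum(prob.X.values[k, i, t] * B.values[k, j, t]
                               for k in range(4))
                    expected += (pred - prob.Y.values[i, j]) ** 2
        assert longitudinal_loss(prob.X, B, prob.Y) == pytest.approx(expected)

    def test_shape_errors_name_axis(self, rng):
        prob = make_problem(seed=3, d=4, n=6, c=3, T=2, k_active=2, rank_r=1)
        with pytest.raises(ValueError, match="feature axis"):
            longitudinal_loss(prob.X, random_tensor(rng, 5, 3, 2), prob.Y)
        with pytest.raises(ValueError, match="time axis"):
            longitudinal_loss(prob.X, random_tensor(rng, 4, 3, 3), prob.Y)
        with pytest.raises(ValueError, match="snp axis"):
            longitudinal_loss(prob.X, random_tensor(rng, 4, 4, 2), prob.Y)


class TestObjective:
    def test_zero_coefficients_any_gamma(self):
        prob = make_problem(seed=4, d=5, n=7, c=3, T=2, k_active=2, rank_r=1)
        B0 = CoefficientTensor(np.zeros((5, 3, 2)))
        hp = ModelHyperparameters(gamma1=3.7, gamma2=11.0)
        expected = 2 * (prob.Y.values ** 2).sum()
        assert objective_j2(prob.X, B0, prob.Y, hp) == pytest.approx(expected)

    def test_reduces_to_loss(self, rng):
        prob = make_problem(seed=5, d=5, n=7, c=3, T=2, k_active=2, rank_r=1)
        B = random_tensor(rng, 5, 3, 2)
        hp = ModelHyperparameters(gamma1=0.0, gamma2=0.0)
        assert objective_j2(prob.X, B, prob.Y, hp) == \
            pytest.approx(longitudinal_loss(prob.X, B, prob.Y))

    def test_composition_of_terms(self, rng):
        prob = make_problem(seed=6, d=5, n=7, c=3, T=2, k_active=2, rank_r=1)
        B = random_tensor(rng, 5, 3, 2)
        hp = ModelHyperparameters(gamma1=0.5, gamma2=2.0)
        expected = (longitudinal_loss(prob.X, B, prob.Y)
                    + 0.5 * tensor_l21_norm(B)
                    + 2.0 * trace_norm(unfold_mode1(B)))
        assert objective_j2(prob.X, B, prob.Y, hp) == pytest.approx(expected, rel=1e-12)

    def test_convexity_probe(self, rng):
        prob = make_problem(seed=7, d=5, n=7, c=3, T=2, k_active=2, rank_r=1)
        hp = ModelHyperparameters(gamma1=1.3, gamma2=0.7)
        for _ in range(20):
            A = random_tensor(rng, 5, 3, 2)
            B = random_tensor(rng, 5, 3, 2)
            lam = rng.uniform()
            mix = CoefficientTensor(lam * A.values + (1 - lam) * B.values)
            lhs = objective_j2(prob.X, mix, prob.Y, hp)
            rhs = (lam * objective_j2(prob.X, A, prob.Y, hp)
                   + (1 - lam) * objective_j2(prob.X, B, prob.Y, hp))
            assert lhs <= rhs + 1e-10
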