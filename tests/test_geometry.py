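"""Geometry of the SPD manifold: distances, means, matrix functions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spdmap as sm
from spdmap import geometry
from spdmap.exceptions import ConvergenceError, DimensionError, NotSPDError, SymmetryError

from conftest import make_spd


class TestSymEig:
    def test_identity(self):
        w, U = sm.sym_eig(np.eye(3))
        assert np.allclose(w, 1.0)
        assert np.allclose(U, np.eye(3))

    def test_ascending_and_permuted(self):
        w, U = sm.sym_eig(np.diag([4.0, 1.0]))
        assert np.allclose(w, [1.0, 4.0])
        assert np.allclose(np.abs(U), [[0, 1], [1, 0]])

    def test_reconstruction_and_orthonormality(self, rng):
        A = rng.normal(size=(5, 5))
        A = A + A.T
        w, U = sm.sym_eig(A)
        assert np.max(np.abs((U * w) @ U.T - A)) < 1e-10
        assert np.max(np.abs(U.T @ U - np.eye(5))) < 1e-10

    def test_sign_convention(self, rng):
        A = rng.normal(size=(6, 6))
        _, U = sm.sym_eig(A + A.T)
        idx = np.argmax(np.abs(U), axis=0)
        assert (U[idx, np.arange(6)] > 0).all()

    def test_nonsymmetric_raises_with_magnitude(self):
        A = np.array([[1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(SymmetryError, match="2"):
            sm.sym_eig(A)


class TestMatrixFunctions:
    def test_power_examples(self):
        assert np.allclose(sm.spd_power(np.eye(3), -0.5), np.eye(3))
        assert np.allclose(sm.spd_power(np.diag([4.0, 9.0]), 0.5), np.diag([2.0, 3.0]))

    def test_power_roundtrip_and_inverse_sqrt(self, rng):
        A = make_spd(rng, 6)
        assert np.max(np.abs(sm.spd_power(sm.spd_power(A, 2.0), 0.5) - A)) < 1e-8
        P = sm.spd_power(A, 0.5) @ sm.spd_power(A, -0.5)
        assert np.max(np.abs(P - np.eye(6))) < 1e-8

    def test_power_rejects_indefinite(self):
        with pytest.raises(NotSPDError):
            sm.spd_power(np.diag([1.0, -1.0]), 0.5)

    def test_log_exp_inverses(self, rng):
        assert np.allclose(sm.spd_log(np.eye(4)), 0.0)
        assert np.allclose(sm.sym_exp(np.zeros((4, 4))), np.eye(4))
        assert np.allclose(sm.spd_log(np.diag([np.e, np.e**2])), np.diag([1.0, 2.0]))
        A = make_spd(rng, 5)
        assert np.max(np.abs(sm.sym_exp(sm.spd_log(A)) - A)) < 1e-8


class TestRiemannianDistance:
    def test_identity_of_indiscernibles(self, rng):
        A = make_spd(rng, 7)
        assert sm.riemannian_distance(A, A) < 1e-8

    @given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=6),
           st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_diagonal_closed_form(self, diag_a, data):
        diag_b = data.draw(st.lists(st.floats(0.1, 10.0),
                                    min_size=len(diag_a), max_size=len(diag_a)))
        a, b = np.array(diag_a), np.array(diag_b)
        d = sm.riemannian_distance(np.diag(a), np.diag(b))
        assert d == pytest.approx(np.sqrt(np.sum(np.log(a / b) ** 2)), abs=1e-10)

    def test_symmetry_and_triangle(self, rng):
        A, B, C = (make_spd(rng, 5) for _ in range(3))
        dab = sm.riemannian_distance(A, B)
        assert dab == pytest.approx(sm.riemannian_distance(B, A), abs=1e-8)
        assert sm.riemannian_distance(A, C) <= dab + sm.riemannian_distance(B, C) + 1e-8

    def test_affine_invariance(self, rng):
        A, B = make_spd(rng, 6), make_spd(rng, 6)
        d = sm.riemannian_distance(A, B)
        for _ in range(10):
            X = rng.normal(size=(6, 6)) + 0.5 * np.eye(6)
            assert sm.riemannian_distance(X @ A @ X.T, X @ B @ X.T) == pytest.approx(d, abs=1e-6)

    def test_inversion_invariance(self, rng):
        A, B = make_spd(rng, 5), make_spd(rng, 5)
        d = sm.riemannian_distance(A, B)
        assert sm.riemannian_distance(np.linalg.inv(A), np.linalg.inv(B)) == pytest.approx(d, abs=1e-8)

    def test_errors(self, rng):
        A = make_spd(rng, 4)
        with pytest.raises(DimensionError):
            sm.riemannian_distance(A, make_spd(rng, 5))
        with pytest.raises(NotSPDError):
            sm.riemannian_distance(A, np.diag([1.0, -1.0, 1.0, 1.0]))


class TestEuclideanDistance:
    def test_examples(self, rng):
        A = make_spd(rng, 4)
        assert sm.euclidean_distance(A, A) == 0.0
        assert sm.euclidean_distance(np.zeros((2, 2)), np.eye(2)) == pytest.approx(np.sqrt(2))
        B = make_spd(rng, 4)
        assert sm.euclidean_distance(A, B) == pytest.approx(
            np.sqrt(np.sum((A - B) ** 2)))


class TestFrechetMeans:
    def test_mean_of_copies(self, rng):
        A = make_spd(rng, 5)
        assert np.max(np.abs(sm.frechet_mean_riemannian([A, A, A]) - A)) < 1e-6

    def test_commuting_geometric_mean(self):
        m = sm.frechet_mean_riemannian([np.diag([1.0, 1.0]), np.diag([4.0, 1.0])])
        assert np.allclose(m, np.diag([2.0, 1.0]), atol=1e-6)

    def test_congruence_equivariance(self, rng):
        Fs = [make_spd(rng, 5) for _ in range(4)]
        X = rng.normal(size=(5, 5)) + 0.5 * np.eye(5)
        lhs = sm.frechet_mean_riemannian([X @ F @ X.T for F in Fs])
        rhs = X @ sm.frechet_mean_riemannian(Fs) @ X.T
        assert np.max(np.abs(lhs - rhs)) < 1e-6

    def test_objective_monotone_and_gradient_at_tol(self, rng):
        Fs = [make_spd(rng, 6) for _ in range(5)]
        mean, info = geometry.frechet_mean_riemannian(Fs, return_info=True)
        obj = np.array(info["objective"])
        assert np.all(np.diff(obj) <= 1e-10)
        assert info["grad_norms"][-1] <= 1e-8

    def test_nonconvergence_carries_gradient(self, rng):
        Fs = [make_spd(rng, 5) for _ in range(4)]
        with pytest.raises(ConvergenceError) as exc:
            sm.frechet_mean_riemannian(Fs, tol=1e-16, max_iter=2)
        assert exc.value.gradient_norm is not None

    def test_euclidean_mean(self, rng):
        A = make_spd(rng, 4)
        assert np.allclose(sm.frechet_mean_euclidean([A]), A)
        assert np.allclose(
            sm.frechet_mean_euclidean([np.diag([1.0, 1.0]), np.diag([3.0, 1.0])]),
            np.diag([2.0, 1.0]))
        with pytest.raises(ValueError):
            sm.frechet_mean_euclidean([])

    def test_euclidean_mean_first_order_optimal(self, rng):
        Fs = [make_spd(rng, 4) for _ in range(5)]
        m = sm.frechet_mean_euclidean(Fs)
        ssq = sum(np.sum((m - F) ** 2) for F in Fs)
        for _ in range(10):
            D = rng.normal(size=(4, 4)) * 1e-3
            pert = sum(np.sum((m + D - F) ** 2) for F in Fs)
            assert pert >= ssq - 1e-12


class TestAssertSPD:
    def test_pass_through(self, rng):
        A = make_spd(rng, 5)
        out, mass = sm.assert_spd(A)
        assert mass == 0.0
        assert np.allclose(out, A)

    def test_repair_clips(self):
        A = np.diag([1.0, -0.5])
        out, mass = sm.assert_spd(A, repair=True)
        w = np.linalg.eigvalsh(out)
        assert w[0] > 0
        assert mass == pytest.approx(0.5, rel=1e-6)

    def test_reject_without_repair(self):
        with pytest.raises(NotSPDError):
            sm.assert_spd(np.diag([1.0, -0.5]))
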