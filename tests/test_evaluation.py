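"""Pairwise distances, nearest neighbors, distance regression, LOOCV."""

import numpy as np
import pytest

import spdmap as sm
from spdmap import evaluation, geometry

from conftest import make_spd


class TestPairwiseDistances:
    def test_identical_matrices(self, rng):
        A = make_spd(rng, 4)
        D = sm.pairwise_distances([A, A, A])
        assert np.max(D.values) < 1e-6

    def test_two_matrices(self, rng):
        A, B = make_spd(rng, 4), make_spd(rng, 4)
        D = sm.pairwise_distances([A, B], metric="riemannian")
        assert D.values[0, 1] == pytest.approx(geometry.riemannian_distance(A, B))

    @pytest.mark.parametrize("metric", ["riemannian", "euclidean"])
    def test_brute_force_oracle(self, rng, metric):
        mats = [make_spd(rng, 5) for _ in range(5)]
        dist = (geometry.riemannian_distance if metric == "riemannian"
                else geometry.euclidean_distance)
        D = sm.pairwise_distances(mats, metric=metric)
        for i in range(5):
            for j in range(5):
                expect = 0.0 if i == j else dist(mats[i], mats[j])
                assert D.values[i, j] == pytest.approx(expect, abs=1e-10)
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0.0)

    def test_summary_fields(self, rng):
        mats = [make_spd(rng, 4) for _ in range(6)]
        s = sm.pairwise_distances(mats).summary()
        assert set(s) == {"mean", "sd", "min", "max"}
        assert s["min"] <= s["mean"] <= s["max"]


class TestNearestNeighbors:
    def test_strict_minimum_and_ties(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 0.5], [2.0, 0.5, 0.0]])
        assert sm.nearest_neighbors(D).tolist() == [1, 2, 1]
        tie = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 2.0], [1.0, 2.0, 0.0]])
        assert sm.nearest_neighbors(tie)[0] == 1  # tie -> lowest index

    def test_brute_force_oracle(self, rng):
        V = rng.random((6, 6))
        V = V + V.T
        np.fill_diagonal(V, 0.0)
        nn = sm.nearest_neighbors(V)
        for i in range(6):
            best, bd = None, np.inf
            for j in range(6):
                if j != i and V[i, j] < bd:
                    best, bd = j, V[i, j]
            assert nn[i] == best

    def test_agreement(self):
        a = np.array([1, 0, 1])
        assert sm.nn_agreement(a, a) == 3
        assert sm.nn_agreement(a, np.array([1, 2, 0])) == 1


class TestDistanceRegression:
    def test_proportional_gives_one(self, rng):
        V = rng.random((6, 6))
        V = V + V.T
        np.fill_diagonal(V, 0.0)
        assert sm.distance_regression(V, 3.5 * V) == pytest.approx(1.0)

    def test_affine_rescaling_invariance(self, rng):
        A = rng.random((7, 7)); A = A + A.T; np.fill_diagonal(A, 0.0)
        B = rng.random((7, 7)); B = B + B.T; np.fill_diagonal(B, 0.0)
        r = sm.distance_regression(A, B)
        assert sm.distance_regression(2.0 * A, B) == pytest.approx(r, abs=1e-12)
        assert sm.distance_regression(A, 0.1 * B) == pytest.approx(r, abs=1e-12)

    def test_independent_near_zero(self):
        r2s = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            A = rng.random((30, 30)); A = A + A.T; np.fill_diagonal(A, 0.0)
            B = rng.random((30, 30)); B = B + B.T; np.fill_diagonal(B, 0.0)
            r2s.append(sm.distance_regression(A, B))
        assert np.median(r2s) < 0.05

    def test_zero_variance_error(self):
        A = np.ones((4, 4)) - np.eye(4)
        B = np.random.default_rng(0).random((4, 4))
        B = B + B.T; np.fill_diagonal(B, 0.0)
        with pytest.raises(ValueError, match="zero-variance"):
            sm.distance_regression(A, B)


class TestLOOCV:
    def test_identical_subjects_zero_msd(self, rng):
        F = make_spd(rng, 5)
        S = sm.symmetrize_normalize(rng.random((5, 5)))
        cohort = sm.Cohort(["a", "b", "c"], [S] * 3, [F] * 3)
        rep = sm.loocv_evaluate([], cohort)
        assert rep.msd("riemannian_mean") < 1e-10

    def test_two_fold_hand_unrolled(self, rng):
        Fs = [make_spd(rng, 4), make_spd(rng, 4)]
        S = sm.symmetrize_normalize(rng.random((4, 4)))
        cohort = sm.Cohort(["a", "b"], [S, S], Fs)
        rep = sm.loocv_evaluate([], cohort)
        d2 = geometry.riemannian_distance(Fs[0], Fs[1]) ** 2
        assert rep.msd("riemannian_mean") == pytest.approx(d2, rel=1e-8)

    def test_nn_mean_full_p_degenerates_to_mean(self, small_cohort):
        cohort, _ = small_cohort
        rep = sm.loocv_evaluate([f"nn_mean:{cohort.K - 1}"], cohort)
        assert rep.msd(f"nn_mean:{cohort.K - 1}") == pytest.approx(
            rep.msd("riemannian_mean"), abs=1e-8)

    def test_report_msd_recomputable(self, small_cohort):
        cohort, _ = small_cohort
        rep = sm.loocv_evaluate(["euclidean_mean"], cohort)
        for rec in rep.per_model.values():
            assert rec["msd"] == pytest.approx(
                float(np.nanmean(rec["squared_distances"])), abs=1e-12)

    def test_report_save(self, tmp_path, small_cohort):
        cohort, _ = small_cohort
        rep = sm.loocv_evaluate(["euclidean_mean"], cohort)
        rep.save(tmp_path / "out")
        assert (tmp_path / "out" / "per_subject_distances.csv").exists()
        assert "riemannian_mean" in (tmp_path / "out" / "report.txt").read_text()

    def test_unknown_spec(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError, match="unknown model spec"):
            sm.loocv_evaluate(["glass_ceiling"], cohort)
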