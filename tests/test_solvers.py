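"""Source-to-target solvers: Procrustes, entropic OT, ridge, ProMises,
parcel-wise fitting and block-diagonal application."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import orthogonal_procrustes

from intalign import (
    FullTransform,
    ParcelTransform,
    ParcelwiseAlignment,
    Parcellation,
    ProcrustesAlignment,
    SurfaceGeometry,
    TimeseriesImage,
    apply_transform,
    fit_parcelwise,
    load_transform,
    optimal_transport_fit,
    procrustes_fit,
    promises_fit,
    ridge_fit,
    save_transform,
    transport_cost,
    transport_entropy,
)
from intalign.solvers import _functional_cost, sinkhorn_plan


def random_permutation_matrix(n, rng):
    P = np.zeros((n, n))
    P[np.arange(n), rng.permutation(n)] = 1.0
    return P


class TestProcrustes:
    def test_self_alignment_is_identity(self, rng):
        FX = rng.standard_normal((4, 9))
        t = procrustes_fit(FX, FX)
        assert np.allclose(t.R, np.eye(4), atol=1e-10)
        assert t.scale_s == pytest.approx(1.0)

    def test_two_vertex_swap(self):
        FX = np.eye(2)
        FY = np.array([[0.0, 1.0], [1.0, 0.0]])
        t = procrustes_fit(FX, FY)
        assert np.allclose(t.R, FY, atol=1e-12)
        assert t.scale_s == pytest.approx(1.0)

    def test_permutation_recovery_with_swap_minimality(self, rng):
        """Recovered R equals the true permutation, and beats every 1-swap
        perturbation of it in residual norm."""
        FX = rng.standard_normal((5, 8))
        P = random_permutation_matrix(5, rng)
        FY = P @ FX
        t = procrustes_fit(FX, FY)
        assert np.abs(t.R - P).max() < 1e-8
        best = np.linalg.norm(t.R @ FX - FY)
        assert best < 1e-8
        for i in range(5):
            for j in range(i + 1, 5):
                Pswap = P.copy()
                Pswap[[i, j]] = Pswap[[j, i]]
                assert np.linalg.norm(Pswap @ FX - FY) > best

    def test_matches_scipy_oracle(self, rng):
        """min ||R FX - FY|| with R = M.T of scipy's min ||FX.T W - FY.T||."""
        FX = rng.standard_normal((6, 10))
        FY = rng.standard_normal((6, 10))
        t = procrustes_fit(FX, FY, allow_scaling=False)
        W, _ = orthogonal_procrustes(FX.T, FY.T)
        assert np.allclose(t.R, W.T, atol=1e-10)

    def test_orthonormality_and_scale(self, rng):
        FX = rng.standard_normal((7, 12))
        FY = 3.0 * rng.standard_normal((7, 12))
        t = procrustes_fit(FX, FY)
        M = t.R / t.scale_s
        assert np.linalg.norm(M.T @ M - np.eye(7)) < 1e-8
        assert t.scale_s > 0
        t.validate()

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_norm_and_angle_preservation(self, seed):
        """The orthonormal factor preserves vector norms and angles between maps."""
        rng = np.random.default_rng(seed)
        FX = rng.standard_normal((5, 7))
        FY = rng.standard_normal((5, 7))
        t = procrustes_fit(FX, FY, allow_scaling=False)
        x, y = rng.standard_normal((2, 5))
        assert np.linalg.norm(t.R @ x) == pytest.approx(np.linalg.norm(x))
        assert np.dot(t.R @ x, t.R @ y) == pytest.approx(np.dot(x, y))

    def test_zero_source_warns_identity(self):
        with pytest.warns(UserWarning, match="all-zero"):
            t = procrustes_fit(np.zeros((3, 4)), np.ones((3, 4)))
        assert np.array_equal(t.R, np.eye(3))

    def test_underdetermined_warns(self, rng):
        with pytest.warns(UserWarning, match="underdetermined"):
            procrustes_fit(rng.standard_normal((5, 3)), rng.standard_normal((5, 3)))

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            procrustes_fit(rng.standard_normal((3, 4)), rng.standard_normal((4, 4)))


class TestOptimalTransport:
    def test_cost_matrix_euclidean(self):
        FX = np.array([[0.0, 0.0], [3.0, 4.0]])
        C = _functional_cost(FX, FX, zscore=False)
        assert np.allclose(C, [[0.0, 5.0], [5.0, 0.0]])

    def test_small_epsilon_self_alignment_identity(self):
        FX = np.array([[0.0, 0.0], [3.0, 4.0]])
        t = optimal_transport_fit(FX, FX, epsilon=0.01, zscore=False)
        assert np.diag(t.R).min() > 0.999
        t.validate()

    def test_large_epsilon_uniform_plan_and_entropy(self, rng):
        FX = rng.standard_normal((2, 6))
        FY = rng.standard_normal((2, 6))
        t = optimal_transport_fit(FX, FY, epsilon=1e6, zscore=False)
        assert np.allclose(t.R, 0.5, atol=1e-3)
        # H of the exactly uniform row/column-stochastic plan at v=2
        assert transport_entropy(np.full((2, 2), 0.5)) == pytest.approx(3.3863, abs=1e-4)

    def test_marginals_within_tolerance(self, rng):
        FX = rng.standard_normal((6, 10))
        FY = rng.standard_normal((6, 10))
        t = optimal_transport_fit(FX, FY, epsilon=0.5)
        assert (t.R >= -1e-12).all()
        assert np.abs(t.R.sum(axis=0) - 1).max() < 1e-6
        assert np.abs(t.R.sum(axis=1) - 1).max() < 1e-6

    def test_cost_weakly_decreases_with_epsilon(self, rng):
        FX = rng.standard_normal((5, 20))
        FY = rng.standard_normal((5, 20))
        C = _functional_cost(FX, FY, zscore=True)
        costs = [
            transport_cost(
                optimal_transport_fit(FX, FY, epsilon=e, max_iter=50_000, tol=1e-7).R.T, C
            )
            for e in (0.05, 0.2, 1.0, 5.0)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(costs, costs[1:]))

    def test_epsilon_positive_required(self, rng):
        with pytest.raises(ValueError):
            optimal_transport_fit(rng.standard_normal((3, 4)), rng.standard_normal((3, 4)), epsilon=0.0)

    def test_nonconvergence_reports_violation(self, rng):
        C = rng.random((4, 4))
        with pytest.raises(RuntimeError, match="marginal violation"):
            sinkhorn_plan(C, epsilon=0.01, max_iter=1, tol=1e-15)


class TestRidge:
    def test_scalar_closed_form(self):
        assert ridge_fit(np.array([[2.0]]), np.array([[4.0]]), alpha=0.0).R == pytest.approx(2.0)
        assert ridge_fit(np.array([[2.0]]), np.array([[4.0]]), alpha=4.0).R == pytest.approx(1.0)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.linear_model import Ridge

        FX = rng.standard_normal((4, 6))
        FY = rng.standard_normal((4, 6))
        t = ridge_fit(FX, FY, alpha=1000.0)
        # independent route: per-row ridge regression of FY.T on FX.T
        oracle = Ridge(alpha=1000.0, fit_intercept=False).fit(FX.T, FY.T).coef_
        assert np.allclose(t.R, oracle, atol=1e-8)

    def test_alpha_to_zero_approaches_pseudoinverse(self, rng):
        FX = rng.standard_normal((4, 10))  # full row rank a.s.
        FY = rng.standard_normal((4, 10))
        t = ridge_fit(FX, FY, alpha=1e-10)
        assert np.allclose(t.R, FY @ np.linalg.pinv(FX), atol=1e-6)

    def test_singular_alpha_zero_errors(self):
        FX = np.ones((3, 4))  # rank 1
        with pytest.raises(np.linalg.LinAlgError, match="alpha"):
            ridge_fit(FX, FX, alpha=0.0)

    def test_self_alignment_is_shrunk_not_identity(self, rng):
        """Ridge shrinks even on self-alignment (unlike Procrustes/OT)."""
        FX = rng.standard_normal((4, 12))
        t = ridge_fit(FX, FX, alpha=100.0)
        assert not np.allclose(t.R, np.eye(4), atol=1e-3)
        assert np.trace(t.R) < 4.0


class TestProMises:
    @pytest.fixture
    def line_geometry(self):
        coords = np.column_stack([np.arange(4.0), np.zeros(4)])
        return SurfaceGeometry(coords)

    def test_k_zero_bit_identical_to_procrustes(self, rng, line_geometry):
        FX = rng.standard_normal((4, 9))
        FY = rng.standard_normal((4, 9))
        D = line_geometry.distances()
        a = promises_fit(FX, FY, k=0.0, distances=D)
        b = procrustes_fit(FX, FY, allow_scaling=False)
        assert np.array_equal(a.R, b.R)

    def test_large_k_prior_dominates_to_identity(self, rng, line_geometry):
        """Brute force over all 4x4 permutations: identity maximizes trace(M'Q),
        and at huge k the fit returns (approximately) the identity."""
        from itertools import permutations

        D = line_geometry.distances()
        Q = np.exp(-D)
        traces = {}
        for perm in permutations(range(4)):
            P = np.zeros((4, 4))
            P[np.arange(4), perm] = 1.0
            traces[perm] = np.trace(P.T @ Q)
        assert max(traces, key=traces.get) == (0, 1, 2, 3)
        FX = rng.standard_normal((4, 9))
        FY = rng.standard_normal((4, 9))
        t = promises_fit(FX, FY, k=1e9, distances=D)
        assert np.allclose(t.R, np.eye(4), atol=1e-3)

    def test_k_sweep_pulls_away_from_permutation(self, line_geometry):
        """With FY a shifted copy of FX, alignment with the shift permutation
        weakens monotonically as the spatial prior strengthens."""
        rng = np.random.default_rng(3)
        FX = rng.standard_normal((4, 30))
        P = np.zeros((4, 4))
        P[np.arange(4), (np.arange(4) + 1) % 4] = 1.0  # cyclic shift
        FY = P @ FX
        D = line_geometry.distances()
        overlaps = [
            np.trace(promises_fit(FX, FY, k=k, distances=D).R.T @ P)
            for k in (0.0, 1.0, 5.0, 50.0, 500.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(overlaps, overlaps[1:]))
        assert overlaps[0] > overlaps[-1]

    def test_negative_k_rejected(self, rng, line_geometry):
        with pytest.raises(ValueError):
            promises_fit(np.eye(4), np.eye(4), k=-1.0, distances=line_geometry.distances())


class TestParcelwise:
    def test_self_alignment_identity_both_solvers(self, rng, small_world):
        parc, _ = small_world
        X = rng.standard_normal((20, 30))
        T = fit_parcelwise(X, X, parc, method="procrustes")
        assert T.is_identity(atol=1e-8)
        T = fit_parcelwise(X, X, parc, method="optimal_transport", hyperparams={"epsilon": 0.01})
        for pid in parc.parcel_ids:
            assert np.diag(T[pid].R).min() > 0.99

    def test_independent_parcels_no_cross_mixing(self, rng, small_world):
        parc, _ = small_world
        X = rng.standard_normal((20, 40))
        Y = X.copy()
        perms = {}
        for pid in parc.parcel_ids:
            idx = parc.vertices_of(pid)
            P = random_permutation_matrix(idx.size, rng)
            perms[pid] = P
            Y[idx] = P @ X[idx]
        T = fit_parcelwise(X, Y, parc, method="procrustes")
        for pid in parc.parcel_ids:
            assert np.abs(T[pid].R - perms[pid]).max() < 1e-8

    def test_single_vertex_parcels(self, rng):
        parc = Parcellation([1, 2, 3])
        X = rng.standard_normal((3, 5))
        T = fit_parcelwise(X, X, parc, method="procrustes")
        for pid in parc.parcel_ids:
            assert T[pid].R.shape == (1, 1)
            assert abs(abs(T[pid].R[0, 0] / T[pid].scale_s) - 1.0) < 1e-12

    def test_solver_error_annotated_with_parcel(self, small_world):
        parc, _ = small_world
        X = np.ones((20, 4))  # rank-1 blocks
        with pytest.raises(np.linalg.LinAlgError, match="parcel 1"):
            fit_parcelwise(X, X, parc, method="ridge", hyperparams={"alpha": 0.0})


class TestApplyTransform:
    def test_identity_bitwise(self, rng, small_world):
        parc, _ = small_world
        T = FullTransform(
            [ParcelTransform(pid, np.eye(10), "identity") for pid in parc.parcel_ids], parc
        )
        im = TimeseriesImage(rng.standard_normal((20, 6)))
        out = apply_transform(T, im)
        assert np.array_equal(out.data, im.data)

    def test_matches_dense_block_diagonal_oracle(self, rng):
        labels = np.array([1, 1, 1, 2, 2, 2, 2, 0, 3, 3])
        parc = Parcellation(labels)
        X = rng.standard_normal((10, 4))
        transforms = []
        dense = np.eye(10)
        for pid in parc.parcel_ids:
            idx = parc.vertices_of(pid)
            R = rng.standard_normal((idx.size, idx.size))
            transforms.append(ParcelTransform(pid, R, "ridge"))
            dense[np.ix_(idx, idx)] = R
        T = FullTransform(transforms, parc)
        assert np.allclose(T.apply_array(X), dense @ X, atol=1e-12)

    def test_linearity(self, rng, small_world, tiny_cohort):
        parc, _ = small_world
        movies, *_ = tiny_cohort
        X = rng.standard_normal((20, 8))
        Y = rng.standard_normal((20, 8))
        T = fit_parcelwise(X, Y, parc, method="procrustes")
        a, b = 2.5, -1.25
        lhs = T.apply_array(a * X + b * Y)
        rhs = a * T.apply_array(X) + b * T.apply_array(Y)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_signal_stays_within_parcel(self, rng, small_world):
        """A map supported on one parcel stays supported on that parcel."""
        parc, _ = small_world
        X = rng.standard_normal((20, 30))
        Y = rng.standard_normal((20, 30))
        T = fit_parcelwise(X, Y, parc, method="procrustes")
        probe = np.zeros(20)
        idx1 = parc.vertices_of(1)
        probe[idx1] = rng.standard_normal(idx1.size)
        out = T.apply_array(probe)
        other = parc.vertices_of(2)
        assert np.all(out[other] == 0.0)

    def test_unassigned_vertices_pass_through(self, rng):
        parc = Parcellation([1, 1, 0, 2, 2])
        X = rng.standard_normal((5, 6))
        Y = rng.standard_normal((5, 6))
        T = fit_parcelwise(X, Y, parc, method="procrustes")
        out = T.apply_array(X)
        assert np.array_equal(out[2], X[2])

    def test_shape_mismatch_rejected(self, rng, small_world):
        parc, _ = small_world
        T = fit_parcelwise(rng.standard_normal((20, 5)), rng.standard_normal((20, 5)), parc)
        with pytest.raises(ValueError):
            T.apply_array(np.zeros((7, 5)))


class TestSerializationAndEstimators:
    def test_transform_roundtrip(self, tmp_path, rng, small_world):
        parc, _ = small_world
        T = fit_parcelwise(rng.standard_normal((20, 25)), rng.standard_normal((20, 25)), parc)
        f = tmp_path / "T.h5"
        save_transform(T, f, manifest_path=tmp_path / "T.manifest.txt")
        back = load_transform(f)
        for pid in parc.parcel_ids:
            assert np.array_equal(back[pid].R, T[pid].R)
            assert back[pid].method == T[pid].method
        manifest = (tmp_path / "T.manifest.txt").read_text()
        assert "parcel\t1" in manifest

    def test_estimator_matches_function(self, rng, small_world):
        parc, _ = small_world
        X = rng.standard_normal((20, 30))
        Y = rng.standard_normal((20, 30))
        est = ParcelwiseAlignment(parcellation=parc, method="procrustes").fit(X, Y)
        direct = fit_parcelwise(X, Y, parc, method="procrustes")
        for pid in parc.parcel_ids:
            assert np.array_equal(est.transform_[pid].R, direct[pid].R)
        assert np.allclose(est.transform(X), direct.apply_array(X))

    def test_sklearn_params_protocol(self):
        est = ProcrustesAlignment(scaling=False)
        assert est.get_params() == {"scaling": False}
        est.set_params(scaling=True)
        assert est.scaling is True
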