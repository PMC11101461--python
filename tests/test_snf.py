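"""Kernel constructions and cross-diffusion fusion."""

import numpy as np
import pytest

from snfmark.cluster import spectral_cluster
from snfmark.rank import nmi
from snfmark.snf import (SNF, SnfParams, affinity, convergence_curve,
                         full_kernel, fuse, relative_spectral_change,
                         sparse_kernel)


class TestAffinity:
    def test_identical_patients_similarity_one(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0], [9.0, 1.0]])
        W = affinity(X, SnfParams(k=2))
        assert W[0, 1] == 1.0

    def test_three_equidistant_patients_hand_value(self):
        """d=1 everywhere, k=1, α=0.5: ε=(1+1+1)/3=1, W=exp(-1/0.5)=e⁻²."""
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        W = affinity(X, SnfParams(k=1, alpha=0.5))
        off = W[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, np.exp(-2.0), rtol=1e-12)

    def test_alpha_monotonicity(self, rng):
        X = rng.normal(size=(12, 5))
        W1 = affinity(X, SnfParams(k=4, alpha=0.3))
        W2 = affinity(X, SnfParams(k=4, alpha=0.9))
        off = ~np.eye(12, dtype=bool)
        assert (W2[off] > W1[off]).all()

    def test_symmetry_and_finiteness_for_large_distances(self):
        X = np.diag([1e3, 1e3, 1e3, 1e3])  # d² up to 2e6
        W = affinity(X, SnfParams(k=2, alpha=0.05))
        assert np.isfinite(W).all()
        np.testing.assert_allclose(W, W.T)

    def test_requires_three_patients(self):
        with pytest.raises(ValueError, match="3 patients"):
            affinity(np.ones((2, 4)), SnfParams(k=1))


class TestFullKernel:
    def test_rows_sum_to_one(self, rng):
        W = np.abs(rng.normal(size=(9, 9)))
        W = (W + W.T) / 2
        P = full_kernel(W)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(np.diag(P), 0.5)

    def test_two_by_two_hand_value(self):
        P = full_kernel(np.array([[1.0, 0.4], [0.4, 1.0]]))
        np.testing.assert_allclose(P, [[0.5, 0.5], [0.5, 0.5]])

    def test_commutes_with_permutation(self, rng):
        W = np.abs(rng.normal(size=(7, 7)))
        W = (W + W.T) / 2
        perm = rng.permutation(7)
        np.testing.assert_allclose(full_kernel(W[np.ix_(perm, perm)]),
                                   full_kernel(W)[np.ix_(perm, perm)])

    def test_zero_row_rejected(self):
        W = np.eye(3)
        with pytest.raises(ValueError, match="off-diagonal"):
            full_kernel(W)


class TestSparseKernel:
    def test_full_k_is_row_normalized_off_diagonal(self, rng):
        W = np.abs(rng.normal(size=(6, 6))) + 0.1
        W = (W + W.T) / 2
        S = sparse_kernel(W, k=5)
        assert np.diag(S).sum() == 0
        np.testing.assert_allclose(S.sum(axis=1), 1.0)
        off = W.copy()
        np.fill_diagonal(off, 0)
        np.testing.assert_allclose(S, off / off.sum(axis=1, keepdims=True))

    def test_k_one_is_one_hot_rows(self, rng):
        W = np.abs(rng.normal(size=(4, 4))) + 0.1
        W = (W + W.T) / 2
        S = sparse_kernel(W, k=1)
        assert ((S > 0).sum(axis=1) == 1).all()
        np.testing.assert_allclose(S.max(axis=1), 1.0)

    def test_rows_sum_to_one(self, rng):
        W = np.abs(rng.normal(size=(10, 10))) + 0.01
        W = (W + W.T) / 2
        np.testing.assert_allclose(sparse_kernel(W, 3).sum(axis=1), 1.0)


def _two_block_views(n=20, seed=0, flip=False):
    """Patients×features views with a planted 2-block structure."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n // 2)
    if flip:
        labels = labels[np.argsort(np.tile([0, 1], n // 2), kind="stable")]
    X = rng.normal(size=(n, 30)) + 3.0 * labels[:, None]
    return X, labels


class TestFuse:
    def test_identical_views_preserve_clustering(self):
        X, labels = _two_block_views()
        W = affinity(X, SnfParams(k=5))
        fused = fuse([W, W, W], SnfParams(k=5, T=10))
        single = spectral_cluster(W, 2, seed=0)
        merged = spectral_cluster(fused, 2, seed=0)
        assert nmi(single, merged) == 1.0
        assert nmi(merged, labels) == 1.0

    def test_orthogonal_views_refine_to_four_blocks(self):
        """Two views each carrying one of two orthogonal 2-block splits over
        the same 4 latent groups: the fused matrix exhibits the 4-block
        refinement (block-mean ordering) and fused clustering beats either
        single view, whose NMI against the 4-group truth is at most 0.5 by
        construction (it knows only one of the two cuts)."""
        rng = np.random.default_rng(3)
        groups = np.repeat([0, 1, 2, 3], 10)
        split_a = (groups // 2)[:, None]  # {0,1} vs {2,3}
        split_b = (groups % 2)[:, None]   # {0,2} vs {1,3}
        Xa = rng.normal(size=(40, 60)) + 3.0 * split_a
        Xb = rng.normal(size=(40, 60)) + 3.0 * split_b
        p = SnfParams(k=9, T=2)
        Wa, Wb = affinity(Xa, p), affinity(Xb, p)
        fused = fuse([Wa, Wb], p)

        def block_mean(S, mask):
            m = mask & ~np.eye(40, dtype=bool)
            return S[m].mean()

        same4 = groups[:, None] == groups[None, :]
        same_a = (groups[:, None] // 2) == (groups[None, :] // 2)
        same_b = (groups[:, None] % 2) == (groups[None, :] % 2)
        one_shared = (same_a | same_b) & ~same4
        none_shared = ~(same_a | same_b)
        assert block_mean(fused, same4) > block_mean(fused, one_shared)
        assert block_mean(fused, one_shared) > block_mean(fused, none_shared)

        fused_nmi = nmi(spectral_cluster(fused, 4, seed=0), groups)
        single_nmi = max(nmi(spectral_cluster(W, 4, seed=0), groups)
                         for W in (Wa, Wb))
        assert fused_nmi > single_nmi
        assert fused_nmi > 0.6

    def test_permutation_invariance(self, rng):
        X1 = rng.normal(size=(12, 6))
        X2 = rng.normal(size=(12, 8))
        p = SnfParams(k=4, T=5)
        W = [affinity(X1, p), affinity(X2, p)]
        fused = fuse(W, p)
        perm = rng.permutation(12)
        fused_p = fuse([w[np.ix_(perm, perm)] for w in W], p)
        np.testing.assert_allclose(fused_p, fused[np.ix_(perm, perm)], atol=1e-12)

    def test_output_symmetric_nonnegative(self, rng):
        W = [affinity(rng.normal(size=(10, 4)), SnfParams(k=3)) for _ in range(3)]
        fused = fuse(W, SnfParams(k=3, T=8))
        np.testing.assert_allclose(fused, fused.T)
        assert (fused >= 0).all()

    def test_mismatched_views_rejected(self, rng):
        p = SnfParams(k=2, T=2)
        with pytest.raises(ValueError, match="mismatched"):
            fuse([np.ones((4, 4)), np.ones((5, 5))], p)
        with pytest.raises(ValueError, match="two views"):
            fuse([np.ones((4, 4))], p)


class TestConvergence:
    def test_curve_length(self, rng):
        X = [rng.normal(size=(10, 5)) for _ in range(2)]
        p = SnfParams(k=3, T=3)
        W = [affinity(x, p) for x in X]
        curve = convergence_curve(W, [2, 3, 4, 5], "T", p)
        assert len(curve) == 3

    def test_t_sweep_decays_on_block_toy(self):
        X, _ = _two_block_views(n=24, seed=5)
        p = SnfParams(k=6)
        W = affinity(X, p)
        curve = convergence_curve([W, W], list(range(2, 21)), "T", p)
        # relative change falls below 1e-3 before T=15 and keeps shrinking
        idx_t15 = list(range(2, 21)).index(14)  # change from T=14 to T=15
        assert curve[idx_t15] < 1e-3
        assert curve[-1] < curve[0]

    def test_converged_region_change_is_tiny(self):
        X, _ = _two_block_views(n=16, seed=6)
        p = SnfParams(k=4)
        W = affinity(X, p)
        curve = convergence_curve([W, W], [40, 41], "T", p)
        assert curve[0] < 1e-5

    def test_identical_matrices_zero_change(self):
        A = np.eye(4) + 0.1
        assert relative_spectral_change(A, A.copy()) == 0.0

    def test_grid_validation(self, rng):
        W = [np.ones((4, 4))] * 2
        with pytest.raises(ValueError, match="two values"):
            convergence_curve(W, [5], "T")
        with pytest.raises(ValueError, match="ascending"):
            convergence_curve(W, [5, 3], "T")
        with pytest.raises(ValueError, match="which"):
            convergence_curve(W, [2, 3], "Q")


class TestEstimator:
    def test_fit_sets_attributes(self, rng):
        views = [rng.normal(size=(15, 6)), rng.normal(size=(15, 9))]
        model = SNF(k=4, alpha=0.5, n_iter=5).fit(views)
        assert model.fused_similarity_.shape == (15, 15)
        assert len(model.affinities_) == 2

    def test_get_set_params_roundtrip(self):
        model = SNF(k=7)
        assert model.get_params()["k"] == 7
        model.set_params(alpha=0.8)
        assert model.alpha == 0.8

    def test_patient_order_mismatch_rejected(self, small_cohort):
        import snfmark.preprocess as pp
        a, _ = pp.filter_features(small_cohort.layers["mrna"])
        b, _ = pp.filter_features(small_cohort.layers["mirna"])
        b = type(b)(b.layer, b.values.iloc[:, ::-1], None)
        with pytest.raises(ValueError, match="ordering"):
            SNF(k=5).fit([pp.minmax_normalize(a), pp.minmax_normalize(b)])
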