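"""Affinity kernels and cross-diffusion fusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fusemod as fm
from fusemod.snf import default_neighborhood


class TestDistances:
    def test_single_feature_pair(self):
        X = pd.DataFrame([[0.0], [3.0]], index=["a", "b"])
        D = fm.euclidean_distances(X)
        assert D.loc["a", "b"] == pytest.approx(3.0)
        assert np.allclose(np.diag(D), 0.0)

    def test_matches_brute_force_sum_of_squares(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"))
        D = fm.euclidean_distances(X)
        for i in range(5):
            for j in range(5):
                expected = np.sqrt(((X.iloc[i] - X.iloc[j]) ** 2).sum())
                assert D.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_non_finite_rejected(self):
        X = pd.DataFrame([[0.0], [np.nan]], index=["a", "b"])
        with pytest.raises(ValueError, match="non-finite"):
            fm.euclidean_distances(X)


class TestScaledAffinity:
    def test_hand_example_three_points_on_line(self, toy_distance):
        # patients at 0, 1, 5 with k=1: eps(a,b) = (1 + 1 + 1)/3 = 1,
        # so W(a,b) = exp(-1 / 0.5) = e^-2
        W = fm.scaled_affinity(toy_distance, mu=0.5, k=1)
        assert W.loc["a", "b"] == pytest.approx(np.exp(-2.0), abs=1e-6)
        assert np.allclose(np.diag(W), 1.0)

    def test_symmetric_on_random_input(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"p{i}" for i in range(8)])
        W = fm.scaled_affinity(fm.euclidean_distances(X), mu=0.7, k=3)
        assert np.allclose(W, W.T)
        assert (W.to_numpy() > 0).all()

    def test_k_out_of_range_rejected(self, toy_distance):
        with pytest.raises(ValueError, match="k must"):
            fm.scaled_affinity(toy_distance, mu=0.5, k=3)


class TestFullKernel:
    def test_diagonal_half_and_uniform_offdiag(self):
        W = pd.DataFrame(0.3 * np.ones((3, 3)) + 0.7 * np.eye(3), index=list("abc"), columns=list("abc"))
        P = fm.full_kernel(W)
        assert np.allclose(np.diag(P), 0.5)
        off = P.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.25)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=12))
    def test_rows_sum_to_one_property(self, seed, n):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0.01, 1.0, size=(n, n))
        W = pd.DataFrame((A + A.T) / 2)
        P = fm.full_kernel(W)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(np.diag(P), 0.5)

    def test_zero_offdiagonal_row_rejected(self):
        W = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="off-diagonal"):
            fm.full_kernel(W)


class TestLocalKernel:
    def test_k1_puts_all_mass_on_nearest(self, toy_distance):
        W = fm.scaled_affinity(toy_distance, mu=0.5, k=1)
        S = fm.local_kernel(toy_distance, W, k=1)
        # nearest of a is b, of b is a, of c is b
        assert S.loc["a", "b"] == 1.0 and S.loc["b", "a"] == 1.0 and S.loc["c", "b"] == 1.0
        assert S.to_numpy().sum() == pytest.approx(3.0)

    def test_matches_sort_and_normalize_oracle(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(6, 2)), index=[f"p{i}" for i in range(6)])
        D = fm.euclidean_distances(X)
        W = fm.scaled_affinity(D, mu=0.5, k=2)
        k = 3
        S = fm.local_kernel(D, W, k=k)
        for i in range(6):
            drow = D.iloc[i].to_numpy().copy()
            drow[i] = np.inf
            nn = np.argsort(drow, kind="stable")[:k]
            expected = np.zeros(6)
            expected[nn] = W.iloc[i].to_numpy()[nn]
            expected /= expected.sum()
            assert np.allclose(S.iloc[i].to_numpy(), expected, atol=1e-12)
            # non-neighbors are exactly zero, k nonzeros per row
            assert (S.iloc[i] != 0).sum() == k


class TestFusion:
    def _kernels(self, X, mu=0.5, k=None):
        if k is None:
            k = default_neighborhood(len(X))
        D = fm.euclidean_distances(X)
        W = fm.scaled_affinity(D, mu=mu, k=k)
        return fm.full_kernel(W), fm.local_kernel(D, W, k=k)

    def test_two_patient_output_shape_and_symmetry(self):
        rng = np.random.default_rng(0)
        views = [
            pd.DataFrame(rng.normal(size=(2, 3)), index=["a", "b"]) for _ in range(2)
        ]
        fused = fm.fuse_feature_views(views, k=1, iters=5)
        M = fused.matrix.to_numpy()
        assert M.shape == (2, 2)
        assert np.allclose(M, M.T) and (M >= 0).all()

    def test_single_view_rejected(self):
        X = pd.DataFrame(np.eye(3))
        P, S = self._kernels(X, k=1)
        with pytest.raises(ValueError, match=">= 2 views"):
            fm.snf_fuse([P], [S], T=2)

    @staticmethod
    def _block_contrast(M, labels):
        same = labels.to_numpy()[:, None] == labels.to_numpy()[None, :]
        np.fill_diagonal(same, False)
        diff = ~same
        np.fill_diagonal(diff, False)
        return M.to_numpy()[same].mean() / M.to_numpy()[diff].mean()

    def test_fusion_sharpens_block_structure(self):
        """Fused within/between contrast exceeds each single-view contrast."""
        wins = 0
        for seed in range(10):
            views, truth = fm.simulate_cohort(fm.CohortSpec(seed=seed))
            fused = fm.fuse_feature_views(views)
            fused_contrast = self._block_contrast(fused.matrix, truth.true_labels)
            single = []
            for X in views:
                P, _ = self._kernels(X)
                single.append(self._block_contrast(P, truth.true_labels))
            if fused_contrast > max(single) and fused_contrast > 1:
                wins += 1
        assert wins >= 8

    def test_identical_views_preserve_block_structure(self):
        views, truth = fm.simulate_cohort(fm.CohortSpec(seed=5))
        X = views[0]
        P, S = self._kernels(X)
        fused = fm.snf_fuse([P, P], [S, S], T=20)
        c_single = self._block_contrast(P, truth.true_labels)
        c_fused = self._block_contrast(fused.matrix, truth.true_labels)
        assert c_fused >= c_single * 0.95  # diffusion must not wash out the blocks

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        ids = [f"p{i}" for i in range(12)]
        views = [pd.DataFrame(rng.normal(size=(12, 6)), index=ids) for _ in range(2)]
        fused = fm.fuse_feature_views(views, k=3, iters=10)
        perm = rng.permutation(12)
        pviews = [v.iloc[perm] for v in views]
        pfused = fm.fuse_feature_views(pviews, k=3, iters=10)
        reordered = fused.matrix.iloc[perm, :].iloc[:, perm]
        assert np.allclose(pfused.matrix.to_numpy(), reordered.to_numpy(), atol=1e-10)

    def test_fusion_change_decays(self):
        """Relative change between successive fused averages shrinks."""
        views, _ = fm.simulate_cohort(fm.CohortSpec(seed=1))
        f5 = fm.fuse_feature_views(views, iters=5)
        f30 = fm.fuse_feature_views(views, iters=30)
        assert f30.max_rel_change < f5.max_rel_change
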