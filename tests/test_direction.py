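"""Unit tests for the characteristic-direction estimator and its pieces."""

import numpy as np
import pytest

from chardir import (
    DegenerateDataError,
    ExpressionMatrix,
    InputError,
    ShrinkageSpec,
    SmallClassWarning,
    TwoClassDesign,
    ZeroDirectionError,
    characteristic_direction,
    class_means,
    pooled_within_covariance,
    rank_genes,
    shrink_covariance,
)
from conftest import make_two_class


def dense_direction(X, design, gamma):
    """Independent dense-space oracle: normalize((g*S + (1-g)*s2*I)^-1 dmu)."""
    with np.errstate(all="raise"):
        mu_c, mu_p = class_means(X, design)
    dmu = mu_p - mu_c
    S = pooled_within_covariance(X, design).dense()
    s2 = S.diagonal().mean()
    M = gamma * S + (1.0 - gamma) * s2 * np.eye(X.n_genes)
    if gamma == 1.0:
        b = np.linalg.pinv(M, rcond=1e-12, hermitian=True) @ dmu
    else:
        b = np.linalg.solve(M, dmu)
    b = b / np.linalg.norm(b)
    return b if b @ dmu >= 0 else -b


class TestClassMeans:
    def test_duplicated_columns_give_the_column_back(self):
        col = np.arange(5.0)
        values = np.column_stack([col, col, col + 9, col + 11])
        X = ExpressionMatrix(values, [f"g{i}" for i in range(5)],
                             ["a", "b", "c", "d"])
        design = TwoClassDesign(["a", "b"], ["c", "d"])
        with pytest.warns(SmallClassWarning):
            mu_c, mu_p = class_means(X, design)
        np.testing.assert_array_equal(mu_c, col)
        np.testing.assert_array_equal(mu_p, col + 10)

    def test_matches_brute_force_per_gene_average(self):
        X, design = make_two_class(10, 3, 3, seed=5)
        mu_c, mu_p = class_means(X, design)
        # independent elementwise oracle
        expect_c = np.array([np.mean([X.values[i, j] for j in range(3)])
                             for i in range(10)])
        expect_p = np.array([np.mean([X.values[i, j] for j in range(3, 6)])
                             for i in range(10)])
        np.testing.assert_allclose(mu_c, expect_c, atol=1e-14)
        np.testing.assert_allclose(mu_p, expect_p, atol=1e-14)

    def test_unknown_sample_id_is_named_in_the_error(self, small_matrix):
        X, _ = small_matrix
        design = TwoClassDesign(["c0", "c1", "c2"], ["t0", "t1", "nope"])
        with pytest.raises(InputError, match="nope"):
            class_means(X, design)


class TestPooledCovariance:
    def test_constant_columns_give_zero_operator(self):
        values = np.tile(np.arange(4.0)[:, None], (1, 4))
        X = ExpressionMatrix(values, list("abcd"), ["s0", "s1", "s2", "s3"])
        design = TwoClassDesign(["s0", "s1"], ["s2", "s3"])
        with pytest.warns(SmallClassWarning):
            op = pooled_within_covariance(X, design)
        np.testing.assert_array_equal(op.dense(), np.zeros((4, 4)))
        np.testing.assert_array_equal(op.matvec(np.ones(4)), np.zeros(4))

    def test_hand_computed_pooled_variance_single_gene(self):
        # classes {0, 2} and {10, 12}: within-class SS = 2 + 2, dof = 2
        values = np.array([[0.0, 2.0, 10.0, 12.0], [1.0, 1.0, 1.0, 1.0]])
        X = ExpressionMatrix(values, ["g", "flat"], ["s0", "s1", "s2", "s3"])
        design = TwoClassDesign(["s0", "s1"], ["s2", "s3"])
        with pytest.warns(SmallClassWarning):
            op = pooled_within_covariance(X, design)
        assert op.dense()[0, 0] == pytest.approx(2.0)

    def test_agrees_with_dense_brute_force(self):
        X, design = make_two_class(12, 4, 5, seed=3)
        op = pooled_within_covariance(X, design)
        idx_c, idx_p = design.indices(X)
        Xc, Xp = X.values[:, idx_c], X.values[:, idx_p]
        expect = (
            (Xc - Xc.mean(1, keepdims=True)) @ (Xc - Xc.mean(1, keepdims=True)).T
            + (Xp - Xp.mean(1, keepdims=True)) @ (Xp - Xp.mean(1, keepdims=True)).T
        ) / (9 - 2)
        np.testing.assert_allclose(op.dense(), expect, atol=1e-12)
        v = np.random.default_rng(0).normal(size=12)
        np.testing.assert_allclose(op.matvec(v), expect @ v, atol=1e-12)


class TestShrinkage:
    def test_gamma_zero_is_scalar_identity(self, small_matrix):
        X, design = small_matrix
        op = pooled_within_covariance(X, design)
        shrunk = shrink_covariance(op, ShrinkageSpec(gamma=0.0))
        s2 = op.diagonal_mean()
        np.testing.assert_allclose(shrunk.dense(), s2 * np.eye(10), atol=1e-12)

    def test_gamma_one_is_identity_map_on_sigma_hat(self, small_matrix):
        X, design = small_matrix
        op = pooled_within_covariance(X, design)
        shrunk = shrink_covariance(op, ShrinkageSpec(gamma=1.0))
        np.testing.assert_allclose(shrunk.dense(), op.dense(), atol=1e-12)

    def test_gamma_half_halves_off_diagonals(self, small_matrix):
        X, design = small_matrix
        op = pooled_within_covariance(X, design)
        S = op.dense()
        s2 = S.diagonal().mean()
        half = shrink_covariance(op, 0.5).dense()
        off = ~np.eye(10, dtype=bool)
        np.testing.assert_allclose(half[off], S[off] / 2, atol=1e-12)
        np.testing.assert_allclose(np.diag(half), (np.diag(S) + s2) / 2,
                                   atol=1e-12)

    def test_zero_variance_with_shrinkage_is_degenerate(self):
        values = np.ones((3, 4))
        X = ExpressionMatrix(values, list("abc"), ["s0", "s1", "s2", "s3"])
        design = TwoClassDesign(["s0", "s1"], ["s2", "s3"])
        with pytest.warns(SmallClassWarning):
            op = pooled_within_covariance(X, design)
        with pytest.raises(DegenerateDataError):
            shrink_covariance(op, 0.5)


class TestCharacteristicDirection:
    def test_gamma_zero_closed_form_is_normalized_mean_difference(self):
        X, design = make_two_class(40, 4, 4, seed=11)
        b = characteristic_direction(X, design, 0.0)
        mu_c, mu_p = class_means(X, design)
        dmu = mu_p - mu_c
        cosine = b.components @ (dmu / np.linalg.norm(dmu))
        assert cosine >= 1 - 1e-12

    @pytest.mark.parametrize("gamma", [0.0, 0.25, 0.5, 1.0])
    def test_squared_components_sum_to_one(self, gamma):
        X, design = make_two_class(60, 5, 4, seed=int(gamma * 100))
        b = characteristic_direction(X, design, gamma)
        assert abs(b.squared.sum() - 1.0) < 1e-10
        np.testing.assert_array_equal(b.squared, b.components**2)
        assert 1 <= b.subspace_dim <= X.n_samples - 1

    @pytest.mark.parametrize("seed,gamma", [(0, 0.5), (1, 0.25), (2, 0.9)])
    def test_subspace_equals_dense_regularized_inverse(self, seed, gamma):
        X, design = make_two_class(50, 4, 4, seed=seed)
        b = characteristic_direction(X, design, gamma)
        expect = dense_direction(X, design, gamma)
        assert np.abs(b.components - expect).max() < 1e-8

    def test_subspace_equals_dense_pseudo_inverse_at_gamma_one(self):
        X, design = make_two_class(80, 5, 5, seed=21)
        b = characteristic_direction(X, design, 1.0)
        expect = dense_direction(X, design, 1.0)
        assert np.abs(b.components - expect).max() < 1e-6

    def test_sign_convention_points_towards_perturbed_class(self):
        shift = np.zeros(30)
        shift[0] = 4.0  # gene 0 strongly up in the perturbed class
        X, design = make_two_class(30, 4, 4, seed=2, shift=shift)
        b = characteristic_direction(X, design, 0.0)
        assert b.components[0] > 0

    def test_permutation_equivariance(self):
        X, design = make_two_class(25, 4, 4, seed=9)
        b = characteristic_direction(X, design, 0.5)
        perm = np.random.default_rng(1).permutation(25)
        Xp = ExpressionMatrix(X.values[perm],
                              [X.gene_ids[i] for i in perm], X.sample_ids)
        bp = characteristic_direction(Xp, design, 0.5)
        np.testing.assert_allclose(bp.components, b.components[perm],
                                   atol=1e-12)

    def test_scale_invariance_at_gamma_one(self):
        X, design = make_two_class(30, 4, 4, seed=13)
        b1 = characteristic_direction(X, design, 1.0)
        Xs = ExpressionMatrix(X.values * 37.0, X.gene_ids, X.sample_ids)
        b2 = characteristic_direction(Xs, design, 1.0)
        np.testing.assert_allclose(b2.components, b1.components, atol=1e-9)

    def test_zero_mean_difference_raises(self):
        values = np.random.default_rng(0).normal(size=(5, 4))
        values[:, 2:] = values[:, :2]  # perturbed duplicates control
        X = ExpressionMatrix(values, list("abcde"), ["s0", "s1", "s2", "s3"])
        design = TwoClassDesign(["s0", "s1"], ["s2", "s3"])
        with pytest.warns(SmallClassWarning):
            with pytest.raises(ZeroDirectionError):
                characteristic_direction(X, design)

    def test_small_class_emits_warning_not_error(self):
        X, design = make_two_class(10, 2, 4, seed=4)
        with pytest.warns(SmallClassWarning):
            characteristic_direction(X, design)


class TestRankGenes:
    def _direction(self, components, gene_ids):
        from chardir import DirectionResult

        return DirectionResult(gene_ids=gene_ids,
                               components=np.asarray(components),
                               gamma=1.0, subspace_dim=1)

    def test_sorts_by_descending_squared_with_scaled_ranks(self):
        sq = np.sqrt([0.7, 0.2, 0.1])
        ranked = rank_genes(self._direction(sq, ["gene1", "gene2", "gene3"]))
        assert ranked.gene_ids == ["gene1", "gene2", "gene3"]
        np.testing.assert_allclose(ranked.scaled_ranks, [0.0, 0.5, 1.0])
        assert ranked.scaled_ranks[0] == 0.0
        assert ranked.scaled_ranks[-1] == 1.0

    def test_ties_break_lexicographically_and_deterministically(self):
        comp = np.array([0.5, -0.5, 0.5, 0.5])
        first = rank_genes(self._direction(comp, ["zz", "aa", "mm", "bb"]))
        for _ in range(3):
            again = rank_genes(self._direction(comp, ["zz", "aa", "mm", "bb"]))
            assert again.gene_ids == first.gene_ids
        assert first.gene_ids == ["aa", "bb", "mm", "zz"]
        assert first.signs.tolist() == [-1, 1, 1, 1]

    def test_least_significant_gene_has_scaled_rank_one(self, medium_matrix):
        X, design = medium_matrix
        ranked = rank_genes(characteristic_direction(X, design))
        assert ranked.scaled_ranks[-1] == 1.0
        assert np.all(np.diff(ranked.squared) <= 0)
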