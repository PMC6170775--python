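"""Phylogenetic comparative statistics: Brownian covariance, Kmult,
PGLS, two-block and phylogenetic PLS, ancestral projection."""

import numpy as np
import pytest

from taloco.io import read_tree
from taloco.phylo import (
    inv_sqrt_psd,
    kmult,
    pgls,
    phylo_cov,
    phylo_pls,
    phylomorphospace,
    two_block_pls,
)
from taloco.synthetic import simulate_tree


def star_tree(n=8, bl=1.0):
    labels = [f"t{i}" for i in range(n)]
    newick = "(" + ",".join(f"{x}:{bl}" for x in labels) + ");"
    return read_tree(newick), labels


def bm_tips(c, q, rng):
    """Simulate Brownian tip data with covariance c per trait."""
    chol = np.linalg.cholesky(c)
    return chol @ rng.normal(size=(c.shape[0], q))


class TestPhyloCov:
    def test_star_tree_is_identity(self):
        tree, labels = star_tree(5)
        assert np.allclose(phylo_cov(tree, labels), np.eye(5))

    def test_nested_example_by_hand(self):
        tree = read_tree("((A:1,B:1):1,C:2);")
        c = phylo_cov(tree, ["A", "B", "C"])
        assert c[0, 0] == pytest.approx(2.0)
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(0.0)
        assert np.allclose(c, c.T)

    def test_positive_semidefinite_on_random_trees(self):
        for seed in range(15):
            tree = simulate_tree(10, seed)
            labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
            c = phylo_cov(tree, labels)
            assert np.linalg.eigvalsh(c).min() > -1e-10

    def test_missing_tip_is_error(self):
        tree, labels = star_tree(4)
        with pytest.raises(ValueError):
            phylo_cov(tree, labels + ["absent"])

    def test_inv_sqrt_roundtrip(self):
        tree = simulate_tree(8, 3)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        c = phylo_cov(tree, labels)
        u = inv_sqrt_psd(c)
        assert np.allclose(u @ c @ u, np.eye(8), atol=1e-8)


def univariate_blomberg_k(y, c):
    """Independently coded univariate Blomberg K oracle."""
    n = y.size
    cinv = np.linalg.inv(c)
    ones = np.ones(n)
    a = (ones @ cinv @ y) / (ones @ cinv @ ones)
    r = y - a
    mse0 = r @ r
    mse = r @ cinv @ r
    expected = (np.trace(c) - n / cinv.sum()) / (n - 1)
    return (mse0 / mse) / expected


class TestKmult:
    def test_matches_univariate_oracle_for_one_trait(self, rng):
        tree = simulate_tree(12, 5)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        c = phylo_cov(tree, labels)
        y = bm_tips(c, 1, rng)
        res = kmult(y, tree, labels, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(
            univariate_blomberg_k(y[:, 0], c), rel=1e-10
        )

    def test_brownian_mean_near_one(self, rng):
        tree = simulate_tree(20, 9)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        c = phylo_cov(tree, labels)
        ks = []
        for _ in range(100):
            res = kmult(bm_tips(c, 3, rng), tree, labels, n_perm=0, seed=0)
            ks.append(res.statistic)
        assert 0.85 <= np.mean(ks) <= 1.15

    def test_invariance_to_trait_and_branch_scaling(self, rng):
        tree = simulate_tree(10, 2)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        y = bm_tips(phylo_cov(tree, labels), 2, rng)
        k1 = kmult(y, tree, labels, n_perm=0).statistic
        k2 = kmult(7.3 * y, tree, labels, n_perm=0).statistic
        scaled = simulate_tree(10, 2)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length *= 11.0
        k3 = kmult(y, scaled, labels, n_perm=0).statistic
        assert k1 == pytest.approx(k2, rel=1e-10)
        assert k1 == pytest.approx(k3, rel=1e-10)

    def test_constant_traits_flagged(self):
        tree = simulate_tree(6, 1)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        with pytest.warns(UserWarning):
            res = kmult(np.ones((6, 2)), tree, labels, n_perm=9, seed=0)
        assert np.isnan(res.statistic)

    def test_permutation_p_reproducible_and_bounded(self, rng):
        tree = simulate_tree(10, 4)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        y = bm_tips(phylo_cov(tree, labels), 2, rng)
        a = kmult(y, tree, labels, n_perm=99, seed=11)
        b = kmult(y, tree, labels, n_perm=99, seed=11)
        assert a.p_value == b.p_value
        assert a.p_value >= 1 / 100


class TestPgls:
    def test_perfect_linear_relation(self, rng):
        tree = simulate_tree(10, 4)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        x = rng.normal(size=10)
        res = pgls(2.0 * x, x, tree, labels, n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_star_tree_reduces_to_ols(self, rng):
        tree, labels = star_tree(12)
        x = rng.normal(size=(12, 2))
        y = rng.normal(size=(12, 3))
        res = pgls(y, x, tree, labels, n_perm=9, seed=0)
        design = np.column_stack([np.ones(12), x])
        beta_ols, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert np.allclose(res.coefficients, beta_ols, atol=1e-8)

    def test_rank_deficient_design_rejected(self, rng):
        tree, labels = star_tree(8)
        x = np.ones((8, 1))  # collinear with the intercept
        with pytest.raises(ValueError):
            pgls(rng.normal(size=8), x, tree, labels, n_perm=9)


class TestTwoBlockPls:
    def test_identical_blocks_give_r_one(self, rng):
        a = rng.normal(size=(10, 4))
        res = two_block_pls(a, a.copy(), n_perm=9, seed=0)
        assert res.r_pls == pytest.approx(1.0, abs=1e-9)

    def test_singular_values_match_hand_svd(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        b = np.array([[2.0, 0.0], [0.0, 1.0], [-2.0, 0.0], [0.0, -1.0]])
        res = two_block_pls(a, b, n_perm=9, seed=0)
        # cross-covariance diag(4/3, 2/3) -> singular values 4/3, 2/3
        assert res.singular_values == pytest.approx([4.0 / 3.0, 2.0 / 3.0])

    def test_zero_variance_block_rejected(self, rng):
        with pytest.raises(ValueError):
            two_block_pls(np.ones((6, 2)), rng.normal(size=(6, 2)), n_perm=9)


class TestPhyloPls:
    def test_star_tree_equals_standard_pls(self, rng):
        tree, labels = star_tree(10)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 4))
        std = two_block_pls(a, b, n_perm=99, seed=5)
        phy = phylo_pls(a, b, tree, labels, n_perm=99, seed=5)
        assert phy.r_pls == pytest.approx(std.r_pls, abs=1e-8)
        assert np.allclose(phy.singular_values, std.singular_values, atol=1e-8)

    def test_identical_blocks_give_r_one(self, rng):
        tree = simulate_tree(8, 6)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        a = bm_tips(phylo_cov(tree, labels), 3, rng)
        res = phylo_pls(a, a.copy(), tree, labels, n_perm=9, seed=0)
        assert res.r_pls == pytest.approx(1.0, abs=1e-9)


class TestPhylomorphospace:
    def test_two_tip_root_at_weighted_midpoint(self):
        tree = read_tree("(A:1,B:3);")
        nodes = phylomorphospace(tree, ["A", "B"], np.array([[0.0, 0.0], [4.0, 8.0]]))
        # inverse-branch-length weights: (1/1*0 + 1/3*4)/(1/1+1/3) = 1
        root = nodes["node0"]
        assert root == pytest.approx([1.0, 2.0])

    def test_star_tree_root_at_mean(self, rng):
        tree, labels = star_tree(6)
        scores = rng.normal(size=(6, 2))
        nodes = phylomorphospace(tree, labels, scores)
        assert nodes["node0"] == pytest.approx(scores.mean(axis=0))

    def test_identical_tip_scores_collapse(self):
        tree = simulate_tree(7, 2)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        scores = np.tile([1.5, -2.0], (7, 1))
        nodes = phylomorphospace(tree, labels, scores)
        for xy in nodes.values():
            assert xy == pytest.approx([1.5, -2.0])
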