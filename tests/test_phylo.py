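"""Phylogenetic comparative statistics: covariance, signal, ASR, PGLS, shifts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cladespec import phylo, synthetic
from cladespec.phylo import ArrayTree

from conftest import random_tree, tree_from_newick


class TestBmCovariance:
    def test_star_tree_unit_branches_is_identity(self, star_tree):
        _, C = phylo.bm_covariance(star_tree)
        np.testing.assert_allclose(C, np.eye(5))

    def test_three_tip_worked_example(self, three_tip_tree):
        labels, C = phylo.bm_covariance(three_tip_tree)
        M = pd.DataFrame(C, index=labels, columns=labels)
        assert M.loc["A", "B"] == 1.0
        assert M.loc["A", "C"] == 0.0
        assert M.loc["A", "A"] == 2.0
        assert M.loc["C", "C"] == 2.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_trees_match_shared_path_oracle(self, seed):
        tree = random_tree(11, seed=seed + 50)
        labels, C = phylo.bm_covariance(tree)
        # oracle: intersect root-to-tip edge paths and sum branch lengths
        paths = {}
        for leaf in tree.leaf_node_iter():
            edges = []
            nd = leaf
            while nd.parent_node is not None:
                edges.append((id(nd), float(nd.edge.length)))
                nd = nd.parent_node
            paths[leaf.taxon.label] = edges
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                ia = {e for e, _ in paths[a]}
                expect = sum(l for e, l in paths[b] if e in ia)
                assert C[i, j] == pytest.approx(expect, rel=1e-12)


def _fixture_12tip():
    """Deterministic 12-tip clade + BM trait, cross-checked against R phytools."""
    rng = np.random.default_rng(7)
    tree = synthetic.simulate_yule_tree(12, rng)
    trait = synthetic.simulate_trait(tree, rng, sigma2=2.0, root_state=5.0)
    return tree, trait


class TestBlombergK:
    def test_matches_phytools_on_fixture(self):
        # frozen from R: phytools::phylosig(tr, x, method="K") -> 1.66262
        tree, trait = _fixture_12tip()
        res = phylo.blomberg_k(tree, trait, n_perm=199, seed=0)
        assert res.estimate == pytest.approx(1.66262, abs=1e-4)

    def test_shuffled_trait_loses_signal(self):
        tree, trait = _fixture_12tip()
        rng = np.random.default_rng(3)
        shuffled = pd.Series(rng.permutation(trait.to_numpy()), index=trait.index)
        k_orig = phylo.blomberg_k(tree, trait, n_perm=0, seed=0).estimate
        ks = []
        for i in range(30):
            s = pd.Series(np.random.default_rng(i).permutation(trait.to_numpy()), index=trait.index)
            ks.append(phylo.blomberg_k(tree, s, n_perm=0, seed=0).estimate)
        assert np.mean(ks) < k_orig

    def test_constant_trait_rejected(self, star_tree):
        trait = pd.Series(1.0, index=[l.taxon.label for l in star_tree.leaf_node_iter()])
        with pytest.raises(ValueError, match="constant"):
            phylo.blomberg_k(star_tree, trait)

    def test_permutation_p_uniform_under_null(self):
        # shuffled (exchangeable) traits: p-values should be uniform
        tree = random_tree(10, seed=77)
        rng = np.random.default_rng(5)
        ps = []
        for i in range(400):
            trait = pd.Series(
                rng.normal(size=10), index=[l.taxon.label for l in tree.leaf_node_iter()]
            )
            ps.append(phylo.blomberg_k(tree, trait, n_perm=99, seed=i).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.005


class TestPagelLambda:
    def test_matches_phytools_on_fixture(self):
        # frozen from R: phytools::phylosig(tr, x, method="lambda")
        #   -> lambda 1.00944, logL -14.4695
        tree, trait = _fixture_12tip()
        res = phylo.pagel_lambda(tree, trait)
        assert res.estimate == pytest.approx(1.00944, abs=2e-3)
        assert res.details["loglik"] == pytest.approx(-14.4695, abs=2e-3)

    def test_definitional_endpoints(self, three_tip_tree):
        _, C = phylo.bm_covariance(three_tip_tree)
        np.testing.assert_allclose(phylo._lambda_V(C, 1.0), C)
        np.testing.assert_allclose(phylo._lambda_V(C, 0.0), np.diag(np.diag(C)))

    def test_optimum_beats_endpoints(self):
        tree = random_tree(30, seed=9)
        trait = synthetic.simulate_trait(tree, np.random.default_rng(4), sigma2=1.0)
        res = phylo.pagel_lambda(tree, trait)
        _, C = phylo.bm_covariance(tree)
        x = ArrayTree(tree).align(trait)
        for lam in (0.0, 1.0):
            ll, _, _ = phylo._lambda_profile_loglik(C, x, lam)
            assert res.details["loglik"] >= ll - 1e-8

    def test_star_like_trait_estimates_near_zero(self):
        tree = random_tree(40, seed=10)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        trait = pd.Series(np.random.default_rng(11).normal(size=40), index=labels)
        res = phylo.pagel_lambda(tree, trait)
        assert res.estimate < 0.3
        assert res.p > 0.001  # no real signal to declare


class TestAsr:
    def test_two_tip_equal_branches_root_is_mean(self):
        tree = tree_from_newick("(A:1,B:1);")
        res = phylo.asr_bm(tree, pd.Series({"A": 10.0, "B": 20.0}))
        assert res.mu == pytest.approx(15.0)

    def test_two_tip_inverse_variance_weighting(self):
        tree = tree_from_newick("(A:1,B:3);")
        res = phylo.asr_bm(tree, pd.Series({"A": 0.0, "B": 4.0}))
        assert res.mu == pytest.approx((0 / 1 + 4 / 3) / (1 / 1 + 1 / 3))

    def test_constant_tips_reconstruct_constant_with_zero_variance(self):
        tree = random_tree(12, seed=13)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        res = phylo.asr_bm(tree, pd.Series(7.5, index=labels))
        np.testing.assert_allclose(res.table["estimate"], 7.5)
        np.testing.assert_allclose(res.table["variance"], 0.0, atol=1e-12)

    def test_shift_and_scale_equivariance(self):
        tree = random_tree(15, seed=14)
        trait = synthetic.simulate_trait(tree, np.random.default_rng(15), sigma2=1.0)
        base = phylo.asr_bm(tree, trait)
        shifted = phylo.asr_bm(tree, trait + 11.0)
        scaled = phylo.asr_bm(tree, trait * 3.0)
        np.testing.assert_allclose(shifted.table["estimate"], base.table["estimate"] + 11.0)
        np.testing.assert_allclose(scaled.table["estimate"], base.table["estimate"] * 3.0)

    def test_root_matches_phytools_ml_on_fixture(self):
        # frozen from R: phytools::anc.ML root state 3.45977
        tree, trait = _fixture_12tip()
        res = phylo.asr_bm(tree, trait)
        assert res.mu == pytest.approx(3.45977, abs=1e-4)


class TestPgls:
    def _data(self, n=25, seed=16):
        tree = random_tree(n, seed=seed)
        rng = np.random.default_rng(seed + 1)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        x = pd.Series(rng.normal(size=n), index=labels, name="x")
        resid = synthetic.simulate_trait(tree, rng, sigma2=1.0)
        y = pd.Series(1.5 + 2.0 * x + resid, name="y")
        return tree, y, x

    def test_identity_correlation_reproduces_ols(self):
        tree, y, x = self._data()
        res = phylo.pgls(tree, y, x, correlation="identity")
        # plain normal equations on the same case order
        labels = ArrayTree(tree).tip_labels
        X = np.column_stack([np.ones(len(labels)), x.loc[labels]])
        beta = np.linalg.solve(X.T @ X, X.T @ y.loc[labels])
        np.testing.assert_allclose(res.params.to_numpy(), beta, rtol=1e-9)

    def test_lambda_zero_on_ultrametric_tree_is_ols(self):
        tree, y, x = self._data()
        res = phylo.pgls(tree, y, x, correlation="lambda", fixed_lambda=0.0)
        ref = phylo.pgls(tree, y, x, correlation="identity")
        np.testing.assert_allclose(res.params.to_numpy(), ref.params.to_numpy(), rtol=1e-8)
        np.testing.assert_allclose(res.pvalues.to_numpy(), ref.pvalues.to_numpy(), rtol=1e-6)

    def test_three_tip_closed_form_gls(self, three_tip_tree):
        y = pd.Series({"A": 1.0, "B": 2.0, "C": 4.0}, name="y")
        x = pd.Series({"A": 0.0, "B": 1.0, "C": 2.0}, name="x")
        # the public pgls() pre-check needs k+3 cases; exercise the GLS core
        labels, C = phylo.bm_covariance(three_tip_tree)
        X = np.column_stack([np.ones(3), x.loc[labels]])
        Vinv = np.linalg.inv(C)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y.loc[labels])
        b, _, _, _ = phylo._gls(y.loc[labels].to_numpy(), X, C)
        np.testing.assert_allclose(b, beta, rtol=1e-10)

    def test_slope_recovered_with_bm_residuals(self):
        tree, y, x = self._data(n=60, seed=20)
        res = phylo.pgls(tree, y, x, correlation="lambda")
        assert res.params["x"] == pytest.approx(2.0, abs=0.5)
        assert res.pvalues["x"] < 1e-6
        assert 0.0 <= res.lambda_ <= res.params.size + 10  # sane bound
        assert "lambda" in res.summary()


class TestShiftScan:
    def test_pure_bm_keeps_zero_shifts(self, yule50):
        trait = synthetic.simulate_trait(yule50, np.random.default_rng(21), sigma2=1.0)
        res = phylo.shift_scan(yule50, trait, max_shifts=3)
        assert res.selected.n_shifts == 0
        assert res.models[0].criterion_name == "mbic"

    def test_planted_shift_recovered(self, yule50):
        at = ArrayTree(yule50)
        sizes = {
            i: int(np.sum(at.is_tip[at.descendants[i]]))
            for i in range(1, len(at.nodes))
        }
        edge = next(i for i, s in sizes.items() if 8 <= s <= 15 and not at.is_tip[i])
        clade = set(at.clade_tips(edge))
        trait = synthetic.simulate_trait(yule50, np.random.default_rng(22), sigma2=1.0)
        trait = trait + trait.index.isin(clade) * 6.0
        res = phylo.shift_scan(at, trait, max_shifts=3)
        neighbors = {edge, int(at.parent[edge])} | set(at.children[edge]) | set(
            at.children[at.parent[edge]]
        )
        assert res.selected.n_shifts >= 1
        assert res.selected.shift_edges[0] in neighbors
        # the shifted regime's optimum exceeds the base optimum
        assert res.selected.optima[1] > res.selected.optima[0]

    def test_too_few_tips_rejected(self, three_tip_tree):
        trait = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0})
        with pytest.raises(ValueError, match="8 tips"):
            phylo.shift_scan(three_tip_tree, trait)
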