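"""Phylogenetic signal, disparity, rate comparison, and model selection."""

import numpy as np
import pytest

from opershape.comparative_stats import (compare_evolutionary_rates,
                                         disparity_test,
                                         fit_evolutionary_models, kmult,
                                         procrustes_variance)
from opershape.phylo import TimeTree, bm_simulate
from opershape.synthetic_data import simulate_tree


def blomberg_k_oracle(tree, y):
    """Direct-formula univariate Blomberg K, coded independently."""
    n = len(y)
    C = tree.vcv()
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a = float(ones @ Cinv @ y) / float(ones @ Cinv @ ones)
    mse0 = float((y - a) @ (y - a)) / (n - 1)
    mse = float((y - a) @ Cinv @ (y - a)) / (n - 1)
    expected = (np.trace(C) - n / float(ones @ Cinv @ ones)) / (n - 1)
    return (mse0 / mse) / expected


class TestKmult:
    def test_univariate_equals_blomberg_oracle(self, rng):
        tree = simulate_tree(24, 0.1, seed=8)
        y = bm_simulate(tree, 1.0, [0.0], n_sims=1, seed=4)[0][:, 0]
        res = kmult(y, tree, n_perm=10, seed=0)
        assert res.K == pytest.approx(blomberg_k_oracle(tree, y), abs=1e-8)

    def test_duplicate_taxa_rejected(self, balanced4_tree):
        with pytest.raises(ValueError, match="duplicate"):
            kmult(np.zeros((4, 2)), balanced4_tree, taxa=["A", "A", "B", "C"])

    def test_taxon_mismatch_rejected(self, balanced4_tree):
        with pytest.raises(ValueError, match="mismatch"):
            kmult(np.zeros((4, 2)), balanced4_tree, taxa=["A", "B", "C", "X"])

    def test_p_value_in_open_unit_interval(self, rng):
        tree = simulate_tree(16, 0.1, seed=9)
        y = rng.normal(size=(16, 3))
        res = kmult(y, tree, n_perm=99, seed=5)
        assert 0 < res.p <= 1


class TestProcrustesVariance:
    def test_identical_shapes_zero(self):
        X = np.tile(np.arange(8.0), (5, 1))
        assert procrustes_variance(X) == 0.0

    def test_two_point_group(self):
        # two shapes symmetric about their mean, separated by distance d:
        # each sits d/2 from the mean, so the divisor-n variance is d^2/4
        base = np.zeros((1, 6))
        offset = np.array([[0.3, 0, 0.4, 0, 0, 0]])  # |offset| = d = 0.5
        X = np.vstack([base + offset / 2, base - offset / 2])
        d = 0.5
        assert procrustes_variance(X) == pytest.approx(d**2 / 4, rel=1e-12)

    def test_matches_double_loop_recomputation(self, rng):
        X = rng.normal(size=(9, 12))
        mean = X.mean(axis=0)
        direct = np.mean([np.sum((x - mean) ** 2) for x in X])
        assert procrustes_variance(X) == pytest.approx(direct, rel=1e-12)

    def test_invariant_to_member_order(self, rng):
        X = rng.normal(size=(7, 10))
        perm = rng.permutation(7)
        assert procrustes_variance(X) == pytest.approx(
            procrustes_variance(X[perm]), rel=1e-12
        )


class TestDisparityTest:
    def test_small_group_rejected(self, rng):
        X = rng.normal(size=(4, 6))
        groups = {"t0": "a", "t1": "a", "t2": "a", "t3": "b"}
        with pytest.raises(ValueError, match="fewer than 2"):
            disparity_test(X, groups, taxa=[f"t{i}" for i in range(4)])

    def test_inflated_group_detected(self, rng):
        n = 30
        a = rng.normal(size=(n, 10))
        b = 3.0 * rng.normal(size=(n, 10))
        X = np.vstack([a, b])
        taxa = [f"t{i}" for i in range(2 * n)]
        groups = {t: ("a" if i < n else "b") for i, t in enumerate(taxa)}
        res = disparity_test(X, groups, n_perm=999, seed=1, taxa=taxa)
        assert res.p <= 0.01
        assert res.fold_difference > 1


class TestRateComparison:
    def test_fourfold_contrast_recovered_once(self):
        tree = simulate_tree(64, 0.05, seed=12)
        half = tree.n_tips // 2
        groups = {t: ("fast" if i < half else "slow")
                  for i, t in enumerate(tree.tip_labels)}
        rng = np.random.default_rng(3)
        C = tree.vcv()
        chol = np.linalg.cholesky(C)
        scale = np.where([groups[t] == "fast" for t in tree.tip_labels], 2.0, 1.0)
        Y = (chol @ rng.standard_normal((tree.n_tips, 2))) * scale[:, None]
        res = compare_evolutionary_rates(tree, Y, groups, n_sims=199, seed=7)
        assert res.rates["fast"] > res.rates["slow"]
        assert res.p <= 0.05

    def test_single_tip_group_rejected(self, balanced4_tree):
        groups = {"A": "x", "B": "y", "C": "y", "D": "y"}
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_evolutionary_rates(balanced4_tree, np.zeros((4, 2)), groups)


class TestModelSelection:
    @pytest.fixture
    def tree64(self):
        return simulate_tree(64, 0.05, seed=21)

    def test_star_tree_bm_equals_wn(self, rng):
        star = TimeTree.from_newick("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);")
        y = dict(zip("ABCDEFGH", rng.normal(size=8)))
        table = fit_evolutionary_models(star, {k: [v] for k, v in y.items()})
        assert table.fits["BM"].log_likelihood == pytest.approx(
            table.fits["WN"].log_likelihood, abs=1e-6
        )

    def test_eb_nests_bm(self, tree64):
        y = bm_simulate(tree64, 1.0, [0.0], n_sims=1, seed=1)[0][:, 0]
        table = fit_evolutionary_models(tree64, y)
        # on BM data the EB optimum collapses to r = 0, recovering BM exactly
        assert table.fits["EB"].log_likelihood >= (
            table.fits["BM"].log_likelihood - 1e-8
        )
        if table.fits["EB"].params["r"] == 0.0:
            assert table.fits["EB"].log_likelihood == pytest.approx(
                table.fits["BM"].log_likelihood, abs=1e-8
            )

    def test_bm_sigma2_matches_gls_closed_form(self, tree64):
        y = bm_simulate(tree64, 2.5, [1.0], n_sims=1, seed=2)[0][:, 0]
        table = fit_evolutionary_models(tree64, y)
        C = tree64.vcv()
        Cinv = np.linalg.inv(C)
        ones = np.ones(len(y))
        z0 = float(ones @ Cinv @ y) / float(ones @ Cinv @ ones)
        sigma2 = float((y - z0) @ Cinv @ (y - z0)) / len(y)
        assert table.fits["BM"].params["sigma2"] == pytest.approx(sigma2, abs=1e-8)
        assert table.fits["BM"].params["z0"] == pytest.approx(z0, abs=1e-8)

    def test_branch_doubling_halves_sigma2(self, tree64):
        y = bm_simulate(tree64, 1.0, [0.0], n_sims=1, seed=3)[0][:, 0]
        t1 = fit_evolutionary_models(tree64, y)
        doubled = TimeTree(tree64.parent, tree64.blen * 2, tree64.labels,
                           tree64.is_tip)
        t2 = fit_evolutionary_models(doubled, y)
        assert t2.fits["BM"].params["sigma2"] == pytest.approx(
            t1.fits["BM"].params["sigma2"] / 2, rel=1e-8
        )
        assert t2.fits["BM"].log_likelihood == pytest.approx(
            t1.fits["BM"].log_likelihood, abs=1e-8
        )

    def test_shift_invariance_of_ranking(self, tree64):
        y = bm_simulate(tree64, 1.0, [0.0], n_sims=1, seed=4)[0][:, 0]
        t1 = fit_evolutionary_models(tree64, y)
        t2 = fit_evolutionary_models(tree64, y + 42.0)
        for m in t1.fits:
            assert t1.fits[m].daicc == pytest.approx(t2.fits[m].daicc, abs=1e-6)

    def test_ou_approaches_bm_for_weak_selection(self, tree64):
        # on BM-generated data the OU fit cannot beat BM by much, and the
        # best dAICc is zero by construction
        y = bm_simulate(tree64, 1.0, [0.0], n_sims=1, seed=5)[0][:, 0]
        table = fit_evolutionary_models(tree64, y)
        assert table.fits["OU"].log_likelihood >= (
            table.fits["BM"].log_likelihood - 1e-6
        )
        assert min(f.daicc for f in table.fits.values()) == 0.0

    def test_non_ultrametric_ou_rejected(self, rng):
        tree = TimeTree.from_newick("((A:1,B:2):1,(C:4,(D:1,E:2):1):0.5);")
        trait = {t: [float(rng.normal())] for t in "ABCDE"}
        with pytest.raises(ValueError, match="ultrametric"):
            fit_evolutionary_models(tree, trait, models=("OU",))
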