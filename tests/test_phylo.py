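"""Tree handling, squared-change parsimony, and BM simulation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from opershape.phylo import (TimeTree, ancestral_scp, bm_simulate,
                             phylomorphospace, prune_to, read_newick)
from opershape.synthetic_data import simulate_tree


class TestTreeIO:
    def test_read_write_round_trip(self, tmp_path, balanced4_tree):
        path = tmp_path / "t.nwk"
        balanced4_tree.write(path)
        back = read_newick(path)
        assert sorted(back.tip_labels) == ["A", "B", "C", "D"]
        np.testing.assert_allclose(
            back.vcv(["A", "B", "C", "D"]),
            balanced4_tree.vcv(["A", "B", "C", "D"]),
        )

    def test_prune_to_all_is_identity(self, balanced4_tree):
        pruned = prune_to(balanced4_tree, ["A", "B", "C", "D"])
        np.testing.assert_allclose(
            pruned.vcv(["A", "B", "C", "D"]),
            balanced4_tree.vcv(["A", "B", "C", "D"]),
            atol=1e-12,
        )

    def test_prune_collapses_and_conserves_path_lengths(self, balanced4_tree):
        pruned = prune_to(balanced4_tree, ["A", "C"])
        assert pruned.n_tips == 2
        depths = pruned.depths()[pruned.tip_indices]
        np.testing.assert_allclose(depths, [2.0, 2.0], atol=1e-12)
        # A and C share only the root
        assert pruned.vcv(["A", "C"])[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_prune_random_tree_preserves_depths(self, rng):
        tree = simulate_tree(20, 0.05, seed=11)
        depths = dict(zip(tree.tip_labels, tree.depths()[tree.tip_indices]))
        keep = list(rng.choice(tree.tip_labels, size=8, replace=False))
        pruned = prune_to(tree, keep)
        pdepths = dict(zip(pruned.tip_labels, pruned.depths()[pruned.tip_indices]))
        for t in keep:
            assert pdepths[t] == pytest.approx(depths[t], abs=1e-10)

    def test_missing_taxa_listed(self, balanced4_tree):
        with pytest.raises(KeyError, match="X"):
            prune_to(balanced4_tree, ["A", "X"])


class TestVcv:
    def test_symmetric_psd_with_depth_diagonal(self):
        tree = simulate_tree(12, 0.1, seed=3)
        C = tree.vcv()
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-10
        np.testing.assert_allclose(np.diag(C),
                                   tree.depths()[tree.tip_indices])


class TestAncestralScp:
    def test_constant_tips_give_constant_ancestors(self, balanced4_tree):
        anc = ancestral_scp(balanced4_tree, {t: [3.5] for t in "ABCD"})
        np.testing.assert_allclose(anc.values, 3.5, atol=1e-12)

    def test_two_tip_closed_form(self):
        tree = TimeTree.from_newick("(A:2.0,B:0.5);")
        v1, v2, b1, b2 = 1.0, 4.0, 2.0, 0.5
        anc = ancestral_scp(tree, {"A": [v1], "B": [v2]})
        expected = (v1 / b1 + v2 / b2) / (1 / b1 + 1 / b2)
        assert anc.values[0, 0] == pytest.approx(expected, abs=1e-10)
        # numeric 1-D check of the same minimum
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda x: (x - v1) ** 2 / b1 + (x - v2) ** 2 / b2
        )
        assert anc.values[0, 0] == pytest.approx(res.x, abs=1e-6)

    def test_five_tip_solution_is_global_minimum(self, rng):
        tree = TimeTree.from_newick(
            "((A:1.2,B:0.7):0.5,(C:0.9,(D:0.4,E:0.6):0.3):0.8);"
        )
        tips = {t: [float(rng.normal())] for t in "ABCDE"}
        anc = ancestral_scp(tree, tips)

        blen = tree.blen
        tipvals = np.zeros(tree.n_nodes)
        for t, v in tips.items():
            tipvals[tree.tip_index(t)] = v[0]

        def objective(internal_vals):
            vals = tipvals.copy()
            vals[anc.node_indices] = internal_vals
            return sum(
                (vals[i] - vals[tree.parent[i]]) ** 2 / blen[i]
                for i in range(1, tree.n_nodes)
            )

        obj_at_solution = objective(anc.values[:, 0])
        for _ in range(10_000):
            rand = rng.normal(scale=2.0, size=len(anc.node_indices))
            assert objective(rand) >= obj_at_solution - 1e-12
        grad = minimize(objective, anc.values[:, 0]).x  # refined optimum
        assert objective(anc.values[:, 0]) == pytest.approx(
            objective(grad), abs=1e-10
        )
        # gradient norm at the solution
        eps = 1e-6
        g = np.array([
            (objective(anc.values[:, 0] + eps * e) -
             objective(anc.values[:, 0] - eps * e)) / (2 * eps)
            for e in np.eye(len(anc.node_indices))
        ])
        assert np.linalg.norm(g) < 1e-6

    def test_linearity_in_tip_values(self, rng):
        tree = simulate_tree(10, 0.1, seed=5)
        x = rng.normal(size=(10, 1))
        y = rng.normal(size=(10, 1))
        ax = ancestral_scp(tree, x).values
        ay = ancestral_scp(tree, y).values
        combo = ancestral_scp(tree, 2.0 * x + 3.0 * y).values
        np.testing.assert_allclose(combo, 2.0 * ax + 3.0 * ay, atol=1e-9)

    def test_invariant_to_branch_rescaling(self, rng):
        tree = simulate_tree(10, 0.1, seed=6)
        x = rng.normal(size=(10, 2))
        a1 = ancestral_scp(tree, x).values
        scaled = TimeTree(tree.parent, tree.blen * 7.3, tree.labels, tree.is_tip)
        a2 = ancestral_scp(scaled, x).values
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_missing_tip_value_rejected(self, balanced4_tree):
        with pytest.raises(KeyError, match="D"):
            ancestral_scp(balanced4_tree, {"A": [1], "B": [2], "C": [3]})


class TestPhylomorphospace:
    def test_two_tip_layout(self):
        tree = TimeTree.from_newick("(A:1,B:1);")
        layout = phylomorphospace(tree, np.array([[0.0, 0.0], [1.0, 1.0]]),
                                  taxa=["A", "B"])
        assert layout.points.shape == (3, 2)
        assert layout.edges.shape == (2, 2)

    def test_star_tree_root_at_centroid(self, star4_tree, rng):
        scores = rng.normal(size=(4, 2))
        layout = phylomorphospace(star4_tree, scores, taxa=["A", "B", "C", "D"])
        root = layout.points[0]
        np.testing.assert_allclose(root, scores.mean(axis=0), atol=1e-9)

    def test_node_points_equal_scp(self, bm16):
        _, tree, truth = bm16
        scores = np.array([truth.tip_traits[t] for t in tree.tip_labels])
        layout = phylomorphospace(tree, scores[:, :2])
        anc = ancestral_scp(tree, scores[:, :2])
        np.testing.assert_allclose(layout.points[anc.node_indices], anc.values)


class TestBmSimulate:
    def test_zero_rate_keeps_root_state(self, balanced4_tree):
        tips = bm_simulate(balanced4_tree, 0.0, [2.0, -1.0], n_sims=3, seed=1)
        np.testing.assert_allclose(tips, np.broadcast_to([2.0, -1.0], tips.shape))

    def test_marginal_variance_matches_bm(self):
        tree = TimeTree.from_newick("(A:4.0,B:4.0);")
        sigma2 = 1.7
        tips = bm_simulate(tree, sigma2, [0.0], n_sims=5000, seed=2)
        var = tips[:, 0, 0].var(ddof=1)
        assert var == pytest.approx(sigma2 * 4.0, rel=0.10)

    def test_sister_tip_covariance(self):
        tree = TimeTree.from_newick("((A:1.0,B:1.0):3.0,C:4.0);")
        tips = bm_simulate(tree, 1.0, [0.0], n_sims=5000, seed=3)
        ia = tree.tip_labels.index("A")
        ib = tree.tip_labels.index("B")
        cov = np.cov(tips[:, ia, 0], tips[:, ib, 0])[0, 1]
        assert cov == pytest.approx(3.0, rel=0.15)

    def test_seed_reproducibility(self, balanced4_tree):
        a = bm_simulate(balanced4_tree, 1.0, [0.0], n_sims=4, seed=9)
        b = bm_simulate(balanced4_tree, 1.0, [0.0], n_sims=4, seed=9)
        assert np.array_equal(a, b)

    def test_non_psd_rate_rejected(self, balanced4_tree):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="semi-definite"):
            bm_simulate(balanced4_tree, bad, [0.0, 0.0], n_sims=1, seed=0)
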