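"""Tree handling, K statistics, PGLS, and parsimony against exhaustive oracles."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from femorph.phylo import (ancestral_continuous, bm_covariance,
                           expand_tree_to_specimens, fitch_states, kmult_test,
                           pgls_fit, read_newick, squared_change_objective)
from femorph.synthetic import simulate_tree


def _star(n):
    return read_newick("(" + ",".join(f"t{i}:1" for i in range(n)) + ");",
                       unit_lengths=False), [f"t{i}" for i in range(n)]


class TestNewick:
    def test_unit_length_overwrite(self):
        phy = read_newick("(A:5,(B:2,C:2):3);")
        assert sorted(phy.tip_labels) == ["A", "B", "C"]
        C, labels = bm_covariance(phy)
        i = {l: j for j, l in enumerate(labels)}
        assert C[i["A"], i["A"]] == 1.0
        assert C[i["B"], i["B"]] == 2.0
        assert C[i["B"], i["C"]] == 1.0

    def test_missing_lengths_default_to_one(self):
        phy = read_newick("(A,B);")
        C, _ = bm_covariance(phy)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_round_trip_topology(self, tmp_path):
        phy = simulate_tree(12, seed=2)
        f = tmp_path / "t.nwk"
        phy.write(f)
        back = read_newick(f)
        assert sorted(back.tip_labels) == sorted(phy.tip_labels)
        C1, l1 = bm_covariance(phy, order=sorted(phy.tip_labels))
        C2, l2 = bm_covariance(back, order=sorted(phy.tip_labels))
        np.testing.assert_allclose(C1, C2)

    def test_malformed_newick_raises(self):
        with pytest.raises(ValueError, match="Newick"):
            read_newick("(A,(B,C);")


class TestBMCovariance:
    def test_star_tree_is_identity(self):
        phy, labels = _star(6)
        C, _ = bm_covariance(phy, order=labels)
        np.testing.assert_allclose(C, np.eye(6))

    def test_hand_computed_example(self):
        phy = read_newick("((A:1,B:1):1,C:2);", unit_lengths=False)
        C, labels = bm_covariance(phy, order=["A", "B", "C"])
        np.testing.assert_allclose(
            C, [[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])

    def test_symmetric_diagonal_is_root_to_tip(self):
        phy = simulate_tree(10, seed=4)
        C, labels = bm_covariance(phy)
        np.testing.assert_allclose(C, C.T)
        assert np.all(np.diag(C) >= C.min())
        assert np.all(np.linalg.eigvalsh(C) > -1e-10)

    def test_unmatched_tip_listed(self):
        phy, labels = _star(4)
        with pytest.raises(ValueError, match="ghost"):
            bm_covariance(phy, order=labels[:-1] + ["ghost"])

    def test_specimen_polytomy_expansion(self):
        phy = read_newick("((A,B),C);")
        expanded = expand_tree_to_specimens(
            phy, {"A": ["A_1", "A_2"], "B": ["B_1"], "C": ["C_1", "C_2", "C_3"]})
        assert sorted(expanded.tip_labels) == ["A_1", "A_2", "B_1", "C_1", "C_2", "C_3"]
        C, labels = bm_covariance(expanded, order=sorted(expanded.tip_labels))
        i = {l: j for j, l in enumerate(labels)}
        # conspecific specimens share all but the terminal unit branch
        assert C[i["A_1"], i["A_2"]] == C[i["A_1"], i["A_1"]] - 1.0
        assert C[i["C_1"], i["C_2"]] == C[i["C_1"], i["C_1"]] - 1.0


class TestKmult:
    def test_exactly_one_on_star_trees(self):
        rng = np.random.default_rng(2)
        for n in (8, 20):
            phy, labels = _star(n)
            res = kmult_test(rng.normal(size=(n, 6)), phy, labels,
                             n_perm=99, seed=0)
            assert res.k_mult == pytest.approx(1.0, abs=1e-12)

    def test_bm_simulations_center_on_one(self):
        """Data simulated under BM on a 16-tip unit-length balanced tree give
        mean K in [0.9, 1.1] over 200 replicates (independent simulation oracle:
        Y = L z with C = L L^T)."""
        newick = "((((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1):1," \
                 "(((I:1,J:1):1,(K:1,L:1):1):1,((M:1,N:1):1,(O:1,P:1):1):1):1);"
        phy = read_newick(newick, unit_lengths=False)
        labels = sorted(phy.tip_labels)
        C, _ = bm_covariance(phy, order=labels)
        L = np.linalg.cholesky(C)
        rng = np.random.default_rng(41)
        ks = []
        for _ in range(200):
            Y = L @ rng.standard_normal((16, 4))
            ks.append(kmult_test(Y, phy, labels, n_perm=99, seed=1).k_mult)
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_permutation_p_floor(self):
        phy, labels = _star(8)
        res = kmult_test(np.random.default_rng(0).normal(size=(8, 2)),
                         phy, labels, n_perm=99, seed=3)
        assert res.p_value >= 1.0 / 100.0

    def test_type_one_error_calibrated(self):
        """Label-shuffled nulls reject at alpha=0.05 about 5% of the time."""
        phy = simulate_tree(16, seed=6)
        labels = phy.tip_labels
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 400
        for i in range(n_rep):
            Y = rng.standard_normal((16, 3))  # iid: no signal by construction
            res = kmult_test(Y, phy, labels, n_perm=99, seed=1000 + i)
            rejections += res.p_value <= 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)


class TestPGLS:
    def test_star_tree_equals_ols(self):
        rng = np.random.default_rng(1)
        n = 24
        phy, labels = _star(n)
        size = rng.normal(size=n)
        mode = ["B" if i % 2 else "Q" for i in range(n)]
        Y = rng.normal(size=(n, 5)) + 0.4 * size[:, None]
        res = pgls_fit(Y, size, mode, phy, labels, n_perm=99, seed=2)
        # OLS oracle: sequential sums of squares on the raw data
        dummies = np.array([1.0 if m == "Q" else 0.0 for m in mode])[:, None]
        designs = [np.ones((n, 1))]
        for cols in (size[:, None], dummies, size[:, None] * dummies):
            designs.append(np.hstack([designs[-1], cols]))
        H = lambda X: X @ np.linalg.pinv(X)
        rss = [float(((Y - H(X) @ Y) ** 2).sum()) for X in designs]
        for t, k in zip(res.terms, range(3)):
            expected = (rss[k] - rss[k + 1]) / rss[0]
            assert t.r_squared == pytest.approx(expected, abs=1e-10)

    def test_constant_response_zero_r2(self):
        phy, labels = _star(12)
        Y = np.ones((12, 3)) * 4.2
        res = pgls_fit(Y, np.arange(12.0), ["B"] * 6 + ["Q"] * 6, phy, labels,
                       n_perm=99, seed=0)
        for t in res.terms:
            assert t.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_power_and_size_on_known_design(self):
        """Pure size effect: the size term rejects in >= 90% of replicates and
        the null mode term in about 5%."""
        phy = simulate_tree(64, seed=43)
        labels = phy.tip_labels
        C, _ = bm_covariance(phy, order=labels)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(64))
        rng = np.random.default_rng(43)
        size_rej = 0
        mode_rej = 0
        n_rep = 100
        for _ in range(n_rep):
            size = rng.uniform(-1, 1, size=64)
            mode = rng.choice(["B", "Q"], size=64).tolist()
            Y = (2.0 * size[:, None] * np.ones((1, 3))
                 + L @ rng.standard_normal((64, 3)))
            res = pgls_fit(Y, size, mode, phy, labels, interaction=False,
                           n_perm=99, seed=int(rng.integers(2 ** 31)))
            size_rej += res.term("size").p_value <= 0.05
            mode_rej += res.term("mode").p_value <= 0.05
        assert size_rej >= 0.9 * n_rep
        assert mode_rej / n_rep == pytest.approx(0.05, abs=0.05)

    def test_collinear_design_named(self):
        phy, labels = _star(10)
        with pytest.raises(ValueError, match="collinear"):
            pgls_fit(np.random.default_rng(0).normal(size=(10, 2)),
                     np.ones(10), ["B"] * 5 + ["Q"] * 5, phy, labels,
                     n_perm=99)


class TestAncestralContinuous:
    def test_two_tip_midpoint(self):
        phy = read_newick("(A:1,B:1);")
        anc = ancestral_continuous(np.array([[1.0], [5.0]]), phy, ["A", "B"])
        assert anc["nodes"][0, 0] == pytest.approx(3.0)

    def test_equal_tips_propagate(self):
        phy = simulate_tree(9, seed=5)
        vals = np.full((9, 2), 7.5)
        anc = ancestral_continuous(vals, phy, phy.tip_labels)
        np.testing.assert_allclose(anc["nodes"], 7.5)

    def test_matches_numerical_minimization(self):
        phy = simulate_tree(6, seed=47)
        labels = phy.tip_labels
        rng = np.random.default_rng(47)
        vals = rng.normal(size=(6, 1))
        anc = ancestral_continuous(vals, phy, labels)
        n_internal = anc["nodes"].shape[0]

        def objective(x):
            return squared_change_objective(phy, labels, vals, x.reshape(-1, 1))

        res = minimize(objective, np.zeros(n_internal), method="BFGS")
        np.testing.assert_allclose(anc["nodes"].ravel(), res.x, atol=1e-5)
        # gradient condition at the solution
        base = objective(anc["nodes"].ravel())
        eps = 1e-6
        for i in range(n_internal):
            x = anc["nodes"].ravel().copy()
            x[i] += eps
            assert abs(objective(x) - base) / eps < 1e-4


class TestFitch:
    def _brute_force_changes(self, phy, tip_modes, states=("B", "Q")):
        tree = phy.tree
        internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        best = None
        for combo in itertools.product(states, repeat=len(internal)):
            assign = dict(zip(internal, combo))

            def state(nd):
                return tip_modes[nd.taxon.label] if nd.is_leaf() else assign[nd]

            changes = sum(
                1 for nd in tree.preorder_node_iter()
                if nd.parent_node is not None and state(nd) != state(nd.parent_node))
            best = changes if best is None else min(best, changes)
        return best

    def test_two_clades_one_change_ambiguous_root(self):
        phy = read_newick("((a,b),(c,d));")
        out = fitch_states({"a": "B", "b": "B", "c": "Q", "d": "Q"}, phy)
        assert out["changes"] == 1
        root_set = out["node_sets"]["node0"]
        assert root_set == frozenset({"B", "Q"})

    def test_uniform_tips_no_changes(self):
        phy = simulate_tree(7, seed=1)
        out = fitch_states({t: "B" for t in phy.tip_labels}, phy)
        assert out["changes"] == 0
        assert all(s == frozenset({"B"}) for s in out["node_sets"].values())

    @pytest.mark.parametrize("seed", [53, 54, 55, 56])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        phy = simulate_tree(n, seed=seed)
        tip_modes = {t: ("B" if rng.random() < 0.5 else "Q") for t in phy.tip_labels}
        if len(set(tip_modes.values())) == 1:
            tip_modes[phy.tip_labels[0]] = "Q" if "B" in tip_modes.values() else "B"
        out = fitch_states(tip_modes, phy)
        assert out["changes"] == self._brute_force_changes(phy, tip_modes)
        assert out["changes"] <= n - 1

    def test_polytomy_majority_counted_exactly(self):
        phy = read_newick("(a,b,c,d,e);")
        out = fitch_states({"a": "B", "b": "B", "c": "Q", "d": "Q", "e": "Q"}, phy)
        assert out["changes"] == self._brute_force_changes(phy, {"a": "B", "b": "B",
                                                                 "c": "Q", "d": "Q",
                                                                 "e": "Q"})
        assert out["changes"] == 2

    def test_indeterminate_tips_free_or_excluded(self):
        phy = read_newick("((a,b),(c,d));")
        modes = {"a": "B", "b": "I", "c": "Q", "d": "Q"}
        free = fitch_states(modes, phy, indeterminate="free")
        excl = fitch_states(modes, phy, indeterminate="exclude")
        assert free["changes"] == excl["changes"] == 1
        assert "b" not in excl["node_sets"]
        assert free["node_sets"]["b"] == frozenset({"B", "Q"})

    def test_too_few_scored_tips(self):
        phy = read_newick("(a,b,c);")
        with pytest.raises(ValueError):
            fitch_states({"a": "B", "b": "I", "c": "I"}, phy)
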