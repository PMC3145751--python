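import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phylorobust as pr
from phylorobust.treestats import CladeHypothesis, is_monophyletic
from _oracles import dendropy_split_support


class TestTreenessAndLength:
    def test_star_tree_has_zero_treeness(self):
        star = pr.parse_newick("(A:1,B:1,C:1,D:1);")
        assert pr.treeness(star) == 0.0
        assert pr.tree_length(star) == pytest.approx(4.0)

    def test_quartet_example(self, quartet_tree):
        assert pr.tree_length(quartet_tree) == pytest.approx(4.5)
        assert pr.treeness(quartet_tree) == pytest.approx(0.5 / 4.5)

    @given(c=st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=20, deadline=None)
    def test_scaling_invariance(self, c):
        t = pr.parse_newick(f"((A:{c},B:{c}):{0.5 * c},C:{c},D:{c});")
        assert pr.treeness(t) == pytest.approx(0.5 / 4.5, rel=1e-9)

    def test_treeness_in_unit_interval_on_random_trees(self):
        for seed in range(10):
            t = pr.simulate_tree(pr.SimulationConfig(n_taxa=9, seed=seed))
            assert 0.0 <= pr.treeness(t) <= 1.0

    def test_zero_length_tree_rejected(self):
        with pytest.raises(ValueError):
            pr.treeness(pr.parse_newick("(A:0,B:0,C:0);"))


class TestRootToTip:
    def test_midpoint_rooting_example(self):
        t = pr.parse_newick("((A:1,B:2):1,C:4);")
        r = pr.root_to_tip_lengths(t, {"C"})
        assert r == {"A": 4.0, "B": 5.0, "C": 2.0}

    def test_ultrametric_ingroup_values_equal(self, small_dataset):
        r = pr.root_to_tip_lengths(small_dataset.true_tree, small_dataset.outgroup)
        vals = [v for k, v in r.items() if k != small_dataset.outgroup]
        assert np.allclose(vals, vals[0], atol=1e-9)

    def test_non_monophyletic_outgroup_names_intruders(self):
        t = pr.parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        with pytest.raises(ValueError, match="C|B"):
            pr.root_to_tip_lengths(t, {"A", "B"})

    def test_rank_single_tree_matches_direct_ranking(self, small_dataset):
        t = pr.inject_long_branches(small_dataset.true_tree, ["T006"], 8.0)
        r = pr.root_to_tip_lengths(t, small_dataset.outgroup)
        direct = sorted(
            (x for x in r if x != small_dataset.outgroup), key=lambda x: (-r[x], x)
        )
        ranked = pr.rank_long_branches([("t", t)], small_dataset.outgroup, 5)
        assert ranked == direct[:5]

    def test_rank_zero_empty(self, small_dataset):
        assert pr.rank_long_branches([("t", small_dataset.true_tree)], "OUT", 0) == []


class TestLeafStability:
    def identical_set(self, n=20):
        t = pr.simulate_tree(pr.SimulationConfig(n_taxa=7, seed=1))
        return pr.TreeSet(trees=[t.clone(depth=1) for _ in range(n)])

    def test_identical_trees_all_stable(self):
        rep = pr.leaf_stability(self.identical_set())
        assert np.allclose(rep.table["stability"], 1.0)
        assert rep.ci95_halfwidth == pytest.approx(0.0, abs=1e-12)

    def test_split_vote_quartet(self):
        # 2 trees say Xa|bc, 2 trees say Xb|ac -> f1 = f2 = 0.5, score 0
        t1 = pr.parse_newick("((X:1,a:1):1,(b:1,c:1):1);")
        t2 = pr.parse_newick("((X:1,b:1):1,(a:1,c:1):1);")
        ts = pr.TreeSet(trees=[t1.clone(depth=1), t1, t2.clone(depth=1), t2])
        rep = pr.leaf_stability(ts)
        assert rep.stability("X") == pytest.approx(0.0)

    def test_three_one_vote_quartet(self):
        t1 = pr.parse_newick("((X:1,a:1):1,(b:1,c:1):1);")
        t2 = pr.parse_newick("((X:1,b:1):1,(a:1,c:1):1);")
        ts = pr.TreeSet(trees=[t1, t1.clone(depth=1), t1.clone(depth=1), t2])
        rep = pr.leaf_stability(ts)
        assert rep.stability("X") == pytest.approx(0.75 - 0.25)

    def test_order_invariance(self):
        ts = self.identical_set(6)
        out = pr.inject_rogue(ts, "T003", 1.0, seed=5)
        rev = pr.TreeSet(trees=list(out.trees)[::-1])
        a = pr.leaf_stability(out).table["stability"]
        b = pr.leaf_stability(rev).table["stability"]
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_sampled_close_to_exact(self, small_dataset):
        ts = pr.bootstrap_trees(small_dataset.alignment, 100, seed=2)
        exact = pr.leaf_stability(ts, mode="exact")
        sampled = pr.leaf_stability(ts, mode="sampled", m=2000, seed=0)
        assert abs(exact.mean - sampled.mean) < 0.02

    def test_alternative_variants_bounded(self):
        ts = self.identical_set(6)
        out = pr.inject_rogue(ts, "T003", 1.0, seed=5)
        for variant in ("max", "entropy"):
            rep = pr.leaf_stability(out, variant=variant)
            vals = rep.table["stability"].to_numpy()
            assert np.all((vals >= 0) & (vals <= 1 + 1e-12))


class TestCladeSupport:
    def random_treeset(self, seed, n_taxa=8, n_trees=12):
        trees = [
            pr.simulate_tree(pr.SimulationConfig(n_taxa=n_taxa, seed=seed * 100 + i))
            for i in range(n_trees)
        ]
        return pr.TreeSet(trees=trees)

    def test_complement_of_single_taxon_is_trivially_supported(self):
        ts = self.random_treeset(1)
        members = sorted(ts.taxon_universe)[1:]
        assert pr.clade_support(ts, members) == 100.0

    def test_matches_dendropy_counting_oracle(self):
        rng = np.random.default_rng(7)
        for seed in range(8):
            ts = self.random_treeset(seed)
            taxa = sorted(ts.taxon_universe)
            members = set(rng.choice(taxa, size=3, replace=False))
            ours = pr.clade_support(ts, members)
            oracle = dendropy_split_support(list(ts.trees), members)
            assert ours == pytest.approx(oracle)

    def test_complement_symmetry(self):
        ts = self.random_treeset(3)
        taxa = sorted(ts.taxon_universe)
        members = set(taxa[:3])
        comp = set(taxa) - members
        assert pr.clade_support(ts, members) == pytest.approx(pr.clade_support(ts, comp))

    def test_too_few_members_raises(self):
        ts = self.random_treeset(2)
        with pytest.raises(ValueError):
            pr.clade_support(ts, {"T001"})


class TestSupportTable:
    def test_cell_codes(self):
        best = pr.parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        ts = pr.TreeSet(trees=[best.clone(depth=1) for _ in range(10)])
        hyps = [
            CladeHypothesis("good", {"A", "B"}),
            CladeHypothesis("bad", {"A", "C"}),
            CladeHypothesis("missing", {"A", "Z9"}),
        ]
        table = pr.support_table(hyps, [("r1", best, ts)])
        assert table.cells.loc["good", "r1"] == 100
        assert table.cells.loc["bad", "r1"] == "nm"
        assert table.cells.loc["missing", "r1"] == "-"

    def test_nm_beats_replicate_frequency(self):
        best = pr.parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        alt = pr.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ts = pr.TreeSet(trees=[alt.clone(depth=1) for _ in range(10)])
        table = pr.support_table([CladeHypothesis("h", {"A", "B"})], [("r", best, ts)])
        assert table.cells.loc["h", "r"] == "nm"

    def test_every_cell_is_int_or_code(self):
        best = pr.simulate_tree(pr.SimulationConfig(n_taxa=8, seed=4))
        ts = pr.TreeSet(
            trees=[pr.simulate_tree(pr.SimulationConfig(n_taxa=8, seed=40 + i)) for i in range(6)]
        )
        taxa = sorted(ts.taxon_universe)
        hyps = [CladeHypothesis(f"h{i}", set(taxa[i : i + 3])) for i in range(4)]
        table = pr.support_table(hyps, [("r", best, ts)])
        for cell in table.cells.to_numpy().ravel():
            assert cell in ("nm", "-") or (isinstance(cell, (int, np.integer)) and 0 <= cell <= 100)


class TestConsensus:
    def test_identical_trees_full_support(self):
        t = pr.parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        ts = pr.TreeSet(trees=[t.clone(depth=1) for _ in range(4)])
        cons = pr.majority_rule_consensus(ts)
        assert is_monophyletic(cons, {"A", "B"})
        assert is_monophyletic(cons, {"C", "D"})
        sups = [n.support for n in cons.preorder_node_iter() if getattr(n, "support", None) is not None]
        assert sups and all(s == 100 for s in sups)

    def test_even_conflict_gives_star(self):
        t1 = pr.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = pr.parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        ts = pr.TreeSet(trees=[t1, t1.clone(depth=1), t2, t2.clone(depth=1)])
        cons = pr.majority_rule_consensus(ts, threshold=0.5)
        from phylorobust._treeutil import unrooted_view

        view = unrooted_view(cons)
        assert view.split_masks(include_trivial=False) == set()

    def test_consensus_supports_match_clade_support(self):
        trees = [pr.simulate_tree(pr.SimulationConfig(n_taxa=7, seed=s)) for s in range(9)]
        ts = pr.TreeSet(trees=trees)
        cons = pr.majority_rule_consensus(ts)
        labels = sorted(ts.taxon_universe)
        for node in cons.preorder_internal_node_iter():
            sup = getattr(node, "support", None)
            if sup is None:
                continue
            members = {lf.taxon.label for lf in node.leaf_iter()}
            if 2 <= len(members) <= len(labels) - 2:
                assert sup == pytest.approx(pr.clade_support(ts, members))
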