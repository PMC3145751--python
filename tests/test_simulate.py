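import numpy as np
import pytest
from scipy.stats import chisquare

import phylorobust as pr
from phylorobust._treeutil import unrooted_view


class TestSimulateTree:
    def test_deterministic_given_seed(self):
        cfg = pr.SimulationConfig(n_taxa=15, seed=42)
        t1 = pr.tree_to_newick(pr.simulate_tree(cfg))
        t2 = pr.tree_to_newick(pr.simulate_tree(cfg))
        assert t1 == t2

    def test_leaf_and_branch_counts(self):
        tree = pr.simulate_tree(pr.SimulationConfig(n_taxa=10, seed=0))
        view = unrooted_view(tree)
        assert len(view.labels) == 10
        assert len(view.edges) == 2 * 10 - 3  # unrooted binary
        assert all(e.length > 0 for e in view.edges)

    def test_rejects_tiny_trees(self):
        with pytest.raises(ValueError):
            pr.SimulationConfig(n_taxa=2)

    def test_yule_mean_depth_matches_monte_carlo_oracle(self):
        """Mean root-to-tip depth agrees with a direct simulation of the
        same pure-birth process (independent minimal reimplementation)."""
        lam, n, reps = 1.0, 8, 400

        def mc_depth(rng):
            # track only the number of lineages and elapsed time per tip
            k, t = 2, 0.0
            while k < n:
                t += rng.exponential(1.0 / (lam * k))
                k += 1
            t += rng.exponential(1.0 / (lam * n))
            return t

        rng = np.random.default_rng(99)
        oracle = np.array([mc_depth(rng) for _ in range(reps)])
        def height(tree):
            lf = next(tree.leaf_node_iter())
            d, nd = 0.0, lf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            return d

        ours = []
        for seed in range(reps):
            cfg = pr.SimulationConfig(n_taxa=n, seed=seed, scale_root_to_tip=None)
            ours.append(height(pr.simulate_tree(cfg)))
        se = oracle.std(ddof=1) * np.sqrt(1 / reps + 1 / reps)
        assert abs(np.mean(ours) - oracle.mean()) < 3 * se


class TestSimulateAlignment:
    def test_large_alpha_means_homogeneous_rates(self):
        m = pr.SubstModel.hky(alpha=1e8, k=8)
        assert np.all(np.abs(m.category_rates() - 1.0) < 1e-3)

    def test_zero_length_star_tree_gives_constant_columns(self):
        tree = pr.parse_newick("(A:0,B:0,C:0,D:0);")
        sim = pr.simulate_alignment(tree, pr.SubstModel.jc(alpha=0.5, k=4), 50, seed=3)
        assert all(len(set(col)) == 1 for col in sim.alignment.data.T)

    def test_long_branch_reaches_stationarity(self):
        model = pr.SubstModel.gtr([1, 4, 1, 1, 4, 1], [0.4, 0.1, 0.2, 0.3], alpha=0.5, k=4)
        tree = pr.parse_newick("(A:0.001,B:25.0);")
        sim = pr.simulate_alignment(tree, model, 50_000, seed=8)
        seq = sim.alignment.row("B")
        counts = [(seq == b).sum() for b in "ACGT"]
        p = chisquare(counts, f_exp=np.array(model.freqs) * len(seq)).pvalue
        assert p > 0.01

    def test_class_draws_uniform(self):
        tree = pr.simulate_tree(pr.SimulationConfig(n_taxa=6, seed=2))
        sim = pr.simulate_alignment(tree, pr.SubstModel.jc(alpha=0.5, k=8), 10_000, seed=2)
        counts = np.bincount(sim.true_site_class, minlength=8)
        assert chisquare(counts).pvalue > 0.01

    def test_determinism(self):
        tree = pr.simulate_tree(pr.SimulationConfig(n_taxa=6, seed=2))
        m = pr.SubstModel.jc(alpha=0.5, k=4)
        a = pr.simulate_alignment(tree, m, 100, seed=5).alignment
        b = pr.simulate_alignment(tree, m, 100, seed=5).alignment
        assert np.array_equal(a.data, b.data)

    def test_jc_distance_consistency_with_path_length(self):
        """ML JC distance between two taxa approaches the true path length."""
        tree = pr.parse_newick("(A:0.15,B:0.15);")
        model = pr.SubstModel.jc()
        est = []
        for n_sites in (1000, 10_000, 100_000):
            sim = pr.simulate_alignment(tree, model, n_sites, seed=4)
            D = pr.jc_distance_matrix(sim.alignment)
            est.append(D[0, 1])
        assert abs(est[-1] - 0.30) < 0.01
        errors = np.abs(np.array(est) - 0.30)
        assert errors[-1] <= errors[0] + 0.01


class TestInjections:
    def test_long_branch_multiplier_one_is_identity(self, small_dataset):
        t = small_dataset.true_tree
        out = pr.inject_long_branches(t, ["T003"], 1.0)
        assert pr.tree_to_newick(out) == pr.tree_to_newick(t)

    def test_long_branch_arithmetic(self, small_dataset):
        t = small_dataset.true_tree
        r0 = pr.root_to_tip_lengths(t, small_dataset.outgroup)
        pend = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        out = pr.inject_long_branches(t, ["T003"], 10.0)
        r1 = pr.root_to_tip_lengths(out, small_dataset.outgroup)
        assert r1["T003"] - r0["T003"] == pytest.approx(9 * pend["T003"])
        for other in r0:
            if other != "T003":
                assert r1[other] == pytest.approx(r0[other])

    def test_injected_taxa_top_root_to_tip_ranks(self, small_dataset):
        taxa = ["T002", "T005"]
        out = pr.inject_long_branches(small_dataset.true_tree, taxa, 5.0)
        top = pr.rank_long_branches([("t", out)], small_dataset.outgroup, 2)
        assert set(top) == set(taxa)

    def test_unknown_taxon_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            pr.inject_long_branches(small_dataset.true_tree, ["NOPE"], 2.0)


class TestInjectRogue:
    def make_treeset(self, n_trees=30, seed=0):
        tree = pr.simulate_tree(pr.SimulationConfig(n_taxa=8, seed=seed))
        return pr.TreeSet(trees=[tree.clone(depth=1) for _ in range(n_trees)])

    def test_p_zero_is_identity(self):
        ts = self.make_treeset()
        out = pr.inject_rogue(ts, "T004", 0.0, seed=1)
        assert [pr.tree_to_newick(t) for t in out] == [pr.tree_to_newick(t) for t in ts]

    def test_p_one_moves_only_the_rogue(self):
        from _oracles import quartet_counts_oracle

        ts = self.make_treeset(n_trees=40)
        out = pr.inject_rogue(ts, "T004", 1.0, seed=1)
        others = [l for l in sorted(ts.taxon_universe) if l != "T004"][:4]
        # quartets not touching the rogue keep a single resolution
        counts = quartet_counts_oracle(list(out.trees), others)
        assert sorted(counts) == [0, 0, 40]

    def test_rogue_is_least_stable(self):
        ts = self.make_treeset(n_trees=100, seed=3)
        out = pr.inject_rogue(ts, "T002", 1.0, seed=3)
        rep = pr.leaf_stability(out)
        assert rep.table["stability"].idxmin() == "T002"
        assert pr.rank_unstable(out, 1) == ["T002"]

    def test_absent_taxon_rejected(self):
        with pytest.raises(ValueError):
            pr.inject_rogue(self.make_treeset(), "NOPE", 0.5, seed=0)


class TestEnvironmentalPool:
    def test_exact_duplicates_at_identity_one(self):
        pool = pr.make_environmental_pool([("r1", "ACGTACGTAC")], identity_targets=[1.0], seed=0)
        assert pool[0][1] == "ACGTACGTAC"

    def test_target_identity_by_construction(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 100))
        pool = pr.make_environmental_pool([("r", ref)], identity_targets=[0.5], seed=1)
        ham = sum(a == b for a, b in zip(ref, pool[0][1])) / 100
        assert ham == pytest.approx(0.5, abs=0.005)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            pr.make_environmental_pool([], seed=0)


class TestMakeDataset:
    def test_determinism_and_provenance(self):
        cfg = pr.SimulationConfig(n_taxa=10, n_sites_dna=100, n_sites_protein=30, seed=3,
                                  long_branch_spec=(2, 10.0), rogue_spec=(2, 1.0))
        a = pr.make_dataset(cfg)
        b = pr.make_dataset(cfg)
        assert np.array_equal(a.alignment.data, b.alignment.data)
        assert a.long_branch_taxa == b.long_branch_taxa
        assert a.outgroup == "OUT"
        assert len(a.true_site_rates) == a.alignment.n_cols
        assert set(a.long_branch_taxa).isdisjoint(a.rogue_taxa)

    def test_partition_layout(self):
        cfg = pr.SimulationConfig(
            n_taxa=8, n_sites_dna=120, n_sites_protein=40, seed=1,
            long_branch_spec=(1, 10.0), rogue_spec=(1, 1.0),
        )
        ds = pr.make_dataset(cfg)
        assert ds.alignment.partitions["ssu"].size == 120
        assert ds.alignment.partitions["actin"].size == 40
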