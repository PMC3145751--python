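import numpy as np
import pytest

import phylorobust as pr
from phylorobust._treeutil import unrooted_view
from _oracles import greedy_derep_oracle, nw_identity


class TestJcDistances:
    def test_identical_sequences_zero(self):
        aln = pr.Alignment(labels=["a", "b"], data=np.array([list("ACGTACGT")] * 2))
        D = pr.jc_distance_matrix(aln)
        assert D[0, 1] == pytest.approx(0.0)

    def test_closed_form_at_p_distance_point_one(self):
        # 10% observed difference: d = -(3/4) ln(1 - 4*0.1/3)
        a = "ACGTACGTAC"
        b = "ACGTACGTAG"  # 1/10 mismatch
        aln = pr.Alignment(labels=["a", "b"], data=np.array([list(a), list(b)]))
        D = pr.jc_distance_matrix(aln)
        assert D[0, 1] == pytest.approx(-(3 / 4) * np.log(1 - 4 * 0.1 / 3), abs=1e-12)
        assert D[0, 1] == pytest.approx(0.1073, abs=1e-4)

    def test_symmetry_zero_diagonal(self, small_dataset):
        D = pr.jc_distance_matrix(small_dataset.alignment)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_saturated_pair_capped_with_warning(self):
        aln = pr.Alignment(
            labels=["a", "b"], data=np.array([list("ACGTACGTACGT"), list("CAGTCGTACGTA")])
        )
        # force full mismatch
        aln = pr.Alignment(labels=["a", "b"], data=np.array([list("AAAA"), list("CCCC")]))
        with pytest.warns(UserWarning, match="capped"):
            D = pr.jc_distance_matrix(aln, max_distance=4.0)
        assert D[0, 1] == pytest.approx(4.0)

    def test_no_shared_columns_raises(self):
        aln = pr.Alignment(labels=["a", "b"], data=np.array([list("AC--"), list("--GT")]))
        with pytest.raises(ValueError, match="share no"):
            pr.jc_distance_matrix(aln)


class TestNeighborJoining:
    def test_additive_quartet_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5)); additive distances
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 0, 0],
            ],
            dtype=float,
        )
        D[3, 2] = D[2, 3] = 9.0
        D[3, 3] = 0.0
        tree = pr.nj_tree(D, labels)
        view = unrooted_view(tree)
        masks = view.split_masks(include_trivial=False)
        ab = (1 << view.index["A"]) | (1 << view.index["B"])
        from phylorobust._treeutil import canonical

        assert canonical(ab, view.full_mask) in masks
        lengths = {}
        for e in view.edges:
            members = frozenset(l for l in view.labels if (e.mask >> view.index[l]) & 1)
            lengths[members] = e.length
        assert lengths[frozenset({"A"})] == pytest.approx(2.0)
        assert lengths[frozenset({"B"})] == pytest.approx(3.0)
        assert lengths[frozenset({"A", "B"})] == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = pr.nj_tree(D, ["x", "y", "z"])
        pend = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert pend["x"] == pytest.approx(1.0)
        assert pend["y"] == pytest.approx(2.0)
        assert pend["z"] == pytest.approx(3.0)

    def test_taxon_order_invariance(self, small_dataset):
        D = pr.jc_distance_matrix(small_dataset.alignment)
        labels = small_dataset.alignment.labels
        t1 = pr.nj_tree(D, labels)
        perm = np.random.default_rng(0).permutation(len(labels))
        t2 = pr.nj_tree(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        v1, v2 = unrooted_view(t1), unrooted_view(t2)
        assert v1.split_masks() == v2.split_masks()

    def test_agrees_with_dendropy_nj(self, small_dataset):
        """Independent cross-check: dendropy's NJ on the same matrix gives
        the same unrooted topology."""
        import dendropy

        aln = small_dataset.alignment
        D = pr.jc_distance_matrix(aln)
        ours = pr.nj_tree(D, aln.labels)

        csv = "," + ",".join(aln.labels) + "\n"
        for i, l in enumerate(aln.labels):
            csv += l + "," + ",".join(f"{x:.10f}" for x in D[i]) + "\n"
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_io.StringIO(csv), delimiter=","
        )
        ref = pdm.nj_tree()
        v1 = unrooted_view(ours)
        v2 = unrooted_view(
            pr.parse_newick(ref.as_string(schema="newick").replace("[&U]", ""))
        )
        assert v1.split_masks(include_trivial=False) == v2.split_masks(include_trivial=False)

    def test_negative_branch_clamped(self):
        D = np.array(
            [[0.0, 0.1, 0.4, 0.5], [0.1, 0.0, 0.45, 0.55], [0.4, 0.45, 0.0, 0.05], [0.5, 0.55, 0.05, 0.0]]
        )
        tree = pr.nj_tree(D, ["a", "b", "c", "d"])
        for e in unrooted_view(tree).edges:
            assert e.length >= 0.0


class TestBootstrap:
    def test_counts_and_determinism(self, small_dataset):
        ts1 = pr.bootstrap_trees(small_dataset.alignment, 25, seed=4)
        ts2 = pr.bootstrap_trees(small_dataset.alignment, 25, seed=4)
        assert len(ts1) == 25
        assert [pr.tree_to_newick(t) for t in ts1] == [pr.tree_to_newick(t) for t in ts2]

    def test_clean_signal_high_support(self, small_dataset):
        """With long internal branches and no noise, true clades are
        recovered in nearly all replicates."""
        ts = pr.bootstrap_trees(small_dataset.alignment, 100, seed=1)
        view = unrooted_view(small_dataset.true_tree)
        n = len(view.labels)
        label_of = {i: l for l, i in view.index.items()}
        checked = 0
        for e in view.edges:
            pop = bin(e.mask).count("1")
            if 3 <= pop <= n - 3 and e.length > 0.08:
                members = {label_of[i] for i in range(n) if (e.mask >> i) & 1}
                assert pr.clade_support(ts, members) >= 70.0
                checked += 1
        assert checked >= 1


class TestPairwiseIdentity:
    def test_identical(self):
        assert pr.pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_simple_mismatch(self):
        assert pr.pairwise_identity("ACGT", "ACGA") == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pr.pairwise_identity("", "ACGT")

    def test_terminal_overhang_free(self):
        # identical core, one sequence longer on both ends
        assert pr.pairwise_identity("GGACGTACGTAA", "ACGTACGT") == 1.0

    def test_matches_dp_oracle_on_random_related_pairs(self, rng):
        for t in range(50):
            L = int(rng.integers(10, 31))
            a = "".join(rng.choice(list("ACGT"), L))
            b = list(a)
            for p in rng.choice(L, size=max(1, L // 8), replace=False):
                b[p] = rng.choice([c for c in "ACGT" if c != b[p]])
            if rng.random() < 0.7:
                pos = int(rng.integers(1, len(b) - 1))
                if rng.random() < 0.5:
                    del b[pos]
                else:
                    b.insert(pos, str(rng.choice(list("ACGT"))))
            b = "".join(b)
            assert pr.pairwise_identity(a, b) == pytest.approx(nw_identity(a, b), abs=1e-9)


class TestDereplicate:
    def test_identical_trio_one_retained(self):
        seqs = [("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "ACGTACGT")]
        retained, cluster = pr.dereplicate(seqs, threshold=0.98)
        assert [l for l, _ in retained] == ["a"]
        assert cluster == {"a": "a", "b": "a", "c": "a"}

    def test_pool_against_exhaustive_oracle(self, rng):
        refs = [("r%d" % i, "".join(rng.choice(list("ACGT"), 200))) for i in range(4)]
        pool = pr.make_environmental_pool(refs, identity_targets=(1.0, 0.99, 0.90), seed=6)
        retained, cluster = pr.dereplicate(pool, threshold=0.98)
        want_retained, want_cluster = greedy_derep_oracle(pool, 0.98)
        assert [l for l, _ in retained] == want_retained
        assert cluster == want_cluster
        # the 0.99 copies are absorbed, the 0.90 copies retained
        for label in cluster:
            if "_q99_" in label:
                assert cluster[label] != label
            if "_q90_" in label:
                assert cluster[label] == label

    def test_threshold_above_max_identity_keeps_all(self):
        seqs = [("a", "ACGTACGTAC"), ("b", "TGCATGCATG")]
        retained, _ = pr.dereplicate(seqs, threshold=1.0)
        assert len(retained) == 2


class TestRemoveTaxa:
    def test_empty_removal_identity(self, small_dataset):
        out = pr.remove_taxa(small_dataset.alignment, [])
        assert out.labels == small_dataset.alignment.labels

    def test_alignment_counts(self, small_dataset):
        aln = small_dataset.alignment
        out = pr.remove_taxa(aln, aln.labels[:3])
        assert out.n_taxa == aln.n_taxa - 3

    def test_treeset_pruning_sums_lengths(self):
        t = pr.parse_newick("((A:1,B:2):3,(C:4,D:5):6);")
        ts = pr.TreeSet(trees=[t])
        out = pr.remove_taxa(ts, ["B"], min_remaining=3)
        pruned = out[0]
        leaves = {lf.taxon.label for lf in pruned.leaf_node_iter()}
        assert leaves == {"A", "C", "D"}
        # A's path to the root junction keeps total length 1 + 3
        r = pr.root_to_tip_lengths(pruned, {"A"})
        assert r["C"] + r["A"] == pytest.approx(1 + 3 + 6 + 4)

    def test_too_aggressive_removal_rejected(self, small_dataset):
        aln = small_dataset.alignment
        with pytest.raises(ValueError):
            pr.remove_taxa(aln, aln.labels[:-2])
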