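"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: likelihoods by
exhaustive enumeration of internal-node states, quartet splits by direct
set comparison, alignment identity by a plain Needleman-Wunsch DP, and
split counting by dendropy's own bipartition encoding.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

from phylorobust.likelihood import _char_vectors  # leaf-state encoding only


def brute_force_site_lnl(aln, tree, model) -> np.ndarray:
    """Site log-likelihoods by summing over all internal-state assignments."""
    rates = model.category_rates()
    w, right, left = model.eigen()

    def P(t, r):
        return np.clip((right * np.exp(w * r * t)[None, :]) @ left, 0.0, None)

    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    s = model.n_states
    table = _char_vectors(model)
    row = {l: i for i, l in enumerate(aln.labels)}
    out = np.zeros(aln.n_cols)
    for c in range(aln.n_cols):
        tot = 0.0
        for r in rates:
            Ps = {id(n): P(n.edge.length or 0.0, r) for n in nodes if n.parent_node is not None}
            for assign in itertools.product(range(s), repeat=len(internals)):
                amap = {id(n): st for n, st in zip(internals, assign)}
                val = model.freqs[amap[id(tree.seed_node)]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    ps = amap[id(n.parent_node)]
                    if n.is_leaf():
                        v = table[aln.data[row[n.taxon.label], c]]
                        val *= float((Ps[id(n)][ps] * v).sum())
                    else:
                        val *= float(Ps[id(n)][ps, amap[id(n)]])
                tot += val / len(rates)
        out[c] = np.log(tot)
    return out


def dendropy_split_support(trees: list[dendropy.Tree], members: set[str]) -> float:
    """Percent of trees where ``members`` is one side of a split, counted
    entirely with dendropy's bipartition machinery."""
    hits = 0
    eligible = 0
    for t in trees:
        newick = t.as_string(schema="newick")
        tt = dendropy.Tree.get(data=newick, schema="newick")
        leaves = {lf.taxon.label for lf in tt.leaf_node_iter()}
        present = members & leaves
        if len(present) < 2:
            continue
        eligible += 1
        rest = leaves - present
        if len(rest) <= 1:
            hits += 1
            continue
        tt.encode_bipartitions()
        target = frozenset(present)
        found = False
        for bp in tt.bipartition_encoding:
            side = {
                tx.label
                for tx in tt.taxon_namespace
                if bp.split_bitmask & tt.taxon_namespace.taxon_bitmask(tx)
            }
            if side == target or (leaves - side) == target:
                found = True
                break
        if found:
            hits += 1
    return 100.0 * hits / eligible


def nw_identity(a: str, b: str, open_gap=-5.0, extend_gap=-1.0) -> float:
    """Free-end-gap affine DP identity oracle (match 1, mismatch 0).

    Optimizes lexicographically (score, matches, -columns) — score, matches
    and column count are all additive along an alignment path, so the
    3-state affine DP stays exact for the compound objective.  Identity =
    matches / aligned columns with terminal-overhang columns excluded (the
    free end-gap runs contribute no columns).
    """
    n, m = len(a), len(b)
    NEG = (-1e9, 0, 0)
    go = open_gap  # a length-L gap costs open + (L-1) * extend

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = (0.0, 0, 0)
    for i in range(1, n + 1):
        X[i][0] = (0.0, 0, 0)  # free leading end gap, no columns counted
    for j in range(1, m + 1):
        Y[0][j] = (0.0, 0, 0)

    def step(t, dscore, dmatch, dcol):
        return (t[0] + dscore, t[1] + dmatch, t[2] + dcol)

    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                mt = 1 if a[i - 1] == b[j - 1] else 0
                prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                M[i][j] = step(prev, float(mt), mt, -1)
            if i > 0 and j > 0:
                X[i][j] = max(
                    step(M[i - 1][j], go, 0, -1),
                    step(X[i - 1][j], extend_gap, 0, -1),
                    step(Y[i - 1][j], go, 0, -1),
                )
                Y[i][j] = max(
                    step(M[i][j - 1], go, 0, -1),
                    step(X[i][j - 1], go, 0, -1),
                    step(Y[i][j - 1], extend_gap, 0, -1),
                )
    best = NEG
    for i in range(n + 1):
        for j in range(m + 1):
            if i == n or j == m:
                # trailing overhang free: take the cell value as-is
                best = max(best, M[i][j], X[i][j], Y[i][j])
    _, matches, neg_cols = best
    return matches / -neg_cols if neg_cols else 0.0


def greedy_derep_oracle(seqs, threshold):
    """Exhaustive-pairwise greedy dereplication with Hamming identity
    (valid for equal-length, gap-free pools)."""
    ident = {}
    for (la, sa), (lb, sb) in itertools.combinations(seqs, 2):
        assert len(sa) == len(sb)
        ident[(la, lb)] = ident[(lb, la)] = sum(x == y for x, y in zip(sa, sb)) / len(sa)
    retained = []
    cluster = {}
    for label, seq in seqs:
        rep = None
        for rl in retained:
            if ident[(label, rl)] >= threshold:
                rep = rl
                break
        if rep is None:
            retained.append(label)
            cluster[label] = label
        else:
            cluster[label] = rep
    return retained, cluster


def quartet_counts_oracle(trees, taxa_quad):
    """Counts of the three resolutions of one quartet by split comparison."""
    a, b, c, d = taxa_quad
    counts = [0, 0, 0]
    for t in trees:
        leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
        if not {a, b, c, d} <= leaves:
            continue
        tt = dendropy.Tree.get(data=t.as_string(schema="newick"), schema="newick")
        tt.retain_taxa_with_labels([a, b, c, d])
        tt.encode_bipartitions()
        resolved = None
        for bp in tt.bipartition_encoding:
            side = {
                tx.label
                for tx in tt.taxon_namespace
                if bp.split_bitmask & tt.taxon_namespace.taxon_bitmask(tx)
            }
            side = side & {a, b, c, d}
            if len(side) == 2:
                if side in ({a, b}, {c, d}):
                    resolved = 0
                elif side in ({a, c}, {b, d}):
                    resolved = 1
                elif side in ({a, d}, {b, c}):
                    resolved = 2
        if resolved is not None:
            counts[resolved] += 1
    return counts
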