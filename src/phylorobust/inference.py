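"""Distance-based stand-in inference: JC distances, neighbor joining, bootstrap.

This is deliberately *not* a maximum-likelihood search: it is a fast,
deterministic stand-in used to exercise the comparative pipeline end to
end.  Externally inferred trees (ML or Bayesian) can be ingested instead
through the experiment configuration.

Distances are Jukes-Cantor corrected per partition alphabet (s = 4 for
nucleotides, s = 20 for amino acids) over the columns shared by a pair, and
combined across partitions weighted by shared column counts.  Saturated
pairs are capped at a configurable maximum.  Neighbor joining follows
Saitou & Nei with Studier-Keppler O(n^2) updates; negative branch length
estimates are clamped to zero with the deficit moved to the sibling edge.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

from ._rng import rng_for
from .io import Alignment, TreeSet, MISSING_DNA
from .models import DNA_ORDER
from ._aamodels import AA_ORDER

__all__ = ["jc_distance_matrix", "nj_tree", "bootstrap_trees"]


def _codes(block: np.ndarray, alphabet: str) -> np.ndarray:
    """Integer state codes; -1 = missing/ambiguous (excluded from distances)."""
    order = DNA_ORDER if alphabet == "dna" else AA_ORDER
    out = np.full(block.shape, -1, dtype=np.int8)
    for i, ch in enumerate(order):
        out[block == ch] = i
    return out


def _alphabet_groups(aln: Alignment) -> list[tuple[str, np.ndarray]]:
    """(alphabet, columns) per partition; content-guessed only when mixed."""
    groups = []
    for name, cols in aln.partitions.items():
        if aln.alphabet in ("dna", "protein"):
            alphabet = aln.alphabet
        else:
            block = aln.data[:, cols]
            chars = set(np.unique(block).tolist()) - MISSING_DNA - {"U"}
            alphabet = "dna" if chars <= set("ACGT" "RYSWKMBDHV") else "protein"
        groups.append((alphabet, cols))
    return groups


def jc_distance_matrix(
    aln: Alignment,
    max_distance: float = 5.0,
    column_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise Jukes-Cantor distances on shared non-missing columns.

    ``column_weights`` (non-negative ints/floats per column) supports
    bootstrap resampling without materializing resampled alignments.
    Saturated pairs are capped at ``max_distance`` with a warning; a pair
    with no shared columns raises.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    w_all = np.ones(aln.n_cols) if column_weights is None else np.asarray(column_weights, float)
    n = aln.n_taxa
    num = np.zeros((n, n))  # weighted mismatches, JC-corrected contribution
    den = np.zeros((n, n))  # weighted shared columns
    dist_sum = np.zeros((n, n))
    capped = False
    for alphabet, cols in _alphabet_groups(aln):
        s = 4 if alphabet == "dna" else 20
        codes = _codes(aln.data[:, cols], alphabet)
        w = w_all[cols]
        valid = codes >= 0
        vw = valid * w[None, :]
        shared = vw @ valid.T  # sum of weights where both valid
        onehot = np.zeros((n, cols.size, s))
        rows, colidx = np.where(valid)
        onehot[rows, colidx, codes[rows, colidx]] = 1.0
        flat = onehot.reshape(n, -1)
        matches = (onehot * w[None, :, None]).reshape(n, -1) @ flat.T
        with np.errstate(invalid="ignore", divide="ignore"):
            p = 1.0 - matches / shared
        pmax = (s - 1.0) / s
        arg = 1.0 - p / pmax
        sat = arg <= 1e-12
        capped = capped or bool(np.any(sat & (shared > 0) & ~np.eye(n, dtype=bool)))
        with np.errstate(invalid="ignore", divide="ignore"):
            d = -pmax * np.log(np.where(sat, 1.0, arg))
        d = np.where(sat, max_distance, d)
        d = np.minimum(d, max_distance)
        d = np.where(shared > 0, d, 0.0)
        dist_sum += np.nan_to_num(d) * shared
        den += shared
    off = ~np.eye(n, dtype=bool)
    if np.any(den[off] == 0):
        i, j = np.argwhere((den == 0) & off)[0]
        raise ValueError(
            f"taxa {aln.labels[i]!r} and {aln.labels[j]!r} share no scorable columns"
        )
    if capped:
        warnings.warn(f"saturated pairs capped at distance {max_distance}")
    D = dist_sum / den
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def nj_tree(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Negative branch-length estimates are clamped to zero and the deficit is
    moved to the sibling edge, preserving the pair's summed length.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    tns = dendropy.TaxonNamespace(list(labels))
    nodes = [dendropy.Node(taxon=tns.get_taxon(l)) for l in labels]
    D = D.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2.0) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2.0))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(lj)
        newd = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = newd
        D[active, i] = newd
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)
    tree = dendropy.Tree(taxon_namespace=tns)
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, ln in ((i, li), (j, lj), (k, lk)):
            tree.seed_node.add_child(nodes[idx])
            nodes[idx].edge.length = float(max(ln, 0.0))
    else:  # exactly 2 left (possible only when called with n == 2 internally)
        i, j = active
        tree.seed_node.add_child(nodes[i])
        nodes[i].edge.length = float(D[i, j] / 2)
        tree.seed_node.add_child(nodes[j])
        nodes[j].edge.length = float(D[i, j] / 2)
    return tree


def bootstrap_trees(aln: Alignment, n_reps: int, seed: int = 0, max_distance: float = 5.0) -> TreeSet:
    """NJ trees from ``n_reps`` column resamples (shared across partitions)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = rng_for(seed, "bootstrap_trees")
    trees = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            w = rng.multinomial(aln.n_cols, np.full(aln.n_cols, 1.0 / aln.n_cols))
            D = jc_distance_matrix(aln, max_distance=max_distance, column_weights=w)
            trees.append(nj_tree(D, aln.labels))
    return TreeSet(trees=trees)
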