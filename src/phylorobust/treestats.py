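"""Tree-quality metrics, taxon-stability screening and support tabulation.

Three comparative measures for judging alternative reconstructions of the
same group:

* **treeness** — the fraction of total tree length held in internal
  branches; low treeness means most substitutions sit on terminal branches
  and little signal reaches the stems.
* **leaf stability** — for each taxon X, the average over quartets
  {X, a, b, c} of the margin f1 - f2 between the two most frequent of the
  three unrooted quartet resolutions across a set of (bootstrap) trees; a
  taxon that wanders between replicates scores near 0, a taxon placed
  identically everywhere scores 1.
* **clade support** — the percentage of trees in which a named taxon set
  forms one side of a bipartition, tabulated across reconstructions with
  the status codes "nm" (present but not monophyletic in the best tree)
  and "-" (fewer than two members sampled).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from ._rng import rng_for
from ._treeutil import (
    canonical,
    find_split_edge,
    internal_length,
    leaf_distance_matrix,
    root_to_tip_from_edge,
    unrooted_view,
)
from ._treeutil import tree_length as _tree_length
from .io import TreeSet, leaf_labels, parse_newick

__all__ = [
    "CladeHypothesis",
    "LeafStabilityReport",
    "SupportTable",
    "treeness",
    "tree_length",
    "root_to_tip_lengths",
    "rank_long_branches",
    "leaf_stability",
    "rank_unstable",
    "clade_support",
    "support_table",
    "majority_rule_consensus",
]

#: exhaustive quartet enumeration above this many quartets switches to sampling
EXACT_QUARTET_LIMIT = 2_000_000


@dataclass
class CladeHypothesis:
    """A named taxon set whose monophyly is to be scored."""

    name: str
    members: set[str]
    category: str = "proposed"

    def __post_init__(self):
        self.members = set(self.members)
        if not self.members:
            raise ValueError(f"hypothesis {self.name!r} has no members")


def load_hypotheses(path) -> list[CladeHypothesis]:
    """Load a YAML list of {name, category, members} entries."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        CladeHypothesis(name=d["name"], members=set(d["members"]), category=d.get("category", "proposed"))
        for d in raw
    ]


def tree_length(tree: dendropy.Tree) -> float:
    """Total branch length (unrooted topology)."""
    return _tree_length(tree)


def treeness(tree: dendropy.Tree) -> float:
    """Internal branch length / total branch length, in [0, 1]."""
    total = _tree_length(tree)
    if total <= 0:
        raise ValueError("tree has zero total length")
    return internal_length(tree) / total


def root_to_tip_lengths(tree: dendropy.Tree, outgroup) -> dict[str, float]:
    """Path length from the outgroup-rooted root to every leaf.

    The tree is rooted at the midpoint of the outgroup's stem edge; the
    outgroup must be monophyletic on the unrooted topology.
    """
    outgroup = {outgroup} if isinstance(outgroup, str) else set(outgroup)
    if not outgroup:
        raise ValueError("outgroup must be non-empty")
    view = unrooted_view(tree, merge_root=False)
    missing = outgroup - set(view.labels)
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    mask = 0
    for l in outgroup:
        mask |= 1 << view.index[l]
    edge = find_split_edge(view, mask)
    if edge is None:
        intruders = _intruders(tree, outgroup)
        raise ValueError(
            f"outgroup is not monophyletic; conflicting taxa inside its span: {sorted(intruders)}"
        )
    return root_to_tip_from_edge(view, edge)


def _intruders(tree: dendropy.Tree, outgroup: set[str]) -> set[str]:
    t = tree.clone(depth=1)
    anchor = next(l for l in leaf_labels(t) if l not in outgroup)
    t.reroot_at_node(
        next(lf for lf in t.leaf_node_iter() if lf.taxon.label == anchor).parent_node
    )
    taxa = [t.taxon_namespace.get_taxon(l) for l in outgroup]
    mrca = t.mrca(taxa=taxa)
    spanned = {lf.taxon.label for lf in mrca.leaf_iter()}
    return spanned - outgroup


def rank_long_branches(
    trees: list[tuple[str, dendropy.Tree]],
    outgroup,
    n: int,
) -> list[str]:
    """Top-n taxa by root-to-tip length averaged over reconstructions.

    Taxa absent from a tree are averaged over the trees that contain them;
    outgroup taxa are not ranked.  Ties break by label.
    """
    if not trees:
        raise ValueError("no trees supplied")
    og = {outgroup} if isinstance(outgroup, str) else set(outgroup)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for _, tree in trees:
        present_og = og & set(leaf_labels(tree))
        r2t = root_to_tip_lengths(tree, present_og)
        for taxon, d in r2t.items():
            if taxon in og:
                continue
            sums[taxon] = sums.get(taxon, 0.0) + d
            counts[taxon] = counts.get(taxon, 0) + 1
    means = {t: sums[t] / counts[t] for t in sums}
    ranked = sorted(means, key=lambda t: (-means[t], t))
    if n >= len(ranked) + len(og):
        raise ValueError("n must be smaller than the number of ingroup taxa")
    return ranked[:n]


# ---------------------------------------------------------------------------
# Leaf stability


@dataclass
class LeafStabilityReport:
    """Per-taxon positional stability across a tree set."""

    table: pd.DataFrame  # index taxon; columns stability, rank
    mean: float
    ci95_halfwidth: float
    quartet_mode: str  # "exact" or "sampled:<m>"
    variant: str

    def stability(self, taxon: str) -> float:
        return float(self.table.loc[taxon, "stability"])

    def to_tsv(self, path) -> None:
        self.table.sort_values("stability").to_csv(path, sep="\t")


def _quartet_counts(
    trees: list[dendropy.Tree],
    index: dict[str, int],
    quartets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts (Q, 3) of the three resolutions + resolved-tree counts (Q,).

    Resolution order for quartet (a, b, c, d): 0 = ab|cd, 1 = ac|bd,
    2 = ad|bc, decided by the smallest topological four-point sum.
    """
    qa, qb, qc, qd = quartets.T
    counts = np.zeros((len(quartets), 3), dtype=np.int32)
    resolved = np.zeros(len(quartets), dtype=np.int32)
    for tree in trees:
        D = leaf_distance_matrix(tree, index, unit=True)
        s = np.stack(
            [
                D[qa, qb] + D[qc, qd],
                D[qa, qc] + D[qb, qd],
                D[qa, qd] + D[qb, qc],
            ]
        )
        valid = np.all(np.isfinite(s), axis=0)
        order = np.sort(s, axis=0)
        strict = order[0] < order[1]  # unique minimum = resolved quartet
        use = valid & strict
        res = np.argmin(s, axis=0)
        counts[use, res[use]] += 1
        resolved += use
    return counts, resolved


def leaf_stability(
    ts: TreeSet,
    mode: str = "auto",
    m: int | None = None,
    seed: int = 0,
    variant: str = "diff",
) -> LeafStabilityReport:
    """Quartet-based leaf stability over a set of trees.

    For every quartet containing taxon X the three unrooted resolutions have
    relative frequencies f1 >= f2 >= f3 across the trees that contain (and
    resolve) all four taxa; the quartet scores f1 - f2 ("diff" variant; the
    alternatives "max" = f1 and "entropy" = 1 - H(f)/log 3 are available)
    and stability(X) averages the score over quartets.  ``mode`` is
    "exact", "sampled", or "auto" (exact unless the quartet count exceeds
    2e6, then sampled with m = 1000 * n_taxa, stratified per taxon).
    """
    if len(ts) < 2:
        raise ValueError("need at least 2 trees")
    taxa = sorted(ts.taxon_universe)
    n = len(taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    index = {t: i for i, t in enumerate(taxa)}
    n_quartets_exact = n * (n - 1) * (n - 2) * (n - 3) // 24
    if mode == "auto":
        mode = "exact" if n_quartets_exact <= EXACT_QUARTET_LIMIT else "sampled"

    if mode == "exact":
        quartets = np.array(list(itertools.combinations(range(n), 4)), dtype=np.int64)
        label = "exact"
    elif mode == "sampled":
        m = m or 1000 * n
        rng = rng_for(seed, "leaf_stability")
        per_taxon = max(1, m // n)
        rows = []
        for i in range(n):
            others = np.delete(np.arange(n), i)
            for _ in range(per_taxon):
                rows.append(np.concatenate([[i], rng.choice(others, size=3, replace=False)]))
        quartets = np.array(rows, dtype=np.int64)
        label = f"sampled:{per_taxon * n}"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    counts, resolved = _quartet_counts(list(ts.trees), index, quartets)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / resolved[:, None]
    freqs_sorted = np.sort(freqs, axis=1)[:, ::-1]
    if variant == "diff":
        score = freqs_sorted[:, 0] - freqs_sorted[:, 1]
    elif variant == "max":
        score = freqs_sorted[:, 0]
    elif variant == "entropy":
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(freqs > 0, freqs * np.log(freqs), 0.0)
        score = 1.0 + plogp.sum(axis=1) / np.log(3.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    usable = resolved > 0
    if not usable.any():
        raise ValueError("no quartet is resolved in any tree")
    if not usable.all():
        warnings.warn(f"{(~usable).sum()} quartets present/resolved in no tree; excluded")

    sums = np.zeros(n)
    cnts = np.zeros(n)
    for col in range(4):
        np.add.at(sums, quartets[usable, col], score[usable])
        np.add.at(cnts, quartets[usable, col], 1.0)
    stab = np.divide(sums, cnts, out=np.full(n, np.nan), where=cnts > 0)

    order = np.argsort(-stab, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    table = pd.DataFrame({"stability": stab, "rank": rank}, index=pd.Index(taxa, name="taxon"))
    mean = float(np.nanmean(stab))
    sd = float(np.nanstd(stab, ddof=1)) if n > 1 else 0.0
    return LeafStabilityReport(
        table=table,
        mean=mean,
        ci95_halfwidth=1.96 * sd / np.sqrt(n),
        quartet_mode=label,
        variant=variant,
    )


def rank_unstable(ts: TreeSet, n: int, **kwargs) -> list[str]:
    """Bottom-n taxa by leaf stability (ties by label)."""
    taxa = ts.taxon_universe
    if n >= len(taxa):
        raise ValueError("n must be smaller than the taxon count")
    if n == 0:
        return []
    rep = leaf_stability(ts, **kwargs)
    t = rep.table.reset_index().sort_values(["stability", "taxon"])
    return t["taxon"].head(n).tolist()


# ---------------------------------------------------------------------------
# Clade support


def _tree_split_data(tree, index):
    view = unrooted_view(tree, index)
    present = 0
    for l in view.labels:
        present |= 1 << index[l]
    masks = {canonical(e.mask, present) for e in view.edges}
    return present, masks


def clade_support(ts: TreeSet, members) -> float:
    """Percent of trees in which the members form one side of a bipartition.

    Members absent from a tree are dropped for that tree; trees containing
    fewer than two members are skipped.  Raises if fewer than two members
    exist in the tree set at all.
    """
    members = set(members)
    universe = ts.taxon_universe
    if len(members & universe) < 2:
        raise ValueError("fewer than 2 hypothesis members present in the tree set")
    index = {t: i for i, t in enumerate(sorted(universe))}
    hits = 0
    eligible = 0
    for tree in ts:
        present, masks = _tree_split_data(tree, index)
        mmask = 0
        for x in members:
            if x in index and (present >> index[x]) & 1:
                mmask |= 1 << index[x]
        if bin(mmask).count("1") < 2:
            continue
        eligible += 1
        rest = present & ~mmask
        if rest == 0 or bin(rest).count("1") == 1 or canonical(mmask, present) in masks:
            hits += 1
    if eligible == 0:
        raise ValueError("no tree contains two or more members")
    return 100.0 * hits / eligible


def is_monophyletic(tree: dendropy.Tree, members) -> bool:
    """Do the members present in the tree form a clade (unrooted sense)?"""
    members = set(members)
    index = {t: i for i, t in enumerate(sorted(set(leaf_labels(tree)) | members))}
    present, masks = _tree_split_data(tree, index)
    mmask = 0
    for x in members:
        if (present >> index[x]) & 1:
            mmask |= 1 << index[x]
    pop = bin(mmask).count("1")
    if pop < 2:
        return True
    rest = present & ~mmask
    if rest == 0 or bin(rest).count("1") == 1:
        return True
    return canonical(mmask, present) in masks


@dataclass
class SupportTable:
    """Hypotheses x reconstructions grid of support percents / status codes.

    Cells are integers in 0..100, "nm" (members present but non-monophyletic
    in the best tree) or "-" (fewer than two members sampled).  Raw float
    supports are kept alongside for further computation.
    """

    cells: pd.DataFrame  # object dtype: int | "nm" | "-"
    raw: pd.DataFrame  # float bootstrap percents (NaN where not defined)

    def to_tsv(self, path) -> None:
        self.cells.to_csv(path, sep="\t")

    def to_markdown(self) -> str:
        return self.cells.to_markdown()


def support_table(
    hypotheses: list[CladeHypothesis],
    reconstructions: list[tuple[str, dendropy.Tree, TreeSet]],
) -> SupportTable:
    """Tabulate bootstrap support for each hypothesis in each reconstruction."""
    names = [n for n, _, _ in reconstructions]
    if len(set(names)) != len(names):
        raise ValueError("reconstruction names must be unique")
    cells = {}
    raw = {}
    for name, best, ts in reconstructions:
        col = []
        col_raw = []
        best_leaves = set(leaf_labels(best))
        for hyp in hypotheses:
            present = hyp.members & best_leaves
            if len(present) < 2:
                col.append("-")
                col_raw.append(np.nan)
            elif not is_monophyletic(best, hyp.members):
                col.append("nm")
                col_raw.append(np.nan)
            else:
                pct = clade_support(ts, hyp.members)
                col.append(int(round(pct)))
                col_raw.append(pct)
        cells[name] = col
        raw[name] = col_raw
    idx = pd.Index([h.name for h in hypotheses], name="hypothesis")
    return SupportTable(
        cells=pd.DataFrame(cells, index=idx, dtype=object),
        raw=pd.DataFrame(raw, index=idx),
    )


def majority_rule_consensus(ts: TreeSet, threshold: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus with split frequencies attached as supports.

    Splits with frequency strictly above ``threshold`` (>= 0.5, hence
    mutually compatible) are included; supports are percentages.
    """
    if threshold < 0.5:
        raise ValueError("threshold must be >= 0.5")
    taxa = sorted(ts.taxon_universe)
    index = {t: i for i, t in enumerate(taxa)}
    full = (1 << len(taxa)) - 1
    freq: dict[int, int] = {}
    for tree in ts:
        present, masks = _tree_split_data(tree, index)
        if present != full:
            raise ValueError("consensus requires all trees to share the full taxon set")
        for msk in masks:
            pop = bin(msk).count("1")
            if 2 <= pop <= len(taxa) - 2:
                freq[msk] = freq.get(msk, 0) + 1
    n_trees = len(ts)
    chosen = {m: c / n_trees for m, c in freq.items() if c / n_trees > threshold}

    # orient every clade away from taxon 0 so the family is laminar
    clades = []
    sup: dict[int, float] = {}
    for m, f in chosen.items():
        side = m if not (m & 1) else full & ~m
        clades.append((side, f))
        sup[side] = f
    clades.sort(key=lambda x: -bin(x[0]).count("1"))

    children: dict[int | None, list] = {None: []}
    parent_of: dict[int, int | None] = {}
    for side, f in clades:
        parent = None
        for other, _ in clades:
            if other == side:
                continue
            if side & other == side and bin(other).count("1") > bin(side).count("1"):
                if parent is None or bin(other).count("1") < bin(parent).count("1"):
                    parent = other
        parent_of[side] = parent
        children.setdefault(side, [])
        children.setdefault(parent, []).append(side)
    leaf_parent: dict[int, int | None] = {}
    for i in range(len(taxa)):
        bit = 1 << i
        best = None
        for side, _ in clades:
            if side & bit and (best is None or bin(side).count("1") < bin(best).count("1")):
                best = side
        leaf_parent[i] = best

    def render(node: int | None) -> str:
        subs = [render(c) for c in children.get(node, [])]
        subs += [taxa[i] for i in range(len(taxa)) if leaf_parent[i] == node]
        inner = ",".join(subs)
        if node is None:
            return f"({inner});"
        return f"({inner}){sup[node] * 100:g}"

    tree = parse_newick(render(None))
    return tree
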