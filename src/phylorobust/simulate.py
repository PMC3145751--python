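"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the situation the robustness pipeline is built for: a
two-partition alignment (a fast-evolving nucleotide partition with strong
among-site rate heterogeneity, and a conserved protein partition), a few
taxa on extremely long terminal branches, and a few "rogue" taxa whose
placement is unstable across bootstrap replicates.  Because sequences are
evolved under a known tree and a known discrete-gamma rate draw, the true
per-site rate class of every column is available as ground truth for the
rate-classification and site-stripping stages.

Rogueness has no canonical generative model; two operationalizations are
provided and documented: tree-level prune-and-regraft of a taxon across a
tree set (``inject_rogue``), and data-level signal erosion, replacing a
fraction of a taxon's characters with uniform random states
(``make_dataset`` with a rogue spec).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from ._rng import rng_for
from ._treeutil import regraft_leaf
from .io import Alignment, TreeSet, concatenate
from .models import SubstModel


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the synthetic analog of the comparative study: 40
    taxa, a 1000-column nucleotide partition under an HKY-style GTR with
    gamma shape 0.5 in 8 categories (strong rate heterogeneity), a
    300-column LG protein partition, 4 taxa with x10 terminal branches and
    4 rogue taxa.
    """

    n_taxa: int = 40
    tree_process: str = "yule"  # or "uniform"
    birth_rate: float = 1.0
    branch_length_mean: float = 0.1  # uniform-topology process only
    scale_root_to_tip: float | None = 0.5  # rescale mean root-to-tip depth
    n_sites_dna: int = 1000
    n_sites_protein: int = 300
    model_dna: SubstModel = field(
        default_factory=lambda: SubstModel.hky(
            kappa=4.0, freqs=(0.30, 0.20, 0.25, 0.25), alpha=0.5, k=8
        )
    )
    model_protein: SubstModel | None = field(default_factory=lambda: SubstModel.lg(alpha=0.5, k=8))
    long_branch_spec: tuple[int, float] = (4, 10.0)  # (n taxa, terminal multiplier)
    rogue_spec: tuple[int, float] = (4, 1.0)  # (n taxa, p_move per replicate)
    rogue_noise_frac: float = 0.75  # data-level rogue: fraction of sites randomized
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.long_branch_spec[1] < 1:
            raise ValueError("long-branch multiplier must be >= 1")
        if not 0 <= self.rogue_spec[1] <= 1:
            raise ValueError("p_move must be a probability")
        if min(self.n_sites_dna, 1) < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass
class SimulatedDataset:
    """Ground-truthed synthetic input for the full pipeline."""

    true_tree: dendropy.Tree
    alignment: Alignment
    true_site_rates: np.ndarray  # per current column
    true_site_class: np.ndarray
    outgroup: str
    long_branch_taxa: list[str]
    rogue_taxa: list[str]
    config: SimulationConfig | None


def _label(i: int) -> str:
    return f"T{i + 1:03d}"


def simulate_tree(cfg: SimulationConfig) -> dendropy.Tree:
    """Binary rooted tree with positive branch lengths; deterministic in seed.

    ``yule`` grows a constant-rate pure-birth tree (ultrametric); ``uniform``
    draws a uniform topology by random joins with iid exponential branch
    lengths.
    """
    rng = rng_for(cfg.seed, "simulate_tree")
    n = cfg.n_taxa
    tns = dendropy.TaxonNamespace([_label(i) for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=tns)

    if cfg.tree_process == "yule":
        lam = cfg.birth_rate
        root = tree.seed_node
        active = [root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)]
        while len(active) < n:
            wait = rng.exponential(1.0 / (lam * len(active)))
            for nd in active:
                nd.edge.length += wait
            idx = int(rng.integers(len(active)))
            parent = active.pop(idx)
            active.append(parent.new_child(edge_length=0.0))
            active.append(parent.new_child(edge_length=0.0))
        # one extra waiting time so pendant edges are positive
        wait = rng.exponential(1.0 / (lam * n))
        for nd in active:
            nd.edge.length += wait
        order = rng.permutation(n)
        for nd, i in zip(active, order):
            nd.taxon = tns[int(i)]
    elif cfg.tree_process == "uniform":
        nodes = []
        for i in range(n):
            nd = dendropy.Node(taxon=tns[i])
            nd.edge.length = float(rng.exponential(cfg.branch_length_mean))
            nodes.append(nd)
        while len(nodes) > 2:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            parent = dendropy.Node()
            parent.add_child(a)
            parent.add_child(b)
            parent.edge.length = float(rng.exponential(cfg.branch_length_mean))
            nodes.append(parent)
        for nd in nodes:
            tree.seed_node.add_child(nd)
            nd.edge.length = nd.edge.length
        tree.taxon_namespace = tns
    else:
        raise ValueError(f"unknown tree process {cfg.tree_process!r}")

    if cfg.scale_root_to_tip:
        depths = []
        for lf in tree.leaf_node_iter():
            d = 0.0
            nd = lf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            depths.append(d)
        factor = cfg.scale_root_to_tip / float(np.mean(depths))
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= factor
    return tree


def _evolve(tree, model: SubstModel, n_sites: int, rng) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Evolve states down the tree; returns per-leaf state codes + truth."""
    k, s = model.k, model.n_states
    rates = model.category_rates()
    classes = rng.integers(k, size=n_sites)
    site_rates = rates[classes]
    w, right, left = model.eigen()

    def pmat(t: float, r: float) -> np.ndarray:
        P = (right * np.exp(w * (r * t))[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    states: dict[int, np.ndarray] = {
        id(tree.seed_node): rng.choice(s, size=n_sites, p=model.freqs)
    }
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        parent_states = states[id(nd.parent_node)]
        t = nd.edge.length or 0.0
        child = np.empty(n_sites, dtype=int)
        for j in range(k):
            sel = classes == j
            if not sel.any():
                continue
            cum = np.cumsum(pmat(t, rates[j]), axis=1)
            u = rng.random(sel.sum())
            rows = cum[parent_states[sel]]
            child[sel] = (u[:, None] > rows).sum(axis=1)
        states[id(nd)] = child
    leaf_states = {lf.taxon.label: states[id(lf)] for lf in tree.leaf_node_iter()}
    # free internal states
    return leaf_states, site_rates, classes


def simulate_alignment(
    tree: dendropy.Tree,
    model: SubstModel,
    n_sites: int,
    seed: int,
    partition: str = "all",
) -> SimulatedDataset:
    """Evolve an alignment along ``tree`` with known per-site rate classes.

    Each column draws its category uniformly from the k discrete-gamma
    categories; the root state comes from the stationary frequencies and
    evolves down the tree with P(Q r t).
    """
    Q = model.rate_matrix()
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("rate matrix rows must sum to zero")
    rng = rng_for(seed, f"simulate_alignment:{partition}")
    leaf_states, site_rates, classes = _evolve(tree, model, n_sites, rng)
    labels = sorted(leaf_states)
    chars = np.array(list(model.states))
    data = np.stack([chars[leaf_states[l]] for l in labels])
    aln = Alignment(
        labels=labels,
        data=data,
        partitions={partition: np.arange(n_sites)},
        alphabet=model.alphabet,
    )
    return SimulatedDataset(
        true_tree=tree,
        alignment=aln,
        true_site_rates=site_rates,
        true_site_class=classes,
        outgroup="",
        long_branch_taxa=[],
        rogue_taxa=[],
        config=None,
    )


def inject_long_branches(tree: dendropy.Tree, taxa, multiplier: float) -> dendropy.Tree:
    """Scale the terminal branch of each named taxon by ``multiplier``."""
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    t = tree.clone(depth=1)
    leaves = {lf.taxon.label: lf for lf in t.leaf_node_iter()}
    unknown = [x for x in taxa if x not in leaves]
    if unknown:
        raise ValueError(f"unknown taxa: {unknown}")
    for x in taxa:
        leaves[x].edge.length = (leaves[x].edge.length or 0.0) * multiplier
    return t


def inject_rogue(treeset: TreeSet, taxon: str, p_move: float, seed: int) -> TreeSet:
    """Independently in each tree, with probability p_move prune the taxon
    and regraft it at the midpoint of a uniformly random branch."""
    if taxon not in treeset.taxon_universe:
        raise ValueError(f"taxon not in tree set: {taxon!r}")
    rng = rng_for(seed, f"inject_rogue:{taxon}")
    out = []
    for t in treeset:
        if rng.random() < p_move:
            out.append(regraft_leaf(t, taxon, rng))
        else:
            out.append(t.clone(depth=1))
    return TreeSet(trees=out)


def make_environmental_pool(
    reference: Sequence[tuple[str, str]],
    n_copies: int = 1,
    identity_targets: Sequence[float] = (1.0, 0.99, 0.90),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Mutated copies of reference sequences at controlled identities.

    For each reference and target identity q, emits ``n_copies`` copies with
    round((1-q)*L) random substitutions over the non-gap positions.
    """
    reference = list(reference)
    if not reference:
        raise ValueError("empty reference set")
    if any(not (0 <= q <= 1) for q in identity_targets):
        raise ValueError("identity targets must be in [0, 1]")
    rng = rng_for(seed, "make_environmental_pool")
    alphabet = "ACGT"
    pool = []
    for label, seq in reference:
        arr = np.array(list(seq.upper()))
        editable = np.where(arr != "-")[0]
        for q in identity_targets:
            for c in range(n_copies):
                n_sub = int(round((1.0 - q) * editable.size))
                copy = arr.copy()
                if n_sub > 0:
                    pos = rng.choice(editable, size=n_sub, replace=False)
                    for p in pos:
                        choices = [b for b in alphabet if b != copy[p]]
                        copy[p] = choices[int(rng.integers(len(choices)))]
                pool.append((f"ENV_{label}_q{int(round(q * 100)):02d}_{c}", "".join(copy)))
    return pool


def make_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Full synthetic dataset: tree, two-partition alignment, ground truth.

    Long branches are injected into the true tree *before* sequences are
    evolved, so fast-evolving taxa really are fast; rogue taxa have
    ``rogue_noise_frac`` of their characters replaced by uniform random
    states, eroding their phylogenetic signal so bootstrap placement
    becomes unstable.  One taxon ("OUT") diverges at the root and serves as
    the outgroup, attached at the same tip height so the whole true tree
    stays clock-like; it is excluded from both injected sets.
    """
    from dataclasses import replace as dc_replace

    rng = rng_for(cfg.seed, "make_dataset")
    ingroup_tree = simulate_tree(dc_replace(cfg, n_taxa=cfg.n_taxa - 1))
    # attach the outgroup at the root, at the same tip height (clock-like)
    depths = []
    for lf in ingroup_tree.leaf_node_iter():
        d, nd = 0.0, lf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(d)
    height = float(np.mean(depths))
    stem = 0.25 * height
    tns = ingroup_tree.taxon_namespace
    out_taxon = tns.new_taxon("OUT")
    tree = dendropy.Tree(taxon_namespace=tns)
    old_root = ingroup_tree.seed_node
    tree.seed_node.add_child(old_root)
    old_root.edge.length = stem
    tree.seed_node.new_child(taxon=out_taxon, edge_length=height + stem)
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    outgroup = "OUT"
    candidates = [l for l in labels if l != outgroup]
    n_lb, mult = cfg.long_branch_spec
    n_rg, _ = cfg.rogue_spec
    picked = rng.choice(len(candidates), size=n_lb + n_rg, replace=False)
    lb_taxa = sorted(candidates[i] for i in picked[:n_lb])
    rogue_taxa = sorted(candidates[i] for i in picked[n_lb:])

    true_tree = inject_long_branches(tree, lb_taxa, mult) if n_lb else tree

    parts = []
    rates_blocks = []
    class_blocks = []
    sim_dna = simulate_alignment(
        true_tree, cfg.model_dna, cfg.n_sites_dna, cfg.seed, partition="ssu"
    )
    parts.append(("ssu", sim_dna.alignment))
    rates_blocks.append(sim_dna.true_site_rates)
    class_blocks.append(sim_dna.true_site_class)
    if cfg.model_protein is not None and cfg.n_sites_protein > 0:
        sim_prot = simulate_alignment(
            true_tree, cfg.model_protein, cfg.n_sites_protein, cfg.seed, partition="actin"
        )
        parts.append(("actin", sim_prot.alignment))
        rates_blocks.append(sim_prot.true_site_rates)
        class_blocks.append(sim_prot.true_site_class)
    aln = concatenate(parts)

    # data-level rogues: replace a fraction of characters with random states
    if rogue_taxa and cfg.rogue_noise_frac > 0:
        noise_rng = rng_for(cfg.seed, "rogue_noise")
        for taxon in rogue_taxa:
            row = aln.labels.index(taxon)
            for pname, cols in aln.partitions.items():
                states = cfg.model_dna.states if pname == "ssu" else cfg.model_protein.states
                n_noise = int(round(cfg.rogue_noise_frac * cols.size))
                pos = noise_rng.choice(cols, size=n_noise, replace=False)
                aln.data[row, pos] = np.array(list(states))[
                    noise_rng.integers(len(states), size=n_noise)
                ]

    return SimulatedDataset(
        true_tree=true_tree,
        alignment=aln,
        true_site_rates=np.concatenate(rates_blocks),
        true_site_class=np.concatenate(class_blocks),
        outgroup=outgroup,
        long_branch_taxa=lb_taxa,
        rogue_taxa=rogue_taxa,
        config=cfg,
    )
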