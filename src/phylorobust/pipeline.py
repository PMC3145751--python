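"""Experiment-grid orchestration and sequence-pool dereplication.

``run_experiment`` reproduces, on one dataset, the comparative design of
the robustness study: from a base alignment it derives rate-stripped
variants (drop the fastest discrete-gamma classes from the nucleotide
partition), taxon-removal variants (drop the longest-branched and the most
unstable taxa, separately and combined) and an environmental-augmentation
variant (add a dereplicated pool of divergent copies); infers a best tree
and a bootstrap tree set per variant (built-in NJ stand-in, or ingested
files from an external ML/Bayesian run); and tabulates tree length,
treeness, mean leaf stability with its 95% CI, and clade support for a set
of named hypotheses across all variants.

Removal lists for the derived variants are frozen from the *base* variant's
trees before any derived variant is built.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from Bio import Align

from ._rng import rng_for
from ._treeutil import prune_taxa
from .io import Alignment, TreeSet, read_treeset, tree_to_newick, leaf_labels
from .inference import bootstrap_trees, jc_distance_matrix, nj_tree
from .likelihood import classify_site_rates, fit_gamma_shape, strip_rate_classes
from .models import SubstModel
from .simulate import SimulationConfig, make_dataset, make_environmental_pool
from .treestats import (
    CladeHypothesis,
    SupportTable,
    leaf_stability,
    rank_long_branches,
    rank_unstable,
    support_table,
    tree_length,
    treeness,
)

__all__ = [
    "pairwise_identity",
    "dereplicate",
    "remove_taxa",
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "render_report",
]


# ---------------------------------------------------------------------------
# Dereplication

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_internal_gap_score = -5.0
    a.extend_internal_gap_score = -1.0
    a.end_gap_score = 0.0
    return a


def _alignment_identity(aln, a: str, b: str) -> tuple[int, int]:
    """(matches, aligned columns) with terminal overhang columns excluded."""
    coords = np.asarray(aln.coordinates)
    steps = coords[:, 1:] - coords[:, :-1]  # (2, n_segments)
    segs = list(zip(steps[0], steps[1], coords[0, :-1], coords[1, :-1]))
    while segs and (segs[0][0] == 0 or segs[0][1] == 0):
        segs.pop(0)
    while segs and (segs[-1][0] == 0 or segs[-1][1] == 0):
        segs.pop()
    columns = 0
    matches = 0
    for dt, dq, t0, q0 in segs:
        columns += int(max(dt, dq))
        if dt == dq:
            sa = a[t0 : t0 + dt]
            sb = b[q0 : q0 + dq]
            matches += sum(x == y for x, y in zip(sa, sb))
    return matches, columns


def pairwise_identity(a: str, b: str, max_cooptimal: int = 64) -> float:
    """Global-alignment identity in [0, 1], terminal gap overhangs free.

    Match 1 / mismatch 0, affine internal gaps (open -5, extend -1), free
    end gaps; identity = matches / aligned columns, excluding the terminal
    overhang columns.  When several alignments tie on score, the identity
    of the one with the most matches (then fewest columns) is reported, so
    the value is well-defined; at most ``max_cooptimal`` co-optimal
    alignments are examined.
    """
    a = a.replace("-", "").upper()
    b = b.replace("-", "").upper()
    if not a or not b:
        raise ValueError("empty sequence")
    import itertools as _it

    best = None
    for aln in _it.islice(_aligner().align(a, b), max_cooptimal):
        matches, columns = _alignment_identity(aln, a, b)
        key = (matches, -columns)
        if best is None or key > best:
            best = key
    matches, neg_cols = best
    return matches / -neg_cols if neg_cols else 0.0


def dereplicate(
    seqs: list[tuple[str, str]],
    threshold: float = 0.98,
    order: str = "input",
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Greedy identity clustering of a sequence pool.

    Scanning in ``order`` ("input" or "length-desc"), a sequence is retained
    iff its identity to every already-retained sequence is below
    ``threshold``; otherwise it is absorbed by the first retained sequence
    reaching the threshold.  Returns the retained sequences and a map
    label -> representative label (retained sequences map to themselves).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if order == "length-desc":
        seqs = sorted(seqs, key=lambda p: (-len(p[1].replace("-", "")), p[0]))
    elif order != "input":
        raise ValueError(f"unknown order {order!r}")
    retained: list[tuple[str, str]] = []
    cluster: dict[str, str] = {}
    for label, seq in seqs:
        rep = None
        for rl, rs in retained:
            if pairwise_identity(seq, rs) >= threshold:
                rep = rl
                break
        if rep is None:
            retained.append((label, seq))
            cluster[label] = label
        else:
            cluster[label] = rep
    return retained, cluster


# ---------------------------------------------------------------------------
# Taxon removal


def remove_taxa(obj, taxa, min_remaining: int = 4):
    """Remove taxa from an Alignment or a TreeSet (degree-2 nodes suppressed)."""
    taxa = set(taxa)
    if isinstance(obj, Alignment):
        if obj.n_taxa - len(taxa & set(obj.labels)) < min_remaining:
            raise ValueError(f"removal would leave fewer than {min_remaining} taxa")
        return obj.remove_taxa(taxa)
    if isinstance(obj, TreeSet):
        universe = obj.taxon_universe
        if len(universe - taxa) < min_remaining:
            raise ValueError(f"removal would leave fewer than {min_remaining} taxa")
        return TreeSet(trees=[prune_taxa(t, taxa & set(leaf_labels(t))) for t in obj])
    raise TypeError(f"cannot remove taxa from {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Experiment grid

DEFAULT_VARIANTS = ("base", "-7", "-76", "-765", "-LB", "-us", "-LB-us", "+Env")

STRIP_LEVELS = {"-7": {7}, "-76": {7, 6}, "-765": {7, 6, 5}}


@dataclass
class ExperimentConfig:
    """Configuration of one comparative experiment grid."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    variants: tuple = DEFAULT_VARIANTS
    hypotheses: list[CladeHypothesis] | None = None  # default: derived from the true tree
    n_long_branch_remove: int | None = None  # default: the injected count
    n_unstable_remove: int | None = None
    n_bootstrap: int = 200
    k_classes: int = 8
    env_n_refs: int = 10
    env_identity_targets: tuple = (1.0, 0.99, 0.90)
    derep_threshold: float = 0.98
    stability_mode: str = "auto"
    ingest: dict | None = None  # variant -> (best_tree_path, treeset_path)
    seed: int = 0

    def __post_init__(self):
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("variant names must be unique")
        if "base" not in self.variants:
            self.variants = ("base",) + tuple(self.variants)


@dataclass
class ExperimentReport:
    """Per-variant metrics, cross-variant support table and manifests."""

    metrics: pd.DataFrame  # index variant: n_taxa, sites_*, tree_length, treeness, ...
    support: SupportTable
    manifests: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "metrics": self.metrics.reset_index().to_dict(orient="list"),
                "support_cells": self.support.cells.reset_index().to_dict(orient="list"),
                "support_raw": self.support.raw.reset_index().to_dict(orient="list"),
                "manifests": self.manifests,
                "provenance": self.provenance,
            },
            default=str,
        )

    @staticmethod
    def from_json(text: str) -> "ExperimentReport":
        d = json.loads(text)
        metrics = pd.DataFrame(d["metrics"]).set_index("variant")
        cells = pd.DataFrame(d["support_cells"]).set_index("hypothesis").astype(object)
        raw = pd.DataFrame(d["support_raw"]).set_index("hypothesis")
        return ExperimentReport(
            metrics=metrics,
            support=SupportTable(cells=cells, raw=raw),
            manifests=d["manifests"],
            provenance=d["provenance"],
        )


def _true_clade_hypotheses(dataset, rng) -> list[CladeHypothesis]:
    """Three mid-size true clades plus one deliberately scrambled group."""
    from ._treeutil import unrooted_view

    view = unrooted_view(dataset.true_tree)
    n = len(view.labels)
    label_of = {i: l for l, i in view.index.items()}
    clades = []
    for e in view.edges:
        pop = bin(e.mask).count("1")
        for mask, size in ((e.mask, pop), (view.full_mask & ~e.mask, n - pop)):
            members = {label_of[i] for i in range(n) if (mask >> i) & 1}
            if 3 <= size <= n // 2 and dataset.outgroup not in members:
                clades.append(members)
    clades.sort(key=lambda m: (-len(m), sorted(m)[0]))
    hyps = [
        CladeHypothesis(name=f"true_clade_{i + 1}", members=m, category="higher-level")
        for i, m in enumerate(clades[:3])
    ]
    pool = sorted(set(view.labels) - {dataset.outgroup})
    scrambled = set(rng.choice(pool, size=min(4, len(pool) - 1), replace=False))
    hyps.append(CladeHypothesis(name="scrambled", members=scrambled, category="proposed"))
    return hyps


def _infer(aln: Alignment, n_bootstrap: int, seed: int):
    D = jc_distance_matrix(aln)
    best = nj_tree(D, aln.labels)
    ts = bootstrap_trees(aln, n_bootstrap, seed=seed)
    return best, ts


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Build the variant grid, infer per-variant trees, compute all metrics."""
    dataset = make_dataset(cfg.sim)
    aln = dataset.alignment
    rng = rng_for(cfg.seed, "run_experiment")
    hypotheses = cfg.hypotheses or _true_clade_hypotheses(dataset, rng)

    variants: dict[str, tuple[Alignment, dendropy.Tree, TreeSet]] = {}
    manifests: dict = {
        "outgroup": dataset.outgroup,
        "injected_long_branch_taxa": dataset.long_branch_taxa,
        "injected_rogue_taxa": dataset.rogue_taxa,
    }

    def infer_variant(name: str, sub_aln: Alignment):
        if cfg.ingest and name in cfg.ingest:
            best_path, ts_path = cfg.ingest[name]
            best = read_treeset(best_path)[0]
            ts = read_treeset(ts_path)
        else:
            import zlib

            best, ts = _infer(
                sub_aln, cfg.n_bootstrap, seed=(cfg.seed ^ zlib.crc32(name.encode())) & 0x7FFFFFFF
            )
        variants[name] = (sub_aln, best, ts)

    if cfg.ingest:
        missing = [v for v in cfg.variants if v not in cfg.ingest]
        if missing:
            raise ValueError(f"ingest map missing variants: {missing}")

    infer_variant("base", aln)
    base_aln, base_best, base_ts = variants["base"]

    # site-rate classification on the base best tree (nucleotide partition)
    strip_variants = [v for v in cfg.variants if v in STRIP_LEVELS]
    if strip_variants:
        model0 = SubstModel.empirical_dna(aln, partition="ssu", k=cfg.k_classes)
        cols = aln.partitions["ssu"]
        alpha = fit_gamma_shape(aln, base_best, model0, cols=cols)
        model = model0.with_alpha(alpha)
        cls = classify_site_rates(aln, base_best, model, cols=cols)
        manifests["gamma_shape"] = alpha
        manifests["class_counts"] = np.bincount(cls.assigned_class, minlength=cfg.k_classes).tolist()
        for name in strip_variants:
            stripped = strip_rate_classes(aln, cls, STRIP_LEVELS[name], restrict_to="ssu")
            manifests[f"sites_removed_{name}"] = int(aln.n_cols - stripped.n_cols)
            infer_variant(name, stripped)

    # removal lists frozen from the base variant's trees
    n_lb = cfg.n_long_branch_remove
    if n_lb is None:
        n_lb = cfg.sim.long_branch_spec[0]
    n_us = cfg.n_unstable_remove
    if n_us is None:
        n_us = cfg.sim.rogue_spec[0]
    lb_list = rank_long_branches([("base", base_best)], dataset.outgroup, n_lb) if n_lb else []
    base_ls = leaf_stability(base_ts, mode=cfg.stability_mode, seed=cfg.seed)
    us_tab = base_ls.table.reset_index().sort_values(["stability", "taxon"])
    us_list = [t for t in us_tab["taxon"].head(n_us) if t != dataset.outgroup]
    manifests["removed_long_branch"] = lb_list
    manifests["removed_unstable"] = us_list

    if "-LB" in cfg.variants:
        infer_variant("-LB", remove_taxa(aln, lb_list))
    if "-us" in cfg.variants:
        infer_variant("-us", remove_taxa(aln, us_list))
    if "-LB-us" in cfg.variants:
        infer_variant("-LB-us", remove_taxa(aln, set(lb_list) | set(us_list)))

    if "+Env" in cfg.variants:
        refs = [
            l
            for l in aln.labels
            if l != dataset.outgroup and l not in dataset.rogue_taxa
        ][: cfg.env_n_refs]
        ssu_cols = aln.partitions.get("ssu", np.arange(aln.n_cols))
        ref_seqs = [(l, "".join(aln.data[aln.labels.index(l), ssu_cols])) for l in refs]
        pool = make_environmental_pool(
            ref_seqs, identity_targets=cfg.env_identity_targets, seed=cfg.seed
        )
        retained, cluster = dereplicate(pool, threshold=cfg.derep_threshold)
        manifests["env_pool_size"] = len(pool)
        manifests["env_retained"] = [l for l, _ in retained]
        manifests["env_clusters"] = cluster
        env_rows = np.full((len(retained), aln.n_cols), "-", dtype="<U1")
        for r, (_, seq) in enumerate(retained):
            env_rows[r, ssu_cols] = list(seq)
        env_aln = Alignment(
            labels=aln.labels + [l for l, _ in retained],
            data=np.vstack([aln.data, env_rows]),
            partitions={k: v.copy() for k, v in aln.partitions.items()},
            source_index=aln.source_index.copy(),
            alphabet=aln.alphabet,
        )
        infer_variant("+Env", env_aln)

    # per-variant metrics + support tabulation
    rows = []
    recon = []
    for name in cfg.variants:
        sub_aln, best, ts = variants[name]
        rep = base_ls if name == "base" else leaf_stability(ts, mode=cfg.stability_mode, seed=cfg.seed)
        row = {
            "variant": name,
            "n_taxa": sub_aln.n_taxa,
            "tree_length": tree_length(best),
            "treeness": treeness(best),
            "mean_leaf_stability": rep.mean,
            "ci95": rep.ci95_halfwidth,
        }
        for pname, cols in sub_aln.partitions.items():
            row[f"sites_{pname}"] = int(cols.size)
        rows.append(row)
        recon.append((name, best, ts))
    metrics = pd.DataFrame(rows).set_index("variant")
    sup = support_table(hypotheses, recon)

    provenance = {
        "seed": cfg.seed,
        "n_bootstrap": cfg.n_bootstrap,
        "inference": "ingest" if cfg.ingest else "nj-jc-bootstrap",
        "sim": {
            k: v
            for k, v in asdict(cfg.sim).items()
            if not isinstance(v, (SubstModel, np.ndarray))
        },
    }
    return ExperimentReport(metrics=metrics, support=sup, manifests=manifests, provenance=provenance)


def render_report(rep: ExperimentReport, outdir, formats=("tsv", "markdown", "json")) -> list[str]:
    """Write the metrics table, support table and manifests to ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    written = []
    metrics = rep.metrics.rename(
        columns={
            "tree_length": "Tree Length",
            "treeness": "Treeness",
            "mean_leaf_stability": "LStability",
            "ci95": "95% CI",
        }
    )
    if "tsv" in formats:
        p = os.path.join(outdir, "metrics.tsv")
        metrics.to_csv(p, sep="\t")
        written.append(p)
        p = os.path.join(outdir, "support.tsv")
        rep.support.to_tsv(p)
        written.append(p)
    if "markdown" in formats:
        p = os.path.join(outdir, "metrics.md")
        with open(p, "w") as fh:
            fh.write(metrics.to_markdown())
        written.append(p)
        p = os.path.join(outdir, "support.md")
        with open(p, "w") as fh:
            fh.write(rep.support.to_markdown())
        written.append(p)
    if "json" in formats:
        p = os.path.join(outdir, "report.json")
        with open(p, "w") as fh:
            fh.write(rep.to_json())
        written.append(p)
    p = os.path.join(outdir, "manifests.json")
    with open(p, "w") as fh:
        json.dump(rep.manifests, fh, indent=1, default=str)
    written.append(p)
    return written
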