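"""Felsenstein-pruning likelihoods and empirical-Bayes site-rate classes.

The engine computes, for every alignment column c and discrete-gamma
category j, the conditional likelihood L_{c,j} of the column given the tree
and the model with all sites evolving at category rate r_j.  The site
log-likelihood marginalizes over categories with a uniform prior,

    lnL_c = ln( (1/k) * sum_j L_{c,j} ),

and the per-column posterior over categories,

    P(j | c) = L_{c,j} / sum_m L_{c,m},

drives the empirical-Bayes rate classification used for fast-site
stripping: class 0 is the slowest category, class k-1 the fastest.

Missing characters ('-', '?', 'N'/'X') are marginalized via partial vectors
of ones; IUPAC ambiguity codes set the compatible states.  Partial
likelihoods are rescaled per node with log accumulators, so alignments with
hundreds of taxa do not underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .io import IUPAC_DNA, MISSING_DNA, MISSING_PROTEIN, Alignment
from .models import SubstModel

__all__ = [
    "SiteLikelihoods",
    "SiteRateClassification",
    "site_likelihoods",
    "total_loglik",
    "classify_site_rates",
    "strip_rate_classes",
    "fit_gamma_shape",
]


def _char_vectors(model: SubstModel) -> dict[str, np.ndarray]:
    s = model.n_states
    states = model.states
    table: dict[str, np.ndarray] = {}
    if model.alphabet == "dna":
        for ch, members in IUPAC_DNA.items():
            v = np.zeros(s)
            for m in members:
                v[states.index(m)] = 1.0
            table[ch] = v
        table["U"] = table["T"]
        missing = MISSING_DNA
    else:
        for i, ch in enumerate(states):
            v = np.zeros(s)
            v[i] = 1.0
            table[ch] = v
        missing = MISSING_PROTEIN
    ones = np.ones(s)
    for ch in missing:
        table[ch] = ones
    return table


def encode_leaf_partials(aln: Alignment, model: SubstModel, cols: np.ndarray | None = None) -> np.ndarray:
    """(n_taxa, n_cols, s) leaf partial-likelihood vectors."""
    table = _char_vectors(model)
    data = aln.data if cols is None else aln.data[:, cols]
    s = model.n_states
    out = np.empty((data.shape[0], data.shape[1], s))
    for ch in np.unique(data):
        v = table.get(ch)
        if v is None:
            warnings.warn(f"character {ch!r} not in alphabet; treated as missing")
            v = np.ones(s)
        out[data == ch] = v
    return out


@dataclass
class SiteLikelihoods:
    """Per-column log-likelihoods and per-category log-likelihoods."""

    site_lnl: np.ndarray  # (n_sites,)
    class_loglik: np.ndarray  # (n_sites, k)
    k: int

    @property
    def total(self) -> float:
        return float(self.site_lnl.sum())


def site_likelihoods(
    aln: Alignment,
    tree: dendropy.Tree,
    model: SubstModel,
    cols: np.ndarray | None = None,
) -> SiteLikelihoods:
    """Pruning-algorithm likelihood of every column under every rate class."""
    labels = set(aln.labels)
    tree_leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in tree_leaves if l not in labels]
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {missing}")

    leaf_partials = encode_leaf_partials(aln, model, cols)
    row_of = {l: i for i, l in enumerate(aln.labels)}
    n_sites = leaf_partials.shape[1]
    k, s = model.k, model.n_states
    w, right, left = model.eigen()
    rates = model.category_rates()

    def pmats(t: float) -> np.ndarray:
        out = np.empty((k, s, s))
        for j, r in enumerate(rates):
            P = (right * np.exp(w * (r * t))[None, :]) @ left
            np.clip(P, 0.0, None, out=P)
            out[j] = P
        return out

    partials: dict[int, np.ndarray] = {}
    scalers: dict[int, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            p = np.broadcast_to(leaf_partials[row_of[nd.taxon.label]], (k, n_sites, s)).copy()
            sc = np.zeros((k, n_sites))
        else:
            p = np.ones((k, n_sites, s))
            sc = np.zeros((k, n_sites))
            for ch in nd.child_nodes():
                P = pmats(ch.edge.length or 0.0)
                cp = partials.pop(id(ch))
                sc += scalers.pop(id(ch))
                p *= np.einsum("kab,knb->kna", P, cp)
            mx = p.max(axis=2)
            nz = mx > 0
            p = np.divide(p, np.where(nz, mx, 1.0)[..., None])
            with np.errstate(divide="ignore"):
                sc += np.where(nz, np.log(np.where(nz, mx, 1.0)), -np.inf)
        partials[id(nd)] = p
        scalers[id(nd)] = sc

    root = tree.seed_node
    L = partials[id(root)] @ model.freqs  # (k, n_sites)
    with np.errstate(divide="ignore"):
        class_loglik = (np.log(L) + scalers[id(root)]).T  # (n_sites, k)
    site_lnl = logsumexp(class_loglik, axis=1) - np.log(k)
    return SiteLikelihoods(site_lnl=site_lnl, class_loglik=class_loglik, k=k)


def total_loglik(
    aln: Alignment,
    tree: dendropy.Tree,
    model: SubstModel | dict[str, SubstModel],
) -> float:
    """Sum of site log-likelihoods; partitioned models sum per partition."""
    if isinstance(model, dict):
        total = 0.0
        for name, mdl in model.items():
            total += site_likelihoods(aln, tree, mdl, cols=aln.partitions[name]).total
        return total
    return site_likelihoods(aln, tree, model).total


@dataclass
class SiteRateClassification:
    """Empirical-Bayes posterior rate-category assignment per column."""

    posteriors: np.ndarray  # (n_sites, k)
    posterior_mean_rate: np.ndarray  # (n_sites,)
    assigned_class: np.ndarray  # (n_sites,) ints in 0..k-1
    k: int
    category_rates: np.ndarray
    columns: np.ndarray  # alignment column indices classified (0-based)
    alignment_checksum: str

    def to_frame(self, aln: Alignment | None = None) -> pd.DataFrame:
        """Report table: 1-based original index, partition, rate, class, posteriors."""
        d = {
            "column": self.columns + 1,
            "posterior_mean_rate": self.posterior_mean_rate,
            "assigned_class": self.assigned_class,
        }
        if aln is not None:
            d["original_column"] = aln.source_index[self.columns] + 1
            part = aln.partition_of()
            d["partition"] = part[self.columns]
        frame = pd.DataFrame(d)
        for j in range(self.k):
            frame[f"p_class{j}"] = self.posteriors[:, j]
        return frame


def classify_site_rates(
    aln: Alignment,
    tree: dendropy.Tree,
    model: SubstModel,
    cols: np.ndarray | None = None,
) -> SiteRateClassification:
    """Assign each column to a discrete-gamma rate class (MAP, ties to slower)."""
    if model.k < 2:
        raise ValueError("classification needs k >= 2 rate categories")
    cols = np.arange(aln.n_cols) if cols is None else np.asarray(cols, int)
    sl = site_likelihoods(aln, tree, model, cols=cols)
    ll = sl.class_loglik
    if not np.all(np.isfinite(ll.max(axis=1))):
        bad = np.where(~np.isfinite(ll.max(axis=1)))[0]
        raise ValueError(f"zero total likelihood at columns {cols[bad][:5] + 1} (1-based)")
    post = np.exp(ll - ll.max(axis=1, keepdims=True))
    post /= post.sum(axis=1, keepdims=True)
    rates = model.category_rates()
    return SiteRateClassification(
        posteriors=post,
        posterior_mean_rate=post @ rates,
        assigned_class=np.argmax(post, axis=1),  # argmax takes the first = slower class on ties
        k=model.k,
        category_rates=rates,
        columns=cols,
        alignment_checksum=aln.checksum(),
    )


def strip_rate_classes(
    aln: Alignment,
    cls: SiteRateClassification,
    remove: set[int],
    restrict_to: str | None = None,
) -> Alignment:
    """Delete columns assigned to the given rate classes.

    ``restrict_to`` limits the deletion to one partition (the usual mode:
    strip the fast classes from the nucleotide partition and leave the
    protein partition untouched).
    """
    if cls.alignment_checksum != aln.checksum():
        raise ValueError("classification was built on a different alignment")
    remove = set(remove)
    if not remove <= set(range(cls.k)):
        raise ValueError(f"classes out of range: {sorted(remove - set(range(cls.k)))}")
    flagged = cls.columns[np.isin(cls.assigned_class, sorted(remove))]
    if restrict_to is not None:
        flagged = np.intersect1d(flagged, aln.partitions[restrict_to])
    keep = np.setdiff1d(np.arange(aln.n_cols), flagged)
    return aln.take_columns(keep)


def fit_gamma_shape(
    aln: Alignment,
    tree: dendropy.Tree,
    model: SubstModel,
    bounds: tuple[float, float] = (0.02, 20.0),
    cols: np.ndarray | None = None,
) -> float:
    """Maximum-likelihood gamma shape by bounded 1-D search (tol 1e-4)."""
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lo < hi")

    def neg(alpha: float) -> float:
        val = site_likelihoods(aln, tree, model.with_alpha(alpha), cols=cols).site_lnl.sum()
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite likelihood at alpha={alpha}")
        return -val

    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4})
    alpha_hat = float(res.x)
    if alpha_hat - lo < 1e-2 * (hi - lo) and neg(lo) <= res.fun + 1e-9:
        warnings.warn("gamma shape pinned to lower bound (little or no rate variation signal)")
        return lo
    return alpha_hat
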