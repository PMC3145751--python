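"""Alignment and tree-set containers and their on-disk formats.

Alignments are taxa x columns character matrices carrying named, disjoint
column partitions (e.g. an rDNA partition and a protein partition) and a
per-column record of the original column number, so that site-stripping
operations stay traceable back to the source alignment.  Trees are dendropy
``Tree`` objects; a :class:`TreeSet` is an ordered collection of them (one
bootstrap sample, or one tree per reconstruction).

Formats: FASTA and relaxed sequential PHYLIP for alignments (via Biopython),
Newick with one-or-many trees per file (via dendropy).  Support values are
read from numeric internal-node labels (RAxML style).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "TreeSet",
    "read_alignment",
    "write_alignment",
    "read_treeset",
    "write_treeset",
    "parse_newick",
    "tree_to_newick",
    "concatenate",
    "write_site_map",
]

#: characters treated as missing data (fully marginalized in likelihoods)
MISSING_DNA = set("-?NXnx.")
MISSING_PROTEIN = set("-?Xx.")

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}

AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Character matrix over named taxa with partitions and source columns.

    Parameters
    ----------
    labels : list of str
        Unique taxon labels, one per row.
    data : ndarray of single characters, shape (n_taxa, n_cols)
    partitions : dict mapping name -> ndarray of column indices (0-based)
        Disjoint, ordered; together they cover a subset of the columns.
    source_index : ndarray of int
        Original (0-based) column number of each current column; user-facing
        reports convert to 1-based.
    alphabet : {"dna", "protein"}
    """

    labels: list[str]
    data: np.ndarray
    partitions: dict[str, np.ndarray] = field(default_factory=dict)
    source_index: np.ndarray | None = None
    alphabet: str = "dna"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2:
            raise AlignmentError("alignment data must be 2-D")
        if len(self.labels) != self.data.shape[0]:
            raise AlignmentError("label count does not match row count")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dupes}")
        if not self.partitions:
            self.partitions = {"all": np.arange(self.data.shape[1])}
        self.partitions = {k: np.asarray(v, dtype=int) for k, v in self.partitions.items()}
        seen = np.concatenate([v for v in self.partitions.values()]) if self.partitions else []
        if len(seen) != len(set(seen.tolist())):
            raise AlignmentError("partitions overlap")
        if self.source_index is None:
            self.source_index = np.arange(self.data.shape[1])
        self.source_index = np.asarray(self.source_index, dtype=int)
        if self.source_index.shape != (self.data.shape[1],):
            raise AlignmentError("source_index length must equal column count")

    # -- basic accessors -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def sequence(self, label: str) -> str:
        return "".join(self.row(label))

    def partition_of(self) -> np.ndarray:
        """Per-column partition name ('' for columns in no partition)."""
        out = np.full(self.n_cols, "", dtype=object)
        for name, cols in self.partitions.items():
            out[cols] = name
        return out

    # -- derived alignments ----------------------------------------------
    def take_columns(self, cols: np.ndarray) -> "Alignment":
        """New alignment restricted to ``cols`` (kept in the given order)."""
        cols = np.asarray(cols, dtype=int)
        pos = {c: i for i, c in enumerate(cols.tolist())}
        parts = {}
        for name, pcols in self.partitions.items():
            kept = np.array([pos[c] for c in pcols.tolist() if c in pos], dtype=int)
            parts[name] = np.sort(kept)
        return Alignment(
            labels=list(self.labels),
            data=self.data[:, cols],
            partitions=parts,
            source_index=self.source_index[cols],
            alphabet=self.alphabet,
        )

    def remove_taxa(self, taxa) -> "Alignment":
        taxa = set(taxa)
        unknown = taxa - set(self.labels)
        if unknown:
            raise AlignmentError(f"unknown taxa: {sorted(unknown)}")
        keep = [i for i, l in enumerate(self.labels) if l not in taxa]
        return Alignment(
            labels=[self.labels[i] for i in keep],
            data=self.data[keep],
            partitions={k: v.copy() for k, v in self.partitions.items()},
            source_index=self.source_index.copy(),
            alphabet=self.alphabet,
        )

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update("|".join(self.labels).encode())
        h.update(self.data.tobytes())
        return h.hexdigest()[:16]


def _normalize_label(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip())


def _guess_alphabet(data: np.ndarray) -> str:
    chars = set(np.unique(data).tolist()) - {"-", "?", ".", "N", "X"}
    return "dna" if chars <= set("ACGTU" "RYSWKMBDHV") else "protein"


def read_alignment(path, format: str = "fasta", alphabet: str | None = None) -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment.

    All characters are upper-cased; 'U' is mapped to 'T' for DNA.  Ragged
    sequence lengths or duplicate labels raise :class:`AlignmentError`.
    """
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise ValueError(f"unsupported format: {format!r}")
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    labels = [_normalize_label(r.id if r.id else r.description) for r in records]
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        ref = len(records[0].seq)
        bad = next(r.id for r in records if len(r.seq) != ref)
        raise AlignmentError(f"ragged alignment: taxon {bad!r} has a different length")
    data = np.array([list(str(r.seq).upper()) for r in records], dtype="<U1")
    if alphabet is None:
        alphabet = _guess_alphabet(data)
    if alphabet == "dna":
        data[data == "U"] = "T"
    return Alignment(labels=labels, data=data, alphabet=alphabet)


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    """Write FASTA or relaxed sequential PHYLIP; parseable by read_alignment."""
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise ValueError(f"unsupported format: {format!r}")
    records = [
        SeqRecord(Seq("".join(row)), id=label, description="")
        for label, row in zip(aln.labels, aln.data)
    ]
    SeqIO.write(records, str(path), fmt)


def write_site_map(aln: Alignment, path) -> None:
    """Sidecar TSV mapping kept columns to original columns (1-based)."""
    part = aln.partition_of()
    with open(path, "w") as fh:
        fh.write("kept_index\toriginal_index\tpartition\n")
        for i in range(aln.n_cols):
            fh.write(f"{i + 1}\t{aln.source_index[i] + 1}\t{part[i]}\n")


def concatenate(parts: list[tuple[str, Alignment]]) -> Alignment:
    """Append partition alignments column-wise into one partitioned alignment.

    Taxa missing from a partition get an all-gap block there; the returned
    alignment records them in ``missing_report`` (taxon -> list of partition
    names with no data).
    """
    if not parts:
        raise AlignmentError("no partitions to concatenate")
    names = [n for n, _ in parts]
    if len(set(names)) != len(names):
        raise AlignmentError("duplicate partition names")
    labels: list[str] = []
    for _, a in parts:
        for l in a.labels:
            if l not in labels:
                labels.append(l)
    blocks = []
    partitions = {}
    source = []
    missing: dict[str, list[str]] = {}
    offset = 0
    for name, a in parts:
        block = np.full((len(labels), a.n_cols), "-", dtype="<U1")
        index = {l: i for i, l in enumerate(a.labels)}
        for j, l in enumerate(labels):
            if l in index:
                block[j] = a.data[index[l]]
            else:
                missing.setdefault(l, []).append(name)
        blocks.append(block)
        partitions[name] = np.arange(offset, offset + a.n_cols)
        source.extend((a.source_index + offset).tolist())
        offset += a.n_cols
    out = Alignment(
        labels=labels,
        data=np.concatenate(blocks, axis=1),
        partitions=partitions,
        source_index=np.array(source),
        alphabet=parts[0][1].alphabet if len(parts) == 1 else "mixed"
        if len({a.alphabet for _, a in parts}) > 1
        else parts[0][1].alphabet,
    )
    out.missing_report = missing  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Trees


class NewickError(ValueError):
    pass


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick statement into a dendropy tree.

    Numeric internal-node labels are interpreted as support values and
    attached to ``edge.head_node`` as ``node.support`` (scale preserved
    as written; RAxML writes 0..100).
    """
    tree = dendropy.Tree.get(
        data=text if text.rstrip().endswith(";") else text + ";",
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    for nd in tree.preorder_node_iter():
        nd.support = None
        if not nd.is_leaf() and nd.label is not None:
            try:
                nd.support = float(nd.label)
            except ValueError:
                pass
    return tree


def tree_to_newick(tree: dendropy.Tree, *, supports: bool = True) -> str:
    """Serialize to Newick; supports re-emitted as internal-node labels."""
    t = tree.clone(depth=1)
    for nd in t.preorder_node_iter():
        sup = getattr(nd, "support", None)
        if not nd.is_leaf() and supports and sup is not None:
            nd.label = format(sup, "g")
    s = t.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    return s.strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


@dataclass
class TreeSet:
    """Ordered collection of trees over a common taxon universe."""

    trees: list[dendropy.Tree]

    def __post_init__(self):
        if not self.trees:
            raise NewickError("TreeSet must contain at least one tree")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def taxon_universe(self) -> set[str]:
        out: set[str] = set()
        for t in self.trees:
            out.update(leaf_labels(t))
        return out


def read_treeset(path) -> TreeSet:
    """Read a Newick file with one-or-many trees (newline or ';' separated)."""
    with open(path) as fh:
        text = fh.read()
    trees = []
    statement = []
    line_no = start_line = 1
    for ch in text:
        if ch == "\n":
            line_no += 1
        statement.append(ch)
        if ch == ";":
            stmt = "".join(statement).strip()
            statement = []
            if stmt:
                try:
                    trees.append(parse_newick(stmt))
                except Exception as exc:
                    raise NewickError(
                        f"{path}: failed to parse tree starting at line {start_line}: {exc}"
                    ) from exc
            start_line = line_no
    tail = "".join(statement).strip()
    if tail:
        raise NewickError(
            f"{path}: unterminated or unbalanced tree statement starting at line {start_line}"
        )
    if not trees:
        raise NewickError(f"{path}: no trees found")
    return TreeSet(trees=trees)


def write_treeset(ts: TreeSet, path) -> None:
    """Write Newick, one tree per line."""
    with open(path, "w") as fh:
        for t in ts:
            fh.write(tree_to_newick(t) + "\n")
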