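"""Readers, writers and validated domain types for alignments, trees and rate-matrix files.

Supported formats: FASTA and relaxed sequential PHYLIP for alignments
(via Biopython), Newick for trees (via dendropy), and PAML-style ``.dat``
files for empirical amino-acid replacement matrices (190 lower-triangle
exchangeabilities followed by 20 equilibrium frequencies).
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical amino-acid ordering used by PAML .dat files and throughout this package.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: Residue codes treated as missing data (uniform conditional likelihood).
MISSING_RESIDUES = set("-XBZ?.*")
#: Integer code assigned to missing residues in encoded alignments.
MISSING_CODE = 20


class FormatError(ValueError):
    """A file could not be parsed in the requested dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A multiple protein alignment: ``n`` taxa by ``s`` aligned sites.

    Rows hold upper-cased residue strings over the 20 standard amino acids
    plus gap/ambiguity codes; ambiguity codes are preserved verbatim and
    treated as missing data downstream.
    """

    name: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        self.rows = [r.upper() for r in self.rows]
        self.validate()

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def s(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def validate(self) -> None:
        if not self.taxa:
            raise ValidationError(f"alignment {self.name!r} has no sequences")
        if len(self.taxa) != len(self.rows):
            raise ValidationError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError(f"duplicate taxon name in alignment {self.name!r}")
        s = len(self.rows[0])
        if s < 1:
            raise ValidationError("alignment has zero sites")
        for name, row in zip(self.taxa, self.rows):
            if len(row) != s:
                raise FormatError(
                    f"ragged alignment {self.name!r}: {name!r} has length "
                    f"{len(row)}, expected {s}"
                )
            bad = set(row) - set(AMINO_ACIDS) - MISSING_RESIDUES
            if bad:
                raise ValidationError(
                    f"unknown residue codes {sorted(bad)} in sequence {name!r}"
                )

    def codes(self) -> np.ndarray:
        """Encode residues as an (n, s) uint8 array; missing/ambiguous -> 20."""
        out = np.full((self.n, self.s), MISSING_CODE, dtype=np.uint8)
        lut = np.full(256, MISSING_CODE, dtype=np.uint8)
        for aa, i in AA_INDEX.items():
            lut[ord(aa)] = i
        for r, row in enumerate(self.rows):
            out[r] = lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
        return out

    def subset(self, taxa: Sequence[str], name: str | None = None) -> "Alignment":
        """Project onto a subset of taxa, keeping every column."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise ValidationError(f"unknown taxa in subset: {missing}")
        return Alignment(
            name=name or self.name,
            taxa=list(taxa),
            rows=[self.rows[index[t]] for t in taxa],
        )


@dataclass
class AlignmentSet:
    """An ordered collection of uniquely named alignments."""

    alignments: list[Alignment]

    def __post_init__(self) -> None:
        if not self.alignments:
            raise ValidationError("empty alignment set")
        names = [a.name for a in self.alignments]
        if len(set(names)) != len(names):
            raise ValidationError("alignment names must be unique")

    @property
    def c(self) -> int:
        return len(self.alignments)

    def __iter__(self):
        return iter(self.alignments)

    def __len__(self) -> int:
        return len(self.alignments)


def read_alignment(path: str | Path, format: str = "fasta", name: str | None = None) -> Alignment:
    """Read one multiple alignment from ``path`` in FASTA or relaxed PHYLIP."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format not in ("fasta", "phylip"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    try:
        if format == "fasta":
            records = list(SeqIO.parse(str(path), "fasta"))
        else:
            records = list(AlignIO.read(str(path), "phylip-relaxed"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"could not parse {path} as {format}: {exc}") from exc
    if not records:
        raise FormatError(f"no sequences found in {path}")
    return Alignment(
        name=name or path.stem,
        taxa=[str(r.id) for r in records],
        rows=[str(r.seq) for r in records],
    )


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    path = Path(path)
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.taxa, aln.rows)
    ]
    if format == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif format == "phylip":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "phylip-relaxed")
    else:
        raise ValueError(f"unsupported alignment format: {format!r}")


def read_alignment_dir(path: str | Path, format: str = "fasta") -> AlignmentSet:
    """Read every alignment file in a directory (sorted by name)."""
    path = Path(path)
    exts = {"fasta": (".fa", ".fasta", ".faa"), "phylip": (".phy", ".phylip")}[format]
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in exts)
    if not files:
        raise FormatError(f"no {format} files found in {path}")
    return AlignmentSet([read_alignment(p, format) for p in files])


# ---------------------------------------------------------------------------
# Replacement-matrix files (PAML .dat layout)
# ---------------------------------------------------------------------------

@dataclass
class MatrixFile:
    """A replacement matrix as stored on disk: 190 exchangeabilities + 20 frequencies.

    ``exchangeabilities`` holds the strict lower triangle of the symmetric
    exchangeability matrix R in row-major PAML order (row i lists the pairs
    with amino acids 1..i-1 in the order A R N D C Q E G H I L K M F P S T W Y V).
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float).ravel()
        self.frequencies = np.asarray(self.frequencies, dtype=float).ravel()
        if self.exchangeabilities.size != 190:
            raise ValidationError(
                f"expected 190 exchangeabilities, got {self.exchangeabilities.size}"
            )
        if self.frequencies.size != 20:
            raise ValidationError(f"expected 20 frequencies, got {self.frequencies.size}")
        if np.any(self.exchangeabilities <= 0):
            raise ValidationError("exchangeabilities must be strictly positive")
        if np.any(self.frequencies <= 0):
            raise ValidationError("frequencies must be strictly positive")
        self.frequencies = self.frequencies / self.frequencies.sum()

    def r_matrix(self) -> np.ndarray:
        """The full symmetric 20x20 exchangeability matrix (zero diagonal)."""
        R = np.zeros((20, 20))
        R[np.tril_indices(20, k=-1)] = self.exchangeabilities
        return R + R.T

    @classmethod
    def from_r_matrix(cls, R: np.ndarray, pi: np.ndarray, name: str = "") -> "MatrixFile":
        R = np.asarray(R, dtype=float)
        return cls(R[np.tril_indices(20, k=-1)], np.asarray(pi, dtype=float), name=name)


def lower_triangle(R: np.ndarray) -> np.ndarray:
    """Flatten a symmetric 20x20 matrix to its 190 lower-triangle entries (PAML order)."""
    return np.asarray(R, dtype=float)[np.tril_indices(20, k=-1)]


def read_matrix(path: str | Path, name: str | None = None) -> MatrixFile:
    """Read a PAML-style .dat matrix file: 19 triangle rows then 20 frequencies."""
    path = Path(path)
    try:
        tokens = path.read_text().split()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if len(tokens) != 210:
        raise FormatError(
            f"{path}: expected 210 numeric tokens (190 exchangeabilities + "
            f"20 frequencies), found {len(tokens)}"
        )
    try:
        values = np.array([float(t) for t in tokens])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric token: {exc}") from exc
    return MatrixFile(values[:190], values[190:], name=name or path.stem)


def write_matrix(mat: MatrixFile, path: str | Path, precision: int = 6) -> None:
    """Write a MatrixFile in PAML .dat layout.

    Exchangeabilities below the print resolution are floored at one unit in
    the last written digit so the file remains strictly positive on re-read.
    """
    floor = 10.0 ** (-precision)
    lines = []
    pos = 0
    for i in range(1, 20):
        row = mat.exchangeabilities[pos : pos + i]
        pos += i
        lines.append(" ".join(f"{max(v, floor):.{precision}f}" for v in row))
    lines.append("")
    lines.append(" ".join(f"{v:.{precision}f}" for v in mat.frequencies))
    Path(path).write_text("\n".join(lines) + "\n")


def builtin_matrix(name: str) -> MatrixFile:
    """Load one of the shipped empirical matrices ('lg' or 'jtt')."""
    data_dir = Path(__file__).parent / "data"
    p = data_dir / f"{name.lower()}.dat"
    if not p.exists():
        raise ValueError(f"no builtin matrix {name!r}; available: lg, jtt")
    return read_matrix(p, name=name.lower())


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class PhyloTree:
    """An unrooted binary phylogeny with branch lengths, stored as parent arrays.

    Internally the tree is held in a rooted representation: node 0 is an
    arbitrary root (an internal node of degree 3 for n >= 3, or one of the two
    leaves for n = 2); every other node stores its parent and the length of
    the edge to it.  The likelihood of a time-reversible model does not depend
    on this root choice.

    Attributes
    ----------
    parent : (N,) int array, -1 for the root
    blen : (N,) float array, branch length to parent (0.0 for the root)
    labels : list of str or None per node; leaves carry taxon names
    """

    def __init__(self, parent: np.ndarray, blen: np.ndarray, labels: list):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        self.labels = list(labels)
        if np.any(self.blen < 0):
            raise ValidationError("negative branch length")
        self._children: list[list[int]] = [[] for _ in self.labels]
        for v, u in enumerate(self.parent):
            if u >= 0:
                self._children[u].append(v)
        leaves = [l for l in self.labels if l is not None]
        if len(set(leaves)) != len(leaves):
            raise ValidationError("duplicate leaf label")

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def leaf_labels(self) -> list[str]:
        return [l for l in self.labels if l is not None]

    def children(self, u: int) -> list[int]:
        return self._children[u]

    def is_leaf(self, u: int) -> bool:
        return not self._children[u]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            u = stack.pop()
            order.append(u)
            stack.extend(self._children[u])
        order.reverse()
        return order

    def edges(self) -> list[tuple[int, int, float]]:
        """All (parent, child, length) edges of the rooted representation."""
        return [
            (int(self.parent[v]), v, float(self.blen[v]))
            for v in range(self.n_nodes)
            if self.parent[v] >= 0
        ]

    def total_length(self) -> float:
        return float(self.blen.sum())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.blen.copy(), list(self.labels))

    # -- Newick conversion --------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        def fmt(u: int) -> str:
            if self.is_leaf(u):
                body = self.labels[u]
            else:
                body = "(" + ",".join(fmt(c) for c in self._children[u]) + ")"
            if self.parent[u] >= 0:
                return f"{body}:{self.blen[u]:.{precision}g}"
            return body

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return fmt(0) + ";"
        finally:
            sys.setrecursionlimit(old)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return read_newick(text)

    def _dendropy(self, namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        if namespace is None:
            namespace = dendropy.TaxonNamespace()
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick", taxon_namespace=namespace
        )

    def rf_distance(self, other: "PhyloTree") -> int:
        """Unweighted Robinson-Foulds distance (unrooted bipartitions)."""
        if set(self.leaf_labels) != set(other.leaf_labels):
            raise ValidationError("trees have different leaf sets")
        ns = dendropy.TaxonNamespace()
        t1 = self._dendropy(ns)
        t2 = other._dendropy(ns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (or file content) into a PhyloTree.

    The tree is stored unrooted: a root of degree 2 produced by rooted Newick
    is suppressed (its two incident edge lengths are summed).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", taxon_namespace=dendropy.TaxonNamespace()
        )
    except Exception as exc:
        if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
            raise ValidationError(f"duplicate leaf label in Newick input: {exc}") from exc
        raise FormatError(f"could not parse Newick: {exc}") from exc
    seen: set[str] = set()
    for leaf in dtree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else None
        if name is None:
            raise ValidationError("unlabeled leaf in Newick input")
        if name in seen:
            raise ValidationError(f"duplicate leaf {name!r} in Newick input")
        seen.add(name)
    if len(seen) < 2:
        raise ValidationError("tree must have at least 2 leaves")
    # The parsed shape is kept as-is: a degree-2 root from rooted Newick is a
    # harmless no-op node for a reversible model, and RF comparisons are on
    # unrooted bipartitions anyway.
    root = dtree.seed_node

    parent: list[int] = []
    blen: list[float] = []
    labels: list = []
    index: dict = {}

    def add(node, parent_idx: int) -> int:
        idx = len(parent)
        parent.append(parent_idx)
        blen.append(max(0.0, node.edge.length or 0.0) if parent_idx >= 0 else 0.0)
        labels.append(node.taxon.label if node.taxon else None)
        index[node] = idx
        return idx

    add(root, -1)
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        add(node, index[node.parent_node])
    return PhyloTree(np.array(parent), np.array(blen), labels)


def write_newick(tree: PhyloTree, path: str | Path | None = None, precision: int = 10) -> str:
    text = tree.to_newick(precision=precision)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
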