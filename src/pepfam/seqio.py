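"""Sequence, interval, alignment and tree I/O.

Foundational types for the peptide/receptor discovery pipeline: amino-acid
and nucleotide sequence records with provenance, 1-based inclusive interval
annotations, multiple sequence alignments and phylogenetic trees, together
with readers/writers for FASTA, a 5-column tab-delimited interval dialect
(with a GFF3 import shim) and newick.

Conventions
-----------
* All coordinates at interfaces are 1-based and inclusive.
* Protein alphabet: the 20 standard residues plus ``X``; nucleotide
  alphabet: ``ACGT`` plus ``N``.  Ambiguity codes are scored as background
  frequency downstream, never rejected.
* Trees are :class:`skbio.TreeNode` objects; a tree is *rooted* when its
  root has exactly two children.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO as _BioSeqIO
from skbio import TreeNode

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

#: alias used throughout: phylogenies are scikit-bio tree nodes
PhyloTree = TreeNode


class SeqFormatError(ValueError):
    """Raised for malformed FASTA/interval/newick inputs."""


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid or nucleotide sequence with provenance.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    species : str
        Species tag (may be empty for species-less collections).
    residues : str
        Uppercase sequence over the alphabet matching ``moltype``.
    moltype : {"protein", "dna"}
    source : {"annotated", "denovo", "seed", "decoy"}
        Where the sequence came from: an annotation set, six-frame rescue,
        a user-provided seed, or a planted decoy.
    """

    id: str
    residues: str
    species: str = ""
    moltype: str = "protein"
    source: str = "annotated"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if self.moltype not in ("protein", "dna"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        if self.source not in ("annotated", "denovo", "seed", "decoy"):
            raise ValueError(f"unknown source {self.source!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        alphabet = PROTEIN_ALPHABET if self.moltype == "protein" else DNA_ALPHABET
        bad = sorted(set(self.residues) - alphabet)
        if bad:
            raise SeqFormatError(
                f"sequence {self.id!r} contains characters outside the "
                f"{self.moltype} alphabet: {''.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def fragment(self, start: int, end: int) -> "SequenceRecord":
        """Residues ``start..end`` (1-based inclusive) as a new record."""
        if not (1 <= start <= end <= len(self)):
            raise ValueError(
                f"range {start}..{end} out of bounds for {self.id!r} "
                f"(length {len(self)})"
            )
        return replace(
            self,
            id=f"{self.id}_{start}-{end}",
            residues=self.residues[start - 1 : end],
        )


@dataclass(frozen=True)
class IntervalAnnotation:
    """A 1-based inclusive stranded feature interval on a sequence."""

    seq_id: str
    start: int
    end: int
    strand: str
    feature: str = "gene"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.start}..{self.end} on {self.seq_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        """True iff [start, end] shares >= 1 bp with this interval."""
        return self.start <= end and start <= self.end


@dataclass
class Msa:
    """A multiple sequence alignment: ordered (id, aligned string) rows.

    Gap symbol is ``-``; all rows have equal length and degapping a row
    recovers the input sequence exactly.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.records:
            widths = {len(s) for _, s in self.records}
            if len(widths) != 1:
                raise ValueError(f"aligned rows have unequal lengths: {sorted(widths)}")
            ids = [i for i, _ in self.records]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate row ids in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_cols(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def row(self, rec_id: str) -> str:
        for i, s in self.records:
            if i == rec_id:
                return s
        raise KeyError(rec_id)

    def column(self, j: int) -> str:
        """Column ``j`` (0-based) as a string, one char per row."""
        return "".join(s[j] for _, s in self.records)

    def degapped(self, rec_id: str) -> str:
        return self.row(rec_id).replace("-", "")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source, moltype: str = "protein", *, species: str = "",
               source_tag: str = "annotated") -> list[SequenceRecord]:
    """Parse FASTA from a path or text stream into sequence records.

    The first whitespace-delimited header token becomes the record id;
    wrapped lines are concatenated and residues uppercased.  Duplicate ids,
    empty records and alphabet violations raise :class:`SeqFormatError`.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle = open(source)
        close = True
    elif isinstance(source, str):
        handle = io.StringIO(source)
        close = False
    else:
        handle, close = source, False
    try:
        records: list[SequenceRecord] = []
        seen: set[str] = set()
        for rec in _BioSeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise SeqFormatError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).strip()
            if not seq:
                raise SeqFormatError(f"empty record {rec.id!r}")
            records.append(
                SequenceRecord(
                    id=rec.id, residues=seq, species=species,
                    moltype=moltype, source=source_tag,
                )
            )
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Sequence[SequenceRecord], path=None,
                line_width: int = 60) -> str:
    """Render records as FASTA text (and optionally write to ``path``)."""
    if not records:
        raise ValueError("refusing to write empty FASTA")
    if line_width < 1:
        raise ValueError("line_width must be positive")
    chunks = []
    for rec in records:
        chunks.append(f">{rec.id}\n")
        for i in range(0, len(rec.residues), line_width):
            chunks.append(rec.residues[i : i + line_width] + "\n")
    text = "".join(chunks)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_msa_fasta(source) -> Msa:
    """Read an aligned FASTA (rows may contain '-') into an :class:`Msa`."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle = open(source)
    else:
        handle = io.StringIO(source) if isinstance(source, str) else source
    rows = [(r.id, str(r.seq).upper()) for r in _BioSeqIO.parse(handle, "fasta")]
    return Msa(rows)


def write_msa_fasta(msa: Msa, path=None, line_width: int = 60) -> str:
    chunks = []
    for rid, row in msa.records:
        chunks.append(f">{rid}\n")
        for i in range(0, len(row), line_width):
            chunks.append(row[i : i + line_width] + "\n")
    text = "".join(chunks)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Interval tables


def read_intervals(source) -> list[IntervalAnnotation]:
    """Read the 5-column tab-delimited interval dialect.

    Columns: seq_id, start, end, strand, feature.  Lines starting with '#'
    are comments.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = source if isinstance(source, str) else source.read()
    out = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise SeqFormatError(f"interval line {ln}: expected 5 columns")
        out.append(
            IntervalAnnotation(
                seq_id=parts[0], start=int(parts[1]), end=int(parts[2]),
                strand=parts[3], feature=parts[4],
            )
        )
    return out


def write_intervals(annotations: Iterable[IntervalAnnotation], path=None) -> str:
    lines = [
        f"{a.seq_id}\t{a.start}\t{a.end}\t{a.strand}\t{a.feature}"
        for a in annotations
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def read_gff3_intervals(source) -> list[IntervalAnnotation]:
    """Import shim mapping GFF3 columns 1,4,5,7,3 onto the interval dialect."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = source if isinstance(source, str) else source.read()
    out = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        c = line.split("\t")
        if len(c) < 8:
            continue
        out.append(
            IntervalAnnotation(
                seq_id=c[0], start=int(c[3]), end=int(c[4]),
                strand=c[6], feature=c[2],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(source) -> PhyloTree:
    """Parse newick text (or a path) into a tree; missing lengths become 0."""
    if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(str(source)).exists():
        text = Path(source).read_text()
    else:
        text = source if isinstance(source, str) else source.read()
    if text.count("(") != text.count(")"):
        raise SeqFormatError("unbalanced parentheses in newick")
    tree = TreeNode.read(io.StringIO(text))
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SeqFormatError(f"duplicate leaf names: {dupes}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def write_newick(tree: PhyloTree, path=None) -> str:
    buf = io.StringIO()
    saved = tree.length
    try:
        if not tree.length:
            tree.length = None  # a zero root length is formatting noise
        tree.write(buf, format="newick")
    finally:
        tree.length = saved
    text = buf.getvalue().strip()
    if not text.endswith(";"):
        text += ";"
    text += "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def is_rooted(tree: PhyloTree) -> bool:
    """A tree is rooted when its root has exactly two children."""
    return len(tree.children) == 2


# ---------------------------------------------------------------------------
# Small shared sequence utilities

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: standard genetic code, indexed by codon; '*' terminates
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate a nucleotide string codon-by-codon; stops become '*'.

    Trailing partial codons are ignored; codons containing N translate
    to 'X'.
    """
    out = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)
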