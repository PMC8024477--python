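"""Reading/writing the standard formats and circular-coordinate sequence arithmetic.

Coordinates are 0-based half-open everywhere inside the package; every file
format and every user-facing report uses 1-based inclusive positions (the
GenBank/GFF3 convention).  Conversion happens only at the I/O boundary.

Features that wrap the origin of a circular genome are represented natively
with ``start > end`` (1-based view) rather than being split in two, so that
interval arithmetic downstream stays circular-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from skbio import TreeNode

logger = logging.getLogger(__name__)

GENOME_ALPHABET = frozenset("ACGTN")

#: IUPAC nucleotide ambiguity codes -> set of plain bases covered.
IUPAC_EXPAND: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse lookup: frozenset of bases -> minimal IUPAC code.
IUPAC_CODE: Mapping[frozenset, str] = {v: k for k, v in IUPAC_EXPAND.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class RangeError(ValueError):
    """Raised when coordinates fall outside the genome."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CircularGenome:
    """A named (by default circular) nucleotide sequence.

    ``sequence`` is upper-case over {A,C,G,T,N}; ``metadata`` carries
    free-form annotations such as strain, species or source accession.
    """

    id: str
    sequence: str
    is_circular: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - GENOME_ALPHABET
        if bad:
            raise FormatError(
                f"genome {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        if not self.sequence:
            raise FormatError(f"genome {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos`` (circular wrap applied)."""
        return self.sequence[(pos - 1) % self.length]


@dataclass(frozen=True)
class Feature:
    """An annotated element on a genome.

    1-based inclusive coordinates; ``start > end`` means the feature wraps
    the origin of a circular genome (span start..L then 1..end).
    """

    name: str
    category: str  # one of {"PCG", "tRNA", "rRNA", "orf"}
    start: int
    end: int
    strand: str  # "+" or "-"
    genome_id: str = ""

    def span(self, genome_len: int) -> int:
        """Number of bases covered, circular-aware."""
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_len - self.start + 1 + self.end

    def segments0(self, genome_len: int) -> list[tuple[int, int]]:
        """Covered region as 0-based half-open linear segments (1 or 2)."""
        if self.start <= self.end:
            return [(self.start - 1, self.end)]
        return [(self.start - 1, genome_len), (0, self.end)]


@dataclass
class AnnotationSet:
    """Ordered collection of features on one genome."""

    genome_id: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            if f.genome_id and f.genome_id != self.genome_id:
                raise ValueError(
                    f"feature {f.name!r} references genome {f.genome_id!r}, "
                    f"not {self.genome_id!r}"
                )

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def by_category(self, category: str) -> list[Feature]:
        return [f for f in self.features if f.category == category]


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    bases: str
    quals: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id!r}: bases/quals length mismatch")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, is_circular: bool = True) -> list[CircularGenome]:
    """Read a FASTA file into :class:`CircularGenome` records.

    Sequences are upper-cased and U is converted to T.  Duplicate record ids
    and non-ACGTN characters raise :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    genomes: list[CircularGenome] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        genomes.append(CircularGenome(id=rec.id, sequence=str(rec.seq), is_circular=is_circular))
    return genomes


def write_fasta(genomes: Iterable[CircularGenome] | Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    """Write genomes (or a label->sequence mapping) as FASTA."""
    if isinstance(genomes, Mapping):
        items = list(genomes.items())
    else:
        items = [(g.id, g.sequence) for g in genomes]
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(path: str | Path, offset: int = 33) -> list[ReadRecord]:
    """Read FASTQ reads with the given Phred offset (33 default, 64 legacy)."""
    fmt = {33: "fastq", 64: "fastq-illumina"}.get(offset)
    if fmt is None:
        raise ValueError(f"unsupported Phred offset {offset}")
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        reads.append(ReadRecord(rec.id, str(rec.seq).upper(),
                                rec.letter_annotations["phred_quality"]))
    return reads


# ---------------------------------------------------------------------------
# GFF3
#
# Parsing is done directly here: the wrap-origin convention (end < start on a
# circular genome) violates the GFF3 standard, so validating parsers reject
# exactly the records this package must accept.

_GFF_TYPE_TO_CATEGORY = {
    "CDS": "PCG",
    "gene": "PCG",
    "protein_coding_gene": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "ORF": "orf",
    "orf": "orf",
    "open_reading_frame": "orf",
}


def read_features(path: str | Path, genome: CircularGenome) -> AnnotationSet:
    """Read a GFF3 file into an :class:`AnnotationSet` for ``genome``.

    GFF3 types map onto categories (CDS/gene -> PCG, tRNA, rRNA,
    ORF/open_reading_frame -> orf); unknown types are skipped with a warning.
    ``end < start`` is accepted as a wrap-origin feature on a circular genome.
    """
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _, ftype, start_s, end_s, _, strand, _, attrs = cols
            category = _GFF_TYPE_TO_CATEGORY.get(ftype)
            if category is None:
                logger.warning("%s:%d: skipping unknown feature type %r", path, lineno, ftype)
                continue
            start, end = int(start_s), int(end_s)
            for pos in (start, end):
                if not 1 <= pos <= genome.length:
                    raise RangeError(
                        f"{path}:{lineno}: coordinate {pos} outside genome "
                        f"of length {genome.length}"
                    )
            if end < start and not genome.is_circular:
                raise RangeError(f"{path}:{lineno}: end < start on a linear genome")
            name = _gff_attr(attrs, "Name") or _gff_attr(attrs, "ID") or f"feature{lineno}"
            features.append(Feature(name, category, start, end, strand, genome.id))
    return AnnotationSet(genome_id=genome.id, features=features)


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None


_CATEGORY_TO_GFF_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "orf": "ORF"}


def write_features(ann: AnnotationSet, path: str | Path, source: str = "mtmarker") -> None:
    """Write an :class:`AnnotationSet` as GFF3 (wrap features keep start > end)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in ann.features:
            fh.write("\t".join([
                ann.genome_id, source, _CATEGORY_TO_GFF_TYPE[f.category],
                str(f.start), str(f.end), ".", f.strand, ".",
                f"ID={f.name};Name={f.name}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# subsequence

def subsequence(genome: CircularGenome, start: int, end: int, strand: str = "+") -> str:
    """Extract the 1-based inclusive interval ``start..end``.

    ``start > end`` wraps the origin of a circular genome; strand "-" returns
    the reverse complement of the extracted region.
    """
    L = genome.length
    if not (1 <= start <= L and 1 <= end <= L):
        raise RangeError(f"interval {start}..{end} outside genome of length {L}")
    if start <= end:
        seq = genome.sequence[start - 1:end]
    else:
        if not genome.is_circular:
            raise RangeError("start > end on a linear genome")
        seq = genome.sequence[start - 1:] + genome.sequence[:end]
    if strand == "-":
        seq = reverse_complement(seq)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return seq


# ---------------------------------------------------------------------------
# newick

def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree with branch lengths as newick; duplicate leaf labels error."""
    labels = [t.name for t in tree.tips()]
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    with open(path, "w") as fh:
        text = str(tree)  # skbio writes newick with trailing ';\n'
        fh.write(text if text.endswith("\n") else text + "\n")


def read_newick(path: str | Path) -> TreeNode:
    """Read a newick tree file."""
    return TreeNode.read(str(path), format="newick")
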