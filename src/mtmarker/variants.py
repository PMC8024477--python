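"""Per-strain SNV sets and the merged position x strain matrix.

Three entry points feed the window scan:

* raw reads can be pre-screened with the two quantitative read-quality rules
  (:func:`filter_reads`),
* whole strain genomes that are colinear with the reference are diffed
  directly (:func:`call_snvs_from_genomes`) using unique shared k-mer
  anchors — a desk-scale substitute for a mapping+calling workflow, valid
  for near-identical organelle genomes,
* externally called variants arrive as single-sample VCFs
  (:func:`read_vcf_per_strain`) and pass through the homozygous-frequency
  filter (:func:`filter_homozygous`).

Indels are excluded throughout: segments where anchoring detects a length
change are masked with a warning, never realigned.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .genome_io import CircularGenome, FormatError, ReadRecord

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


class ColinearityError(ValueError):
    """Raised when two genomes cannot be anchored as colinear."""


class DataConsistencyError(ValueError):
    """Raised when per-strain SNV sets disagree about the reference."""


@dataclass(frozen=True)
class SnvRecord:
    """One single-base substitution in one strain relative to a reference."""

    genome_id: str
    pos: int  # 1-based on the reference
    ref_allele: str
    alt_allele: str
    strain: str
    alt_frequency: float = 1.0

    def __post_init__(self) -> None:
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError(f"alleles must be single A/C/G/T bases: {self}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at pos {self.pos}")


@dataclass
class ReadFilterConfig:
    """The two quantitative read-quality rules.

    A read is dropped when strictly more than ``max_lowqual_fraction`` of its
    bases are below ``lowqual_phred_threshold``, or when its fraction of N
    bases is at least ``max_n_fraction``.
    """

    max_lowqual_fraction: float = 0.5
    lowqual_phred_threshold: int = 5
    max_n_fraction: float = 0.10

    def __post_init__(self) -> None:
        for frac in (self.max_lowqual_fraction, self.max_n_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def filter_reads(
    reads: list[ReadRecord], cfg: ReadFilterConfig | None = None
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Apply the read-quality rules; returns kept reads and per-rule counts.

    A read failing both rules is attributed to the low-quality rule (first
    matching rule wins).
    """
    cfg = cfg or ReadFilterConfig()
    kept: list[ReadRecord] = []
    removed = {"low_quality": 0, "too_many_n": 0}
    for read in reads:
        n_bases = len(read.bases)
        if n_bases == 0:
            removed["low_quality"] += 1
            continue
        lowq = sum(q < cfg.lowqual_phred_threshold for q in read.quals)
        if lowq / n_bases > cfg.max_lowqual_fraction:
            removed["low_quality"] += 1
        elif read.bases.count("N") / n_bases >= cfg.max_n_fraction:
            removed["too_many_n"] += 1
        else:
            kept.append(read)
    return kept, removed


def filter_homozygous(snvs: list[SnvRecord], min_freq: float = 0.85) -> list[SnvRecord]:
    """Keep calls with alternate-allele frequency >= ``min_freq``.

    The threshold is inclusive, matching the semantics of a caller's
    minimum-frequency-for-homozygous option.
    """
    if not 0.0 < min_freq <= 1.0:
        raise ValueError(f"min_freq must be in (0, 1], got {min_freq}")
    return [s for s in snvs if s.alt_frequency >= min_freq]


# ---------------------------------------------------------------------------
# genome-vs-genome calling

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
        pos[kmer] = i
    return {kmer: p for kmer, p in pos.items() if counts[kmer] == 1 and "N" not in kmer}


def _longest_increasing(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of anchors increasing in both coordinates (patience LIS)."""
    if not anchors:
        return []
    tails: list[int] = []  # strain positions of chain tails
    tails_idx: list[int] = []
    parent = [-1] * len(anchors)
    for idx, (_, spos) in enumerate(anchors):
        k = bisect.bisect_left(tails, spos)
        if k == len(tails):
            tails.append(spos)
            tails_idx.append(idx)
        else:
            tails[k] = spos
            tails_idx[k] = idx
        parent[idx] = tails_idx[k - 1] if k > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(anchors[i])
        i = parent[i]
    return chain[::-1]


def _diff_equal_length(reference: CircularGenome, strain: CircularGenome) -> list[SnvRecord]:
    mismatches = [
        i for i, (rb, sb) in enumerate(zip(reference.sequence, strain.sequence))
        if rb != sb and rb != "N" and sb != "N"
    ]
    if len(mismatches) > 0.05 * reference.length:
        raise ColinearityError(
            f"{reference.id!r} and {strain.id!r} differ at "
            f"{len(mismatches)}/{reference.length} positions; not near-identical"
        )
    return [
        SnvRecord(reference.id, i + 1, reference.sequence[i], strain.sequence[i],
                  strain.id)
        for i in mismatches
    ]


def call_snvs_from_genomes(
    reference: CircularGenome, strain: CircularGenome, k: int = 21, min_anchors: int = 2
) -> list[SnvRecord]:
    """Diff a colinear strain genome against the reference.

    Shared k-mers unique in both sequences anchor the comparison; between
    consecutive anchors, equal-length segments are compared base by base and
    mismatches become :class:`SnvRecord` s.  Positions where either base is N
    are skipped; segments whose lengths differ (an indel) are masked with a
    warning.  Insufficient anchors raise :class:`ColinearityError`.
    """
    if reference.sequence == strain.sequence:
        return []
    ref_k = _unique_kmers(reference.sequence, k)
    strain_k = _unique_kmers(strain.sequence, k)
    shared = sorted(
        (rpos, strain_k[kmer]) for kmer, rpos in ref_k.items() if kmer in strain_k
    )
    anchors = _longest_increasing(shared)
    if len(anchors) < min_anchors:
        # short or repeat-dense sequences may lack unique shared k-mers; for
        # equal-length inputs a direct positional diff is exact, guarded by
        # the near-identity precondition
        if reference.length == strain.length:
            return _diff_equal_length(reference, strain)
        raise ColinearityError(
            f"only {len(anchors)} colinear anchor k-mers shared between "
            f"{reference.id!r} and {strain.id!r}; genomes may not be colinear"
        )

    snvs: list[SnvRecord] = []

    def compare(r0: int, r1: int, s0: int, s1: int) -> None:
        if r1 - r0 != s1 - s0:
            logger.warning(
                "length change between anchors (%d..%d vs %d..%d) in %s: "
                "segment masked (indels are not called)", r0, r1, s0, s1, strain.id,
            )
            return
        rseq, sseq = reference.sequence, strain.sequence
        for off in range(r1 - r0):
            rb, sb = rseq[r0 + off], sseq[s0 + off]
            if rb != sb and rb != "N" and sb != "N":
                snvs.append(SnvRecord(reference.id, r0 + off + 1, rb, sb, strain.id))

    # leading segment, inter-anchor gaps (anchors themselves match exactly),
    # trailing segment
    compare(0, anchors[0][0], 0, anchors[0][1])
    for (ra, sa), (rb, sb) in zip(anchors, anchors[1:]):
        compare(ra + k, rb, sa + k, sb)
    last_r, last_s = anchors[-1]
    compare(last_r + k, reference.length, last_s + k, strain.length)
    return snvs


# ---------------------------------------------------------------------------
# matrix

@dataclass
class SnvMatrix:
    """Union of SNV positions x strains relative to one reference.

    ``alleles[i, j]`` is the base strain ``strains[j]`` carries at
    ``positions[i]`` (1-based, strictly increasing); strains without a call
    at a position carry the reference allele.  In "missing-as-unknown" mode
    uncalled cells are "N" and are excluded from haplotype comparison.
    """

    genome_id: str
    positions: np.ndarray  # (P,) int, 1-based ascending
    ref_alleles: np.ndarray  # (P,) '<U1'
    strains: list[str]
    alleles: np.ndarray  # (P, S) '<U1'

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def strain_column(self, strain: str) -> np.ndarray:
        return self.alleles[:, self.strains.index(strain)]


def build_snv_matrix(
    reference: CircularGenome,
    per_strain: dict[str, list[SnvRecord]],
    missing_as_unknown: bool = False,
) -> SnvMatrix:
    """Merge per-strain SNV sets into one matrix.

    Positions are the union over strains, sorted ascending; ref-allele claims
    are validated against the reference sequence and against each other.
    Positions where no strain carries a non-reference allele are dropped.
    """
    claims: dict[int, str] = {}
    for strain, records in per_strain.items():
        for rec in records:
            if rec.genome_id != reference.id:
                raise DataConsistencyError(
                    f"record at pos {rec.pos} references genome {rec.genome_id!r}, "
                    f"matrix reference is {reference.id!r}"
                )
            ref_base = reference.base(rec.pos)
            if rec.ref_allele != ref_base:
                raise DataConsistencyError(
                    f"strain {strain!r} claims ref {rec.ref_allele} at pos {rec.pos}, "
                    f"reference sequence has {ref_base}"
                )
            prev = claims.setdefault(rec.pos, rec.ref_allele)
            if prev != rec.ref_allele:
                raise DataConsistencyError(
                    f"conflicting ref alleles at pos {rec.pos}: {prev} vs {rec.ref_allele}"
                )

    strains = sorted(per_strain)
    positions = np.array(sorted(claims), dtype=np.int64)
    pos_index = {p: i for i, p in enumerate(positions.tolist())}
    ref_alleles = np.array([claims[p] for p in positions.tolist()], dtype="<U1")
    if missing_as_unknown:
        alleles = np.full((len(positions), len(strains)), "N", dtype="<U1")
    else:
        alleles = np.tile(ref_alleles[:, None], (1, max(1, len(strains))))[:, :len(strains)]
    for j, strain in enumerate(strains):
        for rec in per_strain[strain]:
            alleles[pos_index[rec.pos], j] = rec.alt_allele

    # drop positions where every strain matches the reference
    if len(positions):
        keep = (alleles != ref_alleles[:, None]).any(axis=1)
        positions, ref_alleles, alleles = positions[keep], ref_alleles[keep], alleles[keep]
    return SnvMatrix(reference.id, positions, ref_alleles, strains, alleles)


def matrix_to_frame(matrix: SnvMatrix):
    """TSV-ready DataFrame view (pos, ref, one column per strain)."""
    import pandas as pd

    df = pd.DataFrame(matrix.alleles, columns=matrix.strains)
    df.insert(0, "ref", matrix.ref_alleles)
    df.insert(0, "pos", matrix.positions)
    return df


# ---------------------------------------------------------------------------
# VCF I/O

def read_vcf_per_strain(
    paths: dict[str, str | Path], reference: CircularGenome
) -> dict[str, list[SnvRecord]]:
    """Read single-sample VCFs into per-strain SNV sets.

    Only biallelic SNV rows are used; indels and MNVs are skipped and
    counted in the log.  The alternate-allele frequency is taken from the
    INFO ``AF`` field (fraction) or a FORMAT ``FREQ`` percentage when
    present, else defaults to 1.0.
    """
    out: dict[str, list[SnvRecord]] = {}
    for strain, path in paths.items():
        records: list[SnvRecord] = []
        skipped = 0
        try:
            vcf = VCF(str(path))
        except Exception as exc:  # cyvcf2 raises bare OSError on bad input
            raise FormatError(f"{path}: not a readable VCF ({exc})") from exc
        for row in vcf:
            if row.CHROM != reference.id:
                raise DataConsistencyError(
                    f"{path}: CHROM {row.CHROM!r} does not match reference {reference.id!r}"
                )
            alts = row.ALT
            if len(row.REF) != 1 or len(alts) != 1 or len(alts[0]) != 1 \
                    or row.REF not in BASES or alts[0] not in BASES:
                skipped += 1
                continue
            freq = 1.0
            af = row.INFO.get("AF")
            if af is not None:
                freq = float(af)
            else:
                try:
                    raw = row.format("FREQ")
                except KeyError:
                    raw = None
                if raw is not None:
                    try:
                        freq = float(str(raw[0]).strip("[]'\" %")) / 100.0
                    except ValueError:
                        pass
            records.append(
                SnvRecord(reference.id, row.POS, row.REF, alts[0], strain, freq)
            )
        if skipped:
            logger.info("%s: skipped %d non-SNV records", path, skipped)
        out[strain] = records
    return out


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##source=mtmarker\n"
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_strain_vcf(
    records: list[SnvRecord], reference: CircularGenome, path: str | Path,
    strain: str | None = None,
) -> None:
    """Write one strain's SNVs as a single-sample VCF v4.2."""
    if strain is None:
        strain = records[0].strain if records else "sample"
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(f"##contig=<ID={reference.id},length={reference.length}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{strain}\n")
        for rec in sorted(records, key=lambda r: r.pos):
            fh.write(
                f"{rec.genome_id}\t{rec.pos}\t.\t{rec.ref_allele}\t{rec.alt_allele}"
                f"\t.\tPASS\tAF={rec.alt_frequency:g}\tGT\t1/1\n"
            )


def write_matrix_vcf(matrix: SnvMatrix, reference: CircularGenome, path: str | Path) -> None:
    """Write the merged matrix as a multi-sample VCF v4.2."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(f"##contig=<ID={reference.id},length={reference.length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.strains) + "\n")
        for i, pos in enumerate(matrix.positions.tolist()):
            ref = matrix.ref_alleles[i]
            alts = sorted({a for a in matrix.alleles[i] if a not in (ref, "N")})
            code = {ref: "0/0", "N": "./."}
            code.update({a: f"{j + 1}/{j + 1}" for j, a in enumerate(alts)})
            gts = "\t".join(code[a] for a in matrix.alleles[i])
            fh.write(f"{matrix.genome_id}\t{pos}\t.\t{ref}\t{','.join(alts)}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")
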