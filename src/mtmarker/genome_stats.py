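"""Descriptive statistics of a compact circular genome and its annotation.

Covers base composition, intergenic-spacer accounting, gene overlap and
zero-gap adjacency, inverted-repeat detection and start-codon tabulation —
the quantities a mitogenome characterization reports — plus a cross-genome
gene presence/absence matrix.

"Intergenic" here means positions covered by no annotated feature of any
category, with both strands pooled and overlapped positions counted once, so
that merged feature coverage plus total spacer length always equals the
genome length.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    AnnotationSet,
    CircularGenome,
    Feature,
    reverse_complement,
    subsequence,
)


class UndefinedContentError(ValueError):
    """Base composition is undefined (no informative bases)."""


def at_content(seq: str) -> float:
    """Fraction of A+T among non-N bases of ``seq``."""
    if not seq:
        raise UndefinedContentError("empty sequence")
    seq = seq.upper()
    n_informative = len(seq) - seq.count("N")
    if n_informative == 0:
        raise UndefinedContentError("sequence is all N")
    return (seq.count("A") + seq.count("T")) / n_informative


def gc_content(seq: str) -> float:
    """Fraction of G+C among non-N bases of ``seq``."""
    if not seq:
        raise UndefinedContentError("empty sequence")
    seq = seq.upper()
    n_informative = len(seq) - seq.count("N")
    if n_informative == 0:
        raise UndefinedContentError("sequence is all N")
    return (seq.count("G") + seq.count("C")) / n_informative


# ---------------------------------------------------------------------------
# intergenic spacers

@dataclass(frozen=True)
class SpacerInterval:
    """A maximal run of positions covered by no feature (1-based inclusive;
    start > end wraps the origin)."""

    start: int
    end: int
    length: int


def _coverage_mask(ann: AnnotationSet, genome_len: int) -> np.ndarray:
    mask = np.zeros(genome_len, dtype=bool)
    for f in ann:
        if not (1 <= f.start <= genome_len and 1 <= f.end <= genome_len):
            raise ValueError(f"feature {f.name!r} outside genome of length {genome_len}")
        for s0, e0 in f.segments0(genome_len):
            mask[s0:e0] = True
    return mask


def intergenic_spacers(
    genome: CircularGenome, ann: AnnotationSet
) -> tuple[list[SpacerInterval], dict]:
    """Maximal uncovered runs on the circle, plus a summary.

    Returns ``(spacers, summary)`` where summary holds ``total_bp``,
    ``percent`` of the genome and ``mean_length`` (bp, unrounded; reports
    round to the nearest integer).
    """
    L = genome.length
    mask = _coverage_mask(ann, L)
    uncovered = ~mask
    if not uncovered.any():
        return [], {"total_bp": 0, "percent": 0.0, "mean_length": 0.0, "count": 0}
    if uncovered.all():
        spacer = SpacerInterval(1, L, L)
        return [spacer], {"total_bp": L, "percent": 100.0, "mean_length": float(L), "count": 1}

    # runs of uncovered positions on the linearized circle
    idx = np.flatnonzero(uncovered)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    runs = list(zip(starts.tolist(), ends.tolist()))  # 0-based inclusive

    # merge a run touching the end of the sequence with one touching the start
    if genome.is_circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == L - 1:
        first, last = runs[0], runs.pop()
        runs[0] = (last[0], first[1])  # wrap run: start near L, end near 1

    spacers = []
    for s0, e0 in runs:
        length = (e0 - s0 + 1) if s0 <= e0 else (L - s0 + e0 + 1)
        spacers.append(SpacerInterval(s0 + 1, e0 + 1, length))
    total = int(uncovered.sum())
    summary = {
        "total_bp": total,
        "percent": 100.0 * total / L,
        "mean_length": total / len(spacers),
        "count": len(spacers),
    }
    return spacers, summary


# ---------------------------------------------------------------------------
# overlaps and adjacency

@dataclass(frozen=True)
class OverlapRecord:
    feature_a: str
    feature_b: str
    overlap_len: int
    orientation: str  # "same-strand" | "opposite-strand"


def find_overlaps(ann: AnnotationSet, genome_len: int) -> list[OverlapRecord]:
    """Every unordered feature pair sharing >= 1 position, circular-aware."""
    out: list[OverlapRecord] = []
    feats = list(ann)
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            a, b = feats[i], feats[j]
            shared = 0
            for sa, ea in a.segments0(genome_len):
                for sb, eb in b.segments0(genome_len):
                    shared += max(0, min(ea, eb) - max(sa, sb))
            if shared > 0:
                orient = "same-strand" if a.strand == b.strand else "opposite-strand"
                out.append(OverlapRecord(a.name, b.name, shared, orient))
    return out


def find_adjacent_pairs(ann: AnnotationSet, genome_len: int) -> list[tuple[str, str]]:
    """Feature pairs joined with zero gap (end+1 == start mod L) and no overlap."""
    overlapping = {
        frozenset((r.feature_a, r.feature_b)) for r in find_overlaps(ann, genome_len)
    }
    pairs = []
    feats = list(ann)
    for a in feats:
        for b in feats:
            if a is b:
                continue
            if a.end % genome_len + 1 == b.start:
                if frozenset((a.name, b.name)) not in overlapping:
                    pairs.append((a.name, b.name))
    return pairs


# ---------------------------------------------------------------------------
# inverted repeats

@dataclass(frozen=True)
class InvertedRepeatPair:
    """Two nearby units where the right one is the reverse complement of the
    left one within ``mismatches`` differences (1-based left/right starts)."""

    left_start: int
    right_start: int
    unit_len: int
    mismatches: int
    spacer_len: int


def find_inverted_repeats(
    genome: CircularGenome,
    min_len: int = 50,
    max_spacer: int = 2000,
    max_mismatch: int = 0,
) -> list[InvertedRepeatPair]:
    """Seed-and-extend scan for inverted repeat pairs.

    Reports maximal pairs (not extendable either way within the mismatch
    budget) whose downstream unit is the reverse complement of the upstream
    unit, separated by at most ``max_spacer`` bp; pairs whose units overlap
    each other are excluded.  Defaults are tuned for compact organelle
    genomes: exact units of >= 50 bp within 2 kb of each other.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    seq = genome.sequence
    L = len(seq)
    seed_len = min(min_len, 16)

    # seed index: every seed_len-mer -> sorted start positions
    index: dict[str, list[int]] = {}
    for i in range(L - seed_len + 1):
        index.setdefault(seq[i:i + seed_len], []).append(i)

    found: dict[tuple[int, int], tuple[int, int]] = {}  # (l,r)->(unit,mm)
    for i in range(L - seed_len + 1):
        rc_seed = reverse_complement(seq[i:i + seed_len])
        for j in index.get(rc_seed, ()):
            if j <= i:
                continue
            # extend the exact seed match (left unit at i, right unit at j)
            l0, l1 = i, i + seed_len  # half-open left unit
            r0, r1 = j, j + seed_len
            mm = 0
            # outward extension: grow left unit rightwards / right unit leftwards,
            # then left unit leftwards / right unit rightwards
            while l1 < r0 and mm <= max_mismatch:
                step_mm = 0 if seq[l1] == _COMP[seq[r0 - 1]] else 1
                if mm + step_mm > max_mismatch:
                    break
                mm += step_mm
                l1 += 1
                r0 -= 1
            while l0 > 0 and r1 < L and l1 <= r0 and mm <= max_mismatch:
                step_mm = 0 if seq[l0 - 1] == _COMP[seq[r1]] else 1
                if mm + step_mm > max_mismatch:
                    break
                mm += step_mm
                l0 -= 1
                r1 += 1
            unit = l1 - l0
            spacer = r0 - l1
            if unit >= min_len and 0 <= spacer <= max_spacer:
                key = (l0, r0)
                prev = found.get(key)
                if prev is None or unit > prev[0]:
                    found[key] = (unit, mm)

    # drop pairs strictly contained in a longer reported pair
    pairs = [
        InvertedRepeatPair(l0 + 1, r0 + 1, unit, mm, r0 - (l0 + unit))
        for (l0, r0), (unit, mm) in found.items()
    ]
    pairs.sort(key=lambda p: (-p.unit_len, p.left_start))
    kept: list[InvertedRepeatPair] = []
    for p in pairs:
        contained = any(
            q.left_start <= p.left_start
            and p.left_start + p.unit_len <= q.left_start + q.unit_len
            and q.right_start <= p.right_start
            and p.right_start + p.unit_len <= q.right_start + q.unit_len
            for q in kept
        )
        if not contained:
            kept.append(p)
    kept.sort(key=lambda p: p.left_start)
    return kept


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# start codons

def start_codon_table(genome: CircularGenome, ann: AnnotationSet) -> dict[str, str]:
    """First codon of each protein-coding feature, in reading orientation."""
    table: dict[str, str] = {}
    for f in ann.by_category("PCG"):
        if f.span(genome.length) < 3:
            raise ValueError(f"PCG {f.name!r} shorter than one codon")
        if f.strand == "+":
            end = (f.start + 2 - 1) % genome.length + 1
            codon = subsequence(genome, f.start, end, "+")
        else:
            start = (f.end - 3) % genome.length + 1
            codon = subsequence(genome, start, f.end, "-")
        table[f.name] = codon
    return table


# ---------------------------------------------------------------------------
# gene content across genomes

def load_gene_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Load the gene-synonym map (alias -> canonical), lower-cased.

    The default map ships with the package as an editable TSV.
    """
    if path is None:
        ref = resources.files("mtmarker.data").joinpath("gene_synonyms.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    synonyms: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, canonical = line.split("\t")[:2]
        synonyms[alias.strip().lower()] = canonical.strip().lower()
    return synonyms


def gene_content_matrix(
    annotations: list[AnnotationSet],
    core_genes: list[str],
    synonyms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Presence/absence of ``core_genes`` across genomes (bool DataFrame).

    Gene names are matched case-insensitively after applying the synonym map;
    split genes listed as e.g. ``nad11_1``/``nad11_2`` count as the base gene
    when both halves are present.  A summary row ``__missing_anywhere__``
    flags genes absent from at least one genome.
    """
    if not annotations:
        raise ValueError("need at least one annotation set")
    syn = load_gene_synonyms() if synonyms is None else synonyms

    def canonical(name: str) -> str:
        n = name.strip().lower()
        return syn.get(n, n)

    core = [canonical(g) for g in core_genes]
    if len(set(core)) != len(core):
        raise ValueError("core gene list collapses to duplicate canonical names")
    rows = {}
    for ann in annotations:
        names = [canonical(f.name) for f in ann]
        present = set(names)
        # split-gene halves: base present iff both halves are
        halves: dict[str, set[str]] = {}
        for n in names:
            if "_" in n:
                base, part = n.rsplit("_", 1)
                if part.isdigit():
                    halves.setdefault(base, set()).add(part)
        for base, parts in halves.items():
            if len(parts) >= 2:
                present.add(base)
        rows[ann.genome_id] = [g in present for g in core]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=core)
    df.loc["__missing_anywhere__"] = ~df.all(axis=0)
    return df


# ---------------------------------------------------------------------------
# full report

def genome_report(genome: CircularGenome, ann: AnnotationSet) -> dict:
    """One-stop summary used by the stats stage of the pipeline."""
    spacers, spacer_summary = intergenic_spacers(genome, ann)
    overlaps = find_overlaps(ann, genome.length)
    adjacent = find_adjacent_pairs(ann, genome.length)
    irs = find_inverted_repeats(genome)
    codons = start_codon_table(genome, ann)
    counts = {c: len(ann.by_category(c)) for c in ("PCG", "tRNA", "rRNA", "orf")}
    return {
        "genome_id": genome.id,
        "length_bp": genome.length,
        "at_percent": round(100.0 * at_content(genome.sequence), 1),
        "feature_counts": counts,
        "intergenic": {
            "total_bp": spacer_summary["total_bp"],
            "percent": round(spacer_summary["percent"], 1),
            "mean_length_bp": round(spacer_summary["mean_length"]),
            "count": spacer_summary["count"],
        },
        "overlaps": [vars(o) for o in overlaps],
        "adjacent_pairs": adjacent,
        "inverted_repeats": [vars(p) for p in irs],
        "non_atg_starts": {g: c for g, c in codons.items() if c != "ATG"},
    }
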