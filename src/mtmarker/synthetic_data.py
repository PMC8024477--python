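"""Synthetic compact circular genomes with a planted SNV hotspot.

The generator emulates the statistical structure of a compact, AT-rich
diatom-style mitochondrial genome and of an intra-species strain panel:

* a circular reference (default 36,162 bp, 74.9% AT) carrying 64 features
  (35 protein-coding genes, 24 tRNAs, 2 rRNAs, 3 orfs) separated by tiny
  spacers (geometric, mean 39 bp), with three planted overlapping pairs
  (20/20/9 bp, the 9-bp one on opposite strands), three planted zero-gap
  adjacent pairs, ATG start codons except one planted ATC starter, and one
  129-bp exact inverted-repeat pair flanking a designated orf;
* a panel of strains (default 8, the first being the reference itself) with
  a dense hotspot — 26 distinct SNV positions inside one 400-bp window whose
  per-strain haplotypes are pairwise distinct by construction — plus sparse
  strain-private background SNVs (Poisson, mean 3 per derived strain);
* unrelated genomes of the same length and composition for specificity
  panels.

Genes are sequence intervals, not real coding sequences: only the start
codon is meaningful.  All randomness flows from a single seed through
per-component child streams, so each stage is reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import AnnotationSet, CircularGenome, Feature, reverse_complement
from .variants import SnvRecord

BASES = np.array(["A", "C", "G", "T"])


class PackingError(ValueError):
    """The requested features and spacers do not fit the genome length."""


@dataclass
class SimConfig:
    """Knobs of the simulator; defaults are the study conditions."""

    genome_len: int = 36_162
    at_fraction: float = 0.749
    n_pcg: int = 35
    n_trna: int = 24
    n_rrna: int = 2
    n_orf: int = 3
    mean_spacer: int = 39
    overlap_lens: tuple[int, ...] = (20, 20, 9)  # last pair opposite-strand
    adjacent_pairs: int = 3
    ir_unit_len: int = 129
    n_strains: int = 8
    hotspot_len: int = 400
    hotspot_snvs: int = 26
    background_snvs_per_strain: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hotspot_snvs > self.hotspot_len:
            raise ValueError("hotspot_snvs cannot exceed hotspot_len")
        if self.n_strains < 1:
            raise ValueError("need at least one strain")
        if 2 ** self.hotspot_snvs < self.n_strains:
            raise PackingError(
                f"{self.hotspot_snvs} hotspot positions cannot distinguish "
                f"{self.n_strains} strains"
            )

    @property
    def n_features(self) -> int:
        return self.n_pcg + self.n_trna + self.n_rrna + self.n_orf


@dataclass
class TruthSet:
    """Everything the generator planted, for parameter-recovery testing."""

    reference: CircularGenome
    annotations: AnnotationSet
    strain_genomes: dict[str, CircularGenome]
    truth_snvs: dict[str, list[SnvRecord]]
    hotspot_window: tuple[int, int]  # 1-based inclusive
    config: SimConfig = field(default=None)  # type: ignore[assignment]


def _random_sequence(rng: np.random.Generator, n: int, at_fraction: float) -> np.ndarray:
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return rng.choice(BASES, size=n, p=[p_at, p_gc, p_gc, p_at])


# tRNA/rRNA/orf length conventions (bp); PCGs absorb the remaining budget.
_TRNA_LEN = 72
_RRNA_LENS = (1_800, 1_100)
_MIN_PCG_LEN = 150
_ORF_LENS = (297, 477, 303)  # first one is the IR-flanked designated orf


def generate_reference(cfg: SimConfig) -> tuple[CircularGenome, AnnotationSet]:
    """Build the annotated reference genome for ``cfg`` (deterministic per seed)."""
    rng = np.random.default_rng([cfg.seed, 1])
    L = cfg.genome_len
    n_feat = cfg.n_features
    if cfg.n_orf < 1 or cfg.n_pcg < 8 or cfg.n_rrna > len(_RRNA_LENS):
        raise PackingError("feature counts outside the supported layout")

    # --- gap plan around the circle: one gap after each feature -------------
    n_overlap = len(cfg.overlap_lens)
    n_plain = n_feat - n_overlap - cfg.adjacent_pairs - 2
    if n_plain < 0:
        raise PackingError("more planted pairs than features")
    # the designated orf is flanked by two wide gaps that will host the IR
    ir_gap = cfg.ir_unit_len + 12
    plain_gaps = rng.geometric(1.0 / cfg.mean_spacer, size=n_plain).tolist()
    gaps = (
        [-g for g in cfg.overlap_lens]
        + [0] * cfg.adjacent_pairs
        + [ir_gap, ir_gap]
        + plain_gaps
    )

    # --- feature length plan -----------------------------------------------
    fixed = (
        cfg.n_trna * _TRNA_LEN
        + sum(_RRNA_LENS[: cfg.n_rrna])
        + sum(_ORF_LENS[: cfg.n_orf])
    )
    pcg_budget = L - sum(gaps) - fixed
    if pcg_budget < cfg.n_pcg * _MIN_PCG_LEN:
        raise PackingError(
            f"PCG budget {pcg_budget} bp too small for {cfg.n_pcg} genes"
        )
    weights = rng.dirichlet(np.full(cfg.n_pcg, 8.0))
    extra = pcg_budget - cfg.n_pcg * _MIN_PCG_LEN
    pcg_lens = [_MIN_PCG_LEN + 3 * int(w * extra / 3) for w in weights]
    pcg_lens[0] += pcg_budget - sum(pcg_lens)  # absorb rounding remainder

    # --- assemble the ordered feature/gap walk ------------------------------
    # Categories are interleaved; planted pairs use specific categories so
    # the audit is unambiguous: overlaps PCG-PCG, PCG-PCG, orf-tRNA
    # (opposite strand); adjacencies PCG-PCG.
    entries: list[tuple[str, str, int, str]] = []  # (name, category, length, strand)
    pcg_iter = iter(range(cfg.n_pcg))
    trna_iter = iter(range(cfg.n_trna))

    def next_pcg() -> tuple[str, str, int, str]:
        i = next(pcg_iter)
        return (f"pcg{i + 1:02d}", "PCG", pcg_lens[i], "+" if rng.random() < 0.6 else "-")

    def next_trna() -> tuple[str, str, int, str]:
        i = next(trna_iter)
        return (f"trn{i + 1:02d}", "tRNA", _TRNA_LEN, "+" if rng.random() < 0.6 else "-")

    # planted pairs first (each pair consumes the gap that precedes feature 2)
    planted: list[tuple[tuple, tuple, int]] = []
    a = next_pcg()
    b = next_pcg()
    planted.append((a, (b[0], b[1], b[2], a[3]), -cfg.overlap_lens[0]))
    a = next_pcg()
    b = next_pcg()
    planted.append((a, (b[0], b[1], b[2], a[3]), -cfg.overlap_lens[1]))
    orf_a = ("orfA", "orf", _ORF_LENS[1], "+")
    trn_b = next_trna()
    planted.append((orf_a, (trn_b[0], trn_b[1], trn_b[2], "-"), -cfg.overlap_lens[2]))
    for _ in range(cfg.adjacent_pairs):
        a = next_pcg()
        b = next_pcg()
        planted.append((a, b, 0))

    remaining: list[tuple[str, str, int, str]] = []
    remaining += [
        (f"pcg{i + 1:02d}", "PCG", pcg_lens[i], "+" if rng.random() < 0.6 else "-")
        for i in pcg_iter
    ]
    remaining += [
        (f"trn{i + 1:02d}", "tRNA", _TRNA_LEN, "+" if rng.random() < 0.6 else "-")
        for i in trna_iter
    ]
    remaining += [
        (f"rrn{i + 1}", "rRNA", _RRNA_LENS[i], "+" if rng.random() < 0.6 else "-")
        for i in range(cfg.n_rrna)
    ]
    if cfg.n_orf >= 3:
        remaining.append(("orfB", "orf", _ORF_LENS[2], "+" if rng.random() < 0.6 else "-"))
    rng.shuffle(remaining)

    # walk: designated orf with its two IR gaps goes first, then planted
    # pairs, then the shuffled rest, gaps drawn from the plan
    designated = ("orfIR", "orf", _ORF_LENS[0], "+")
    walk: list[tuple[tuple, int]] = []  # (entry, gap BEFORE the entry)
    walk.append((designated, ir_gap))
    plain_iter = iter(plain_gaps)
    first_after_ir = True
    for pair_a, pair_b, inner_gap in planted:
        walk.append((pair_a, ir_gap if first_after_ir else next(plain_iter)))
        first_after_ir = False
        walk.append((pair_b, inner_gap))
    for entry in remaining:
        walk.append((entry, next(plain_iter)))

    # --- materialize coordinates -------------------------------------------
    seq = _random_sequence(rng, L, cfg.at_fraction)
    features: list[Feature] = []
    cursor = 0  # 0-based position where the next gap begins
    for (name, category, length, strand), gap in walk:
        cursor += gap
        start0 = cursor % L
        end0 = (start0 + length - 1) % L
        features.append(Feature(name, category, start0 + 1, end0 + 1, strand, "ref"))
        cursor += length
    if cursor != L:
        raise PackingError(f"layout covers {cursor} bp, genome is {L} bp")

    # --- plant start codons (strand-aware) ----------------------------------
    atc_index = int(rng.integers(0, cfg.n_pcg))  # one PCG starts ATC
    pcg_seen = 0
    for f in features:
        if f.category != "PCG":
            continue
        codon = "ATC" if pcg_seen == atc_index else "ATG"
        pcg_seen += 1
        _write_codon(seq, f, codon, L)

    # --- plant the inverted repeat flanking the designated orf ---------------
    orf = next(f for f in features if f.name == "orfIR")
    unit = _random_sequence(rng, cfg.ir_unit_len, cfg.at_fraction)
    left_end0 = (orf.start - 1 - 6) % L  # 5-bp margin inside the left gap
    left_start0 = (left_end0 - cfg.ir_unit_len) % L
    right_start0 = (orf.end + 5) % L
    _write_segment(seq, left_start0, unit, L)
    rc_unit = np.array(list(reverse_complement("".join(unit))))
    _write_segment(seq, right_start0, rc_unit, L)

    # guard bases just outside both units so the pair cannot be extended and
    # is detected at exactly ir_unit_len
    right_end0 = (right_start0 + cfg.ir_unit_len) % L  # first base after right unit
    _break_pairing(seq, (left_start0 - 1) % L, right_end0)
    _break_pairing(seq, left_end0 % L, (right_start0 - 1) % L)

    genome = CircularGenome(id="ref", sequence="".join(seq),
                            metadata={"simulated": True, "seed": cfg.seed})
    ann = AnnotationSet(genome_id="ref", features=features)
    return genome, ann


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _break_pairing(seq: np.ndarray, left0: int, right0: int) -> None:
    """Ensure seq[left0] is NOT the complement of seq[right0]."""
    if seq[left0] == _COMP[seq[right0]]:
        seq[right0] = "A" if _COMP[seq[left0]] != "A" else "C"


def _write_segment(seq: np.ndarray, start0: int, content: np.ndarray, L: int) -> None:
    for off, base in enumerate(content):
        seq[(start0 + off) % L] = base


def _write_codon(seq: np.ndarray, f: Feature, codon: str, L: int) -> None:
    if f.strand == "+":
        for off, b in enumerate(codon):
            seq[(f.start - 1 + off) % L] = b
    else:
        rc = reverse_complement(codon)
        for off, b in enumerate(rc):
            seq[(f.end - 3 + off) % L] = b


def _protected_positions(ann: AnnotationSet, genome_len: int,
                         ir_region: tuple[int, int] | None) -> set[int]:
    """1-based positions SNVs must avoid: start codons and the IR region."""
    protected: set[int] = set()
    for f in ann:
        if f.category != "PCG":
            continue
        if f.strand == "+":
            protected |= {(f.start - 1 + off) % genome_len + 1 for off in range(3)}
        else:
            protected |= {(f.end - 3 + off) % genome_len + 1 for off in range(3)}
    if ir_region is not None:
        s, e = ir_region
        span = (e - s) % genome_len + 1
        protected |= {(s - 1 + off) % genome_len + 1 for off in range(span)}
    return protected


def _ir_region(ann: AnnotationSet, cfg: SimConfig, genome_len: int) -> tuple[int, int]:
    orf = next(f for f in ann if f.name == "orfIR")
    left_start = (orf.start - 1 - 6 - cfg.ir_unit_len) % genome_len + 1
    right_end = (orf.end + 5 + cfg.ir_unit_len - 1) % genome_len + 1
    return left_start, right_end


def generate_strains(
    reference: CircularGenome, ann: AnnotationSet, cfg: SimConfig
) -> TruthSet:
    """Derive the strain panel with its planted hotspot.

    Strain ``S01`` is the reference itself (the panel's reference strain);
    the remaining strains carry hotspot alleles chosen so all panel
    haplotypes over the hotspot window are pairwise distinct, plus
    strain-private Poisson background SNVs outside the hotspot.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    L = reference.length
    ir = _ir_region(ann, cfg, L)
    protected = _protected_positions(ann, L, ir)

    # hotspot window placement: uniform start, window must avoid the IR region
    ir_span = {(ir[0] - 1 + off) % L + 1 for off in range((ir[1] - ir[0]) % L + 1)}
    for _ in range(10_000):
        start = int(rng.integers(1, L + 1))
        window = [(start - 1 + off) % L + 1 for off in range(cfg.hotspot_len)]
        if not ir_span.intersection(window):
            break
    else:
        raise PackingError("could not place the hotspot window away from the IR")
    end = window[-1]

    candidates = [p for p in window if p not in protected]
    if len(candidates) < cfg.hotspot_snvs:
        raise PackingError("hotspot window has too few mutable positions")
    hot_positions = sorted(
        int(p) for p in rng.choice(candidates, size=cfg.hotspot_snvs, replace=False)
    )

    n_derived = cfg.n_strains - 1
    strains = [f"S{i + 1:02d}" for i in range(cfg.n_strains)]

    # carrier pattern: per hotspot position, a non-empty subset of derived
    # strains; resample until all panel haplotypes (incl. the all-reference
    # row for S01) are pairwise distinct
    for _ in range(10_000):
        pattern = rng.random((cfg.hotspot_snvs, n_derived)) < 0.5
        empty = ~pattern.any(axis=1)
        pattern[empty, :] = False
        for row in np.flatnonzero(empty):
            pattern[row, int(rng.integers(0, n_derived))] = True
        cols = [pattern[:, j].tobytes() for j in range(n_derived)]
        nonzero = all(pattern[:, j].any() for j in range(n_derived))
        if nonzero and len(set(cols)) == n_derived:
            break
    else:
        raise PackingError("failed to draw distinct strain haplotypes")

    alt_of: dict[int, str] = {}
    for pos in hot_positions:
        ref_base = reference.base(pos)
        choices = [b for b in "ACGT" if b != ref_base]
        alt_of[pos] = str(rng.choice(choices))

    truth: dict[str, list[SnvRecord]] = {strains[0]: []}
    used_positions = set(hot_positions)
    for j, strain in enumerate(strains[1:]):
        records = [
            SnvRecord(reference.id, pos, reference.base(pos), alt_of[pos], strain)
            for i, pos in enumerate(hot_positions)
            if pattern[i, j]
        ]
        n_bg = int(rng.poisson(cfg.background_snvs_per_strain))
        placed = 0
        while placed < n_bg:
            pos = int(rng.integers(1, L + 1))
            if pos in used_positions or pos in protected or pos in ir_span \
                    or (pos - start) % L < cfg.hotspot_len:
                continue
            ref_base = reference.base(pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            records.append(SnvRecord(reference.id, pos, ref_base, alt, strain))
            used_positions.add(pos)
            placed += 1
        truth[strain] = sorted(records, key=lambda r: r.pos)

    strain_genomes: dict[str, CircularGenome] = {}
    for strain in strains:
        strain_genomes[strain] = apply_snvs(reference, truth[strain], strain)
    return TruthSet(reference, ann, strain_genomes, truth, (start, end), cfg)


def apply_snvs(
    reference: CircularGenome, records: list[SnvRecord], strain_id: str
) -> CircularGenome:
    """Reference sequence with a strain's substitutions applied."""
    seq = list(reference.sequence)
    for rec in records:
        if seq[rec.pos - 1] != rec.ref_allele:
            raise ValueError(
                f"record at pos {rec.pos} claims ref {rec.ref_allele}, "
                f"sequence has {seq[rec.pos - 1]}"
            )
        seq[rec.pos - 1] = rec.alt_allele
    return CircularGenome(id=strain_id, sequence="".join(seq),
                          metadata={"derived_from": reference.id})


def generate_offtarget_genomes(
    cfg: SimConfig,
    n: int,
    reference: CircularGenome | None = None,
    hotspot_window: tuple[int, int] | None = None,
    flank: int = 300,
    kmer: int = 18,
) -> list[CircularGenome]:
    """Unrelated random genomes of the same length and composition.

    When the reference and its hotspot window are given, each genome is
    screened (and redrawn if needed) so it contains none of the reference's
    ``kmer``-mers from the ``flank`` bp on either side of the window — the
    would-be priming sites.  Used for specificity panels emulating a set of
    unrelated co-occurring species.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([cfg.seed, 3])
    forbidden: set[str] = set()
    if reference is not None and hotspot_window is not None:
        L = reference.length
        s, e = hotspot_window
        span = (e - s) % L + 1
        region = "".join(
            reference.base((s - 1 - flank + off) % L + 1)
            for off in range(span + 2 * flank)
        )
        forbidden = {region[i:i + kmer] for i in range(len(region) - kmer + 1)}
    genomes = []
    for i in range(n):
        for _ in range(100):
            seq = "".join(_random_sequence(rng, cfg.genome_len, cfg.at_fraction))
            doubled = seq + seq[:kmer]
            if not forbidden or not any(
                doubled[j:j + kmer] in forbidden for j in range(len(seq))
            ):
                break
        genomes.append(CircularGenome(id=f"offtarget{i + 1:03d}", sequence=seq,
                                      metadata={"simulated": True}))
    return genomes
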