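"""Degenerate primer design in conserved marker flanks and in-silico PCR.

A good intra-species marker needs conserved flanking sequence so one primer
pair amplifies it from every strain.  Candidate priming intervals are chosen
in the flanks of the marker window by counting SNV-matrix positions they
contain; each primer is the minimal IUPAC consensus of the strain sequences
over its interval, so strain variation inside a priming site becomes a
degenerate base (A/C -> M, A/G -> R, ...) rather than a mismatch.

Specificity is assessed by in-silico PCR: degenerate-aware primer matching
on both strands in convergent orientation with a per-primer mismatch budget,
exactness required at the 3' terminal bases (3' mismatches dominate
amplification failure), and product length limits.  Circular templates are
searched across the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    IUPAC_CODE,
    IUPAC_EXPAND,
    CircularGenome,
    reverse_complement,
    subsequence,
)
from .marker_scan import WindowScore
from .variants import SnvMatrix


class DesignError(ValueError):
    """No acceptable primer placement exists with the given parameters."""


# ---------------------------------------------------------------------------
# consensus

def consensus_iupac(seqs: list[str]) -> str:
    """Per-column minimal IUPAC code covering all observed bases."""
    if not seqs:
        raise ValueError("need at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    out = []
    for col in zip(*[s.upper() for s in seqs]):
        bases: set[str] = set()
        for b in col:
            bases |= IUPAC_EXPAND[b]
        out.append(IUPAC_CODE[frozenset(bases)])
    return "".join(out)


def degeneracy(primer: str) -> int:
    """Product of per-base alternative counts."""
    d = 1
    for b in primer.upper():
        d *= len(IUPAC_EXPAND[b])
    return d


def wallace_tm(primer: str) -> float:
    """Advisory melting temperature, Wallace rule: 2(A+T) + 4(G+C).

    Degenerate positions contribute the mean over their expansions.
    """
    tm = 0.0
    for b in primer.upper():
        exp = IUPAC_EXPAND[b]
        tm += sum(2.0 if x in "AT" else 4.0 for x in exp) / len(exp)
    return tm


# ---------------------------------------------------------------------------
# primer pair

@dataclass
class PrimerPair:
    """Forward/reverse IUPAC oligos with reference binding coordinates.

    ``forward`` reads 5'->3' on the plus strand starting at ``fwd_start``;
    ``reverse`` reads 5'->3' on the minus strand, and ``rev_start`` is the
    1-based plus-strand start of its reverse-complement binding site.
    """

    forward: str
    reverse: str
    fwd_start: int
    rev_start: int
    expected_amplicon_len: int
    report: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FlankInterval:
    """A candidate priming interval (1-based inclusive, may wrap)."""

    start: int
    end: int
    n_variable: int
    side: str  # "upstream" | "downstream"


def find_conserved_flanks(
    matrix: SnvMatrix,
    window: WindowScore,
    genome_len: int,
    flank_search_len: int = 150,
    primer_len: int = 18,
    max_degenerate_positions: int = 1,
    circular: bool = True,
) -> dict[str, list[FlankInterval]]:
    """Candidate priming intervals in the window's flanks.

    Within ``flank_search_len`` bp upstream and downstream of the window,
    every ``primer_len`` sub-interval containing at most
    ``max_degenerate_positions`` SNV-matrix positions is returned,
    nearest-to-window first.
    """
    if flank_search_len < primer_len:
        raise ValueError("flank_search_len must be >= primer_len")
    L = genome_len
    wspan = (window.end - window.start) % L + 1
    if not circular and (window.start - flank_search_len < 1
                         or window.start - 1 + wspan + flank_search_len > L):
        raise DesignError("window too close to the edge of a linear genome")

    positions = set(int(p) for p in matrix.positions)

    def count_variable(s: int) -> int:
        return sum(((s - 1 + off) % L + 1) in positions for off in range(primer_len))

    out: dict[str, list[FlankInterval]] = {"upstream": [], "downstream": []}
    # upstream intervals end just before window.start, nearest first
    for back in range(primer_len, flank_search_len + 1):
        s = (window.start - 1 - back) % L + 1
        e = (s - 1 + primer_len - 1) % L + 1
        nv = count_variable(s)
        if nv <= max_degenerate_positions:
            out["upstream"].append(FlankInterval(s, e, nv, "upstream"))
    # downstream intervals start just after window.end, nearest first
    for fwd in range(0, flank_search_len - primer_len + 1):
        s = (window.end + fwd) % L + 1
        e = (s - 1 + primer_len - 1) % L + 1
        nv = count_variable(s)
        if nv <= max_degenerate_positions:
            out["downstream"].append(FlankInterval(s, e, nv, "downstream"))
    return out


@dataclass
class PrimerConfig:
    primer_len: int = 18
    flank_search_len: int = 150
    max_degenerate_positions: int = 1
    max_degeneracy: int = 8
    circular: bool = True


def _strain_interval_seqs(
    reference: CircularGenome, matrix: SnvMatrix, start: int, end: int
) -> list[str]:
    """Per-strain sequences over a reference interval (matrix substitutions
    applied; the reference itself is included)."""
    L = reference.length
    ref_seq = subsequence(reference, start, end, "+")
    w = len(ref_seq)
    offsets = []
    for i, p in enumerate(matrix.positions):
        off = (int(p) - start) % L
        if off < w:
            offsets.append((i, off))
    seqs = [ref_seq]
    for j in range(len(matrix.strains)):
        hap = list(ref_seq)
        for i, off in offsets:
            if matrix.alleles[i, j] != "N":
                hap[off] = matrix.alleles[i, j]
        seqs.append("".join(hap))
    return seqs


def propose_primers(
    reference: CircularGenome,
    matrix: SnvMatrix,
    window: WindowScore,
    cfg: PrimerConfig | None = None,
) -> PrimerPair:
    """Design a degenerate primer pair bracketing ``window``.

    The nearest conserved interval on each side is used; the forward primer
    is the IUPAC consensus of the strain sequences over the upstream
    interval, the reverse primer the reverse complement of the consensus
    over the downstream interval.  Fails with :class:`DesignError` when a
    side has no conserved interval or the degeneracy cap is exceeded.
    """
    cfg = cfg or PrimerConfig()
    L = reference.length
    flanks = find_conserved_flanks(
        matrix, window, L, cfg.flank_search_len, cfg.primer_len,
        cfg.max_degenerate_positions, cfg.circular,
    )
    if not flanks["upstream"] or not flanks["downstream"]:
        raise DesignError(
            "no conserved flank interval on "
            + ("both sides" if not flanks["upstream"] and not flanks["downstream"]
               else "the upstream side" if not flanks["upstream"]
               else "the downstream side")
            + "; consider a wider flank_search_len"
        )
    up, down = flanks["upstream"][0], flanks["downstream"][0]
    forward = consensus_iupac(_strain_interval_seqs(reference, matrix, up.start, up.end))
    down_consensus = consensus_iupac(
        _strain_interval_seqs(reference, matrix, down.start, down.end)
    )
    reverse = reverse_complement(down_consensus)
    for name, primer in (("forward", forward), ("reverse", reverse)):
        if degeneracy(primer) > cfg.max_degeneracy:
            raise DesignError(
                f"{name} primer degeneracy {degeneracy(primer)} exceeds cap "
                f"{cfg.max_degeneracy}"
            )
    amplicon_len = (down.end - up.start) % L + 1
    gc = np.mean([
        sum(b in "GCS" for b in p) / len(p) for p in (forward, reverse)
    ])
    report = {
        "forward_tm": wallace_tm(forward),
        "reverse_tm": wallace_tm(reverse),
        "forward_degeneracy": degeneracy(forward),
        "reverse_degeneracy": degeneracy(reverse),
        "mean_gc_fraction": float(gc),
        "self_complement_3prime": forward[-3:] == reverse_complement(reverse[-3:]),
    }
    return PrimerPair(forward, reverse, up.start, down.start, amplicon_len, report)


# ---------------------------------------------------------------------------
# in-silico PCR

@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product (1-based inclusive plus-strand coordinates on
    the template; end < start means the product spans the origin)."""

    template_id: str
    start: int
    end: int
    length: int
    fwd_mismatches: int
    rev_mismatches: int
    strand: str  # strand carrying the forward primer


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _match_profile(primer: str, template_codes: np.ndarray, three_prime: str,
                   exact_3prime: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized degenerate matching of ``primer`` at every template offset.

    Returns (mismatch counts, 3'-clean flags), arrays over start offsets.
    ``three_prime`` says which end of the primer string is the 3' end at
    this orientation ("right" for a plus-strand forward image, "left" for
    the reverse primer's plus-strand reverse-complement image).
    """
    plen = len(primer)
    n = len(template_codes) - plen + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32), np.zeros(0, dtype=bool)
    mismatches = np.zeros(n, dtype=np.int32)
    clean3 = np.ones(n, dtype=bool)
    if three_prime == "right":
        terminal = set(range(plen - exact_3prime, plen))
    else:
        terminal = set(range(exact_3prime))
    for j, b in enumerate(primer.upper()):
        allowed = np.zeros(5, dtype=bool)
        for x in IUPAC_EXPAND[b]:
            allowed[_BASE_INDEX[x]] = True
        ok = allowed[template_codes[j:j + n]]
        mismatches += ~ok
        if j in terminal:
            clean3 &= ok
    return mismatches, clean3


def in_silico_pcr(
    pair: PrimerPair,
    templates: list[CircularGenome],
    max_mismatch: int = 2,
    min_len: int = 100,
    max_len: int = 2000,
    exact_3prime: int = 3,
) -> list[Amplicon]:
    """Predict PCR products of ``pair`` on each template.

    Forward sites on either strand are paired with reverse sites on the
    opposite strand in convergent orientation; each primer tolerates at most
    ``max_mismatch`` mismatches, none within its ``exact_3prime`` terminal
    bases (IUPAC codes in the primer match every base they cover).  Circular
    templates are searched across the origin.
    """
    products: list[Amplicon] = []
    rev_image = reverse_complement(pair.reverse)  # plus-strand image of rev site
    for template in templates:
        L = template.length
        seq = template.sequence
        search = seq + (seq[:min(L, max_len)] if template.is_circular else "")
        codes = np.fromiter((_BASE_INDEX[b] for b in search), dtype=np.int8,
                            count=len(search))
        seen: set[tuple[int, int]] = set()
        for strand in "+-":
            if strand == "-":
                rc = codes[::-1]
                codes = np.where(rc < 4, 3 - rc, 4).astype(np.int8)
            fwd_mm, fwd_ok3 = _match_profile(pair.forward, codes, "right", exact_3prime)
            rev_mm, rev_ok3 = _match_profile(rev_image, codes, "left", exact_3prime)
            fwd_sites = np.flatnonzero((fwd_mm <= max_mismatch) & fwd_ok3)
            rev_sites = np.flatnonzero((rev_mm <= max_mismatch) & rev_ok3)
            if len(fwd_sites) == 0 or len(rev_sites) == 0:
                continue
            rev_ends = rev_sites + len(rev_image)  # half-open product ends
            for f in fwd_sites:
                if f >= L:  # forward site must start within the first copy
                    continue
                lo = np.searchsorted(rev_ends, f + min_len)
                hi = np.searchsorted(rev_ends, f + max_len, side="right")
                for r_idx in range(lo, hi):
                    r = rev_sites[r_idx]
                    if r < f + len(pair.forward):
                        continue  # primers must not overlap
                    length = int(rev_ends[r_idx] - f)
                    # map back to plus-strand circular coordinates
                    if strand == "+":
                        start0 = int(f) % L
                    else:
                        start0 = (len(search) - int(rev_ends[r_idx])) % L
                    end0 = (start0 + length - 1) % L
                    key = (start0, end0)
                    if key in seen:
                        continue
                    seen.add(key)
                    products.append(Amplicon(
                        template.id, start0 + 1, end0 + 1, length,
                        int(fwd_mm[f]), int(rev_mm[r]), strand,
                    ))
    products.sort(key=lambda a: (a.template_id, a.start))
    return products


# ---------------------------------------------------------------------------
# percent identity

def percent_identity(a: str, b: str) -> float:
    """Global-alignment percent identity of two sequences.

    Unit match/mismatch/gap scores with end gaps penalized; the value is
    matches / aligned columns (gap-gap columns cannot occur in a pairwise
    alignment), as a percentage.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=-1.0,
        open_gap_score=-1.0,
        extend_gap_score=-1.0,
    )
    aln = aligner.align(a.upper(), b.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return 100.0 * matches / len(s1)
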