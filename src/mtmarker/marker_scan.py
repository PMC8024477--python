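"""Sliding-window scan for SNV-dense, strain-resolving marker regions.

The scan slides a fixed-length window (default 400 bp, the practical upper
bound for a single Illumina paired-end amplicon in metabarcoding work) along
a circular reference at 1-bp steps.  Each window is scored by

* **density** — the number of distinct SNV-matrix positions it contains, and
* **resolution** — the number of distinct strain haplotypes induced by the
  alleles at those positions (a window with no SNVs has resolution 1).

Candidates are ranked resolution-first (resolving the whole strain panel is
the point of the marker), then by density, then by leftmost start.

The implementation slides two pointers over the sorted SNV positions, so a
full 36-kb scan touches each position O(1) times; resolution is re-derived
only when the window's SNV content changes, and content sets are cached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import CircularGenome, subsequence
from .variants import SnvMatrix


@dataclass
class ScanConfig:
    """Parameters of the window scan."""

    window_len: int = 400
    step: int = 1
    circular: bool = True
    include_reference: bool = True
    min_resolution: int | None = None  # None -> size of strain panel

    def __post_init__(self) -> None:
        if self.window_len < 1 or self.step < 1:
            raise ValueError("window_len and step must be >= 1")


@dataclass(frozen=True)
class WindowScore:
    """Score of one candidate window (1-based inclusive coordinates;
    end < start means the window wraps the origin)."""

    start: int
    end: int
    density: int
    resolution: int


@dataclass
class MarkerCandidate:
    """A chosen window with the concrete per-strain haplotypes it induces."""

    window: WindowScore
    haplotypes: dict[str, str]
    rank: int = 0

    def distinct_haplotypes(self) -> int:
        return len(set(self.haplotypes.values()))


def _resolution(columns: np.ndarray, unknown_aware: bool) -> int:
    """Number of distinct strain columns of an (p, s) allele slab.

    With ``unknown_aware`` (missing-as-unknown matrices), two columns count
    as distinct only if they differ at a position where both are known.
    """
    if columns.shape[0] == 0:
        return 1
    n = columns.shape[1]
    if not unknown_aware:
        return len({columns[:, j].tobytes() for j in range(n)})
    # union-find over strains: merge pairs that are compatible everywhere
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(n):
        for b in range(a + 1, n):
            ca, cb = columns[:, a], columns[:, b]
            known = (ca != "N") & (cb != "N")
            if not (ca[known] != cb[known]).any():
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    return len({find(x) for x in range(n)})


def window_scan(
    matrix: SnvMatrix, genome_len: int, cfg: ScanConfig | None = None
) -> list[WindowScore]:
    """Score every window start (1, 1+step, ...) along the reference.

    With ``cfg.circular`` windows wrap the origin and there are exactly
    ``genome_len // step`` windows; in linear mode windows stop at the end.
    ``cfg.include_reference`` adds the reference allele vector as one more
    haplotype when counting resolution (use it when the reference genome is
    itself a member of the strain panel but not a matrix column).
    """
    cfg = cfg or ScanConfig()
    w, L = cfg.window_len, genome_len
    if w > L:
        raise ValueError(f"window_len {w} exceeds genome length {L}")
    if matrix.n_positions and int(matrix.positions.max()) > L:
        raise ValueError("matrix contains positions beyond genome length")

    alleles = matrix.alleles
    unknown_aware = bool((alleles == "N").any()) if alleles.size else False
    if cfg.include_reference and alleles.size:
        alleles = np.concatenate([alleles, matrix.ref_alleles[:, None]], axis=1)

    P = matrix.n_positions
    if cfg.circular:
        starts = range(1, L + 1, cfg.step)
    else:
        starts = range(1, L - w + 2, cfg.step)

    if P == 0:
        return [WindowScore(s, (s + w - 2) % L + 1, 0, 1) for s in starts]

    pos = matrix.positions
    # doubled coordinates let a wrap window [s, s+w-1] be a plain interval
    dpos = np.concatenate([pos, pos + L]) if cfg.circular else pos
    order = np.argsort(dpos, kind="stable")
    dpos_sorted = dpos[order]
    base_rows = np.concatenate([np.arange(P), np.arange(P)]) if cfg.circular \
        else np.arange(P)
    row_of = base_rows[order]

    scores: list[WindowScore] = []
    cache: dict[tuple[int, int], int] = {}
    lo = hi = 0
    n_dpos = len(dpos_sorted)
    for s in starts:
        while lo < n_dpos and dpos_sorted[lo] < s:
            lo += 1
        while hi < n_dpos and dpos_sorted[hi] <= s + w - 1:
            hi += 1
        density = hi - lo
        key = (lo, hi)
        res = cache.get(key)
        if res is None:
            rows = np.sort(row_of[lo:hi])
            res = _resolution(alleles[rows], unknown_aware)
            cache[key] = res
        end = (s + w - 2) % L + 1 if cfg.circular else s + w - 1
        scores.append(WindowScore(s, end, density, res))
    return scores


def rank_windows(scores: list[WindowScore]) -> list[WindowScore]:
    """Sort candidates by (resolution desc, density desc, start asc)."""
    if not scores:
        raise ValueError("no window scores to rank")
    return sorted(scores, key=lambda ws: (-ws.resolution, -ws.density, ws.start))


def extract_marker(
    reference: CircularGenome,
    matrix: SnvMatrix,
    window: WindowScore,
    include_reference: bool = True,
    rank: int = 1,
) -> MarkerCandidate:
    """Materialize per-strain haplotypes over a window.

    Each strain's haplotype is the reference subsequence with that strain's
    matrix alleles substituted at in-window positions.  With
    ``include_reference`` the unmodified reference subsequence is included
    under the reference's own id.
    """
    L = reference.length
    ref_seq = subsequence(reference, window.start, window.end, "+")
    w = len(ref_seq)

    def offset(pos: int) -> int | None:
        off = (pos - window.start) % L
        return off if off < w else None

    in_window = [
        (i, offset(int(p)))
        for i, p in enumerate(matrix.positions)
        if offset(int(p)) is not None
    ]
    haplotypes: dict[str, str] = {}
    if include_reference:
        haplotypes[reference.id] = ref_seq
    for j, strain in enumerate(matrix.strains):
        hap = list(ref_seq)
        for i, off in in_window:
            hap[off] = matrix.alleles[i, j]
        haplotypes[strain] = "".join(hap)
    return MarkerCandidate(window=window, haplotypes=haplotypes, rank=rank)


def scores_to_frame(scores: list[WindowScore]):
    """TSV-ready DataFrame of all window scores."""
    import pandas as pd

    return pd.DataFrame(
        {
            "start": [s.start for s in scores],
            "end": [s.end for s in scores],
            "density": [s.density for s in scores],
            "resolution": [s.resolution for s in scores],
        }
    )


def windows_to_bed(scores: list[WindowScore], genome_id: str, genome_len: int, path) -> None:
    """Write candidate windows as BED (0-based half-open; wrap windows split)."""
    with open(path, "w") as fh:
        for s in scores:
            if s.start <= s.end:
                fh.write(f"{genome_id}\t{s.start - 1}\t{s.end}\t"
                         f"res{s.resolution}_dens{s.density}\n")
            else:
                name = f"res{s.resolution}_dens{s.density}"
                fh.write(f"{genome_id}\t{s.start - 1}\t{genome_len}\t{name}\n")
                fh.write(f"{genome_id}\t0\t{s.end}\t{name}\n")
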