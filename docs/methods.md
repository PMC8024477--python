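# Methods

## Problem setting

Conspecific strains of bloom-forming microalgae are often indistinguishable
at the common barcode loci, yet their organelle genomes accumulate enough
fixed single-nucleotide variants (SNVs) to separate them. `mtmarker`
formalizes the resulting marker-discovery task: given a circular reference
mtDNA and homozygous SNV calls for a panel of strains, find a short window
whose allele patterns give every strain a distinct haplotype, and make that
window amplifiable with one degenerate primer pair that touches nothing
else.

## Coordinates and circularity

Internally all coordinates are 0-based half-open; every file format and
report is 1-based inclusive (GenBank/GFF3 style). A feature or window with
`start > end` wraps the origin natively — it is never split into two
records — so interval arithmetic (spacers, overlaps, windows, flanks,
amplicons) is circular throughout. Wrap-origin GFF3 records (`end < start`)
violate the GFF3 standard; the package reads and writes them deliberately,
which is why its GFF3 layer is a minimal in-house parser rather than a
validating library.

## Variant input

Three routes produce per-strain SNV sets:

* **Read filtering** (pre-screen only): a read is dropped when strictly
  more than 50% of its bases are below Phred 5, or when ≥ 10% of its bases
  are N. Adapter trimming is left to external preprocessing; mapping and
  probabilistic genotype calling are likewise out of scope — users with raw
  reads should call variants with a standard mapper/caller stack and feed
  in VCFs.
* **Homozygous filter for VCF input**: calls with alternate-allele
  frequency ≥ 0.85 are kept. The threshold is inclusive, following the
  semantics of a caller's minimum-frequency-for-homozygous option (a
  prose reading of "support > 85%" would be exclusive; the executable
  option value wins and the discrepancy is noted here). Non-SNV records
  (indels, MNVs) are skipped and counted.
* **Genome-vs-genome calling**: colinear near-identical genomes (≥ 95%
  identity) are anchored on k-mers unique in both sequences (k = 21 —
  effectively unique in a 36-kb genome), chained by longest increasing
  subsequence; equal-length inter-anchor segments are diffed base by base,
  length-changed segments (indels) are masked with a warning, and positions
  involving N are skipped. Short or repeat-dense inputs without enough
  unique anchors fall back to a direct positional diff when lengths are
  equal, guarded by the same identity threshold.

The merged matrix takes the union of positions over strains; a strain
without a call at a position is assumed to carry the reference allele (an
optional missing-as-unknown mode marks it N and excludes it from haplotype
comparison). Conflicting reference-allele claims are a hard error.

## Window scan

`window_scan` scores every window start 1, 1+step, … (default step 1,
circular, so exactly L windows). Density counts distinct matrix positions
in the window; resolution counts distinct strain allele vectors restricted
to those positions (zero SNVs ⇒ resolution 1; in missing-as-unknown mode
two haplotypes are distinct only if they differ where both are known). The
reference can be counted as an extra panel member (`include_reference`) for
matrices that do not carry it as a column. The implementation slides two
pointers over the position array doubled modulo L, so the full scan is
O(L + P·S) rather than O(L·w); resolution is recomputed only when the
window's SNV content changes and content sets are cached. Ranking is
(resolution desc, density desc, start asc): resolving the whole panel is
the stated goal, so it dominates raw density; the leftmost tie-break makes
results deterministic.

## Primer design and in-silico PCR

Within a configurable search range (default 150 bp) on each side of the
chosen window, every primer-length interval (default 18 bp) containing at
most `max_degenerate_positions` (default 1) matrix positions is a
candidate, nearest-to-window first. The forward primer is the minimal
IUPAC consensus of the per-strain sequences over the chosen upstream
interval; the reverse primer is the reverse complement of the downstream
consensus, reported 5′→3′ on the antisense strand as is conventional. The
degeneracy cap (product of per-base alternative counts) defaults to 8.
Melting temperature is advisory only, by the Wallace rule 2(A+T) + 4(G+C),
averaged over degenerate expansions.

In-silico PCR matches both primers degenerate-aware (a primer's IUPAC code
matches every base it covers) on both strands in convergent orientation,
with at most 2 mismatches per primer and none in the 3 terminal 3′ bases —
3′ mismatches dominate amplification failure, so exactness there is the
discriminating constraint. Product length limits default to 100–2,000 bp;
circular templates are searched across the origin by extending the
sequence one maximal product length. Matching is vectorized per primer
position over all template offsets, so a 36-kb template costs a few dozen
numpy slice operations.

Percent identity between two sequences is computed from a global alignment
with unit match/mismatch/gap scores and end gaps penalized (matches divided
by aligned columns, as a percentage).

## Trees

Strain distinguishability — not branch support — is the question the
package answers, so trees are p-distance + neighbor joining rather than
likelihood-based. p-distances exclude sites with N in either sequence. NJ
is the standard Q-criterion agglomeration with negative branch lengths
clamped to zero and ties broken at the lowest active (i, j) index pair,
making it fully deterministic; on additive matrices it recovers topology
and all leaf-to-leaf path lengths exactly (verified against scikit-bio's
implementation as an independent oracle). Robinson–Foulds distance counts
non-trivial bipartitions present in exactly one tree.

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults are the study conditions the pipeline targets: a
36,162-bp circular genome at 74.9% AT; 35 protein-coding genes, 24 tRNAs,
2 rRNAs and 3 orfs packed with geometric spacers of mean 39 bp; two
planted 20-bp same-strand overlaps and one 9-bp opposite-strand overlap;
three zero-gap adjacent gene pairs; one exact 129-bp inverted-repeat pair
flanking a designated orf in the intergenic space; ATG start codons with a
single planted ATC starter; 8 strains (the first being the reference
itself, as reference strains usually are panel members) with 26 hotspot
SNV positions inside one 400-bp window and Poisson(3) strain-private
background SNVs elsewhere.

Design choices made where the layout was open: tRNAs are 72 bp, rRNAs
1,800/1,100 bp and orfs 297/477/303 bp (field-realistic sizes for compact
diatom mitogenomes); protein-coding genes absorb the remaining length
budget as random multiples-of-3 above 150 bp, so the circle closes at
exactly the configured genome length. Hotspot haplotype distinctness is
enforced by rejection sampling over carrier patterns — the real panel's
strains merely happen to be distinct; the simulator guarantees it so
recovery properties are well-posed. SNVs avoid start codons and the IR
region so the stats audit and the scan stay independent; bases flanking
the planted IR are set non-complementary so detection reports exactly the
configured unit length. Off-target genomes are screened to share no 18-mer
with the hotspot's ±300-bp flanks, making the specificity loop a test of
the matcher, not of lucky k-mer collisions.

What the generator does **not** emulate: sequencing errors and read-level
artifacts (variants enter as genomes or VCFs), real codon structure beyond
the start codon, shared polymorphisms between strains (off by default; a
flag enables them), rearrangements, indels, and introns. Passing tests
therefore demonstrate correctness of the window scan, calling, design and
tree machinery under the stated variant model — not robustness to
assembly or mapping artifacts in real data.

## Numerical and degenerate-input conventions

AT content excludes N from the denominator and errors on all-N input.
Intergenic accounting pools both strands and counts overlapped positions
once, so merged feature coverage plus spacer total always equals genome
length; mean spacer length is reported rounded to the nearest bp. The
inverted-repeat scan is seed-and-extend (16-bp seeds) reporting maximal
pairs within the mismatch budget, excluding self-overlapping units, and
dropping pairs contained in longer reported pairs; defaults (min unit 50,
max spacer 2,000, exact match) are tuned to find one short IR pair in a
compact genome without flooding the report. Gene presence/absence applies
a case-insensitive synonym map (shipped as an editable TSV) and counts a
split gene present when both halves are. Window ties, NJ ties and ranking
are all broken deterministically as described above, and all simulator
randomness derives from a single seed through per-component child streams.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the scan-vs-recount
equivalence on 1,000 random instances (genomes ≤ 2 kb, windows ≤ 50),
hotspot recovery on 100 full-size seeded panels, variant recovery on 50
panels (400 strain genomes), specificity against 100 unrelated genomes,
and NJ exactness on 200 random trees of ≤ 12 leaves — sizes chosen so the
whole battery completes in about a minute while keeping every check at the
method's native genome scale where it matters.

## Known limitations

* The genome-vs-genome caller assumes a shared origin and orientation; it
  does not detect rearrangements, and masks rather than realigns indels.
* Primer quality checks are heuristic (degeneracy, GC, Wallace Tm, 3′
  self-complement flag); no nearest-neighbor thermodynamics or dimer ΔG.
* NJ trees carry no support values; they answer "how many distinct
  leaves", not "which branching order is credible".
* The in-silico PCR mismatch model treats all non-3′ positions equally;
  position-weighted or thermodynamic binding models are out of scope.
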