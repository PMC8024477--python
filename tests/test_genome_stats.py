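import numpy as np
import pytest

from conftest import random_annotation
from mtmarker.genome_io import AnnotationSet, CircularGenome, Feature, reverse_complement
from mtmarker.genome_stats import (
    UndefinedContentError,
    at_content,
    find_adjacent_pairs,
    find_inverted_repeats,
    find_overlaps,
    gc_content,
    gene_content_matrix,
    intergenic_spacers,
    start_codon_table,
)


class TestComposition:
    @pytest.mark.parametrize("seq,expected", [
        ("ATAT", 1.0), ("GCGC", 0.0), ("AATGC", 0.6), ("AANTGC", 3 / 5),
    ])
    def test_at_content(self, seq, expected):
        assert at_content(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        with pytest.raises(UndefinedContentError):
            at_content("NNN")

    def test_at_plus_gc_is_one(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        assert at_content(seq) + gc_content(seq) == pytest.approx(1.0)


class TestSpacers:
    def test_single_gap(self, toy_annotation):
        g = CircularGenome("g", "A" * 100)
        spacers, summary = intergenic_spacers(g, toy_annotation)
        assert [(s.start, s.end, s.length) for s in spacers] == [(41, 60, 20)]
        assert summary["total_bp"] == 20 and summary["mean_length"] == 20

    def test_full_coverage(self):
        g = CircularGenome("g", "A" * 100)
        ann = AnnotationSet("g", [Feature("f", "PCG", 1, 100, "+", "g")])
        spacers, summary = intergenic_spacers(g, ann)
        assert spacers == [] and summary["total_bp"] == 0

    def test_no_features_whole_circle(self):
        g = CircularGenome("g", "A" * 100)
        spacers, summary = intergenic_spacers(g, AnnotationSet("g", []))
        assert summary["total_bp"] == 100 and len(spacers) == 1

    def test_wrap_spacer_merged(self):
        # feature in the middle: the two flanking gaps merge across the origin
        g = CircularGenome("g", "A" * 100)
        ann = AnnotationSet("g", [Feature("f", "PCG", 41, 60, "+", "g")])
        spacers, summary = intergenic_spacers(g, ann)
        assert len(spacers) == 1
        (s,) = spacers
        assert (s.start, s.end, s.length) == (61, 40, 80)

    @pytest.mark.parametrize("seed", range(5))
    def test_coverage_conservation(self, seed):
        """Merged feature coverage + total spacer bp = genome length."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(50, 400))
        g = CircularGenome("g", "A" * L)
        ann = random_annotation(rng, L, int(rng.integers(0, 8)))
        spacers, summary = intergenic_spacers(g, ann)
        covered = set()
        for f in ann:
            for s0, e0 in f.segments0(L):
                covered |= set(range(s0, e0))
        assert len(covered) + summary["total_bp"] == L
        assert sum(s.length for s in spacers) == summary["total_bp"]


def brute_force_overlap(a: Feature, b: Feature, L: int) -> int:
    pa = {p for s, e in a.segments0(L) for p in range(s, e)}
    pb = {p for s, e in b.segments0(L) for p in range(s, e)}
    return len(pa & pb)


class TestOverlapsAndAdjacency:
    def test_same_strand_overlap(self):
        ann = AnnotationSet("g", [Feature("A", "PCG", 10, 50, "+", "g"),
                                  Feature("B", "PCG", 31, 80, "+", "g")])
        (rec,) = find_overlaps(ann, 100)
        assert (rec.overlap_len, rec.orientation) == (20, "same-strand")

    def test_disjoint(self):
        ann = AnnotationSet("g", [Feature("A", "PCG", 1, 10, "+", "g"),
                                  Feature("B", "PCG", 20, 30, "+", "g")])
        assert find_overlaps(ann, 100) == []

    def test_wrap_overlap(self):
        ann = AnnotationSet("g", [Feature("A", "PCG", 91, 10, "+", "g"),
                                  Feature("B", "PCG", 5, 20, "-", "g")])
        (rec,) = find_overlaps(ann, 100)
        assert rec.overlap_len == 6 and rec.orientation == "opposite-strand"

    @pytest.mark.parametrize("seed", range(10))
    def test_against_membership_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(20, 200))
        ann = random_annotation(rng, L, 6)
        got = {frozenset((r.feature_a, r.feature_b)): r.overlap_len
               for r in find_overlaps(ann, L)}
        feats = list(ann)
        want = {}
        for i in range(len(feats)):
            for j in range(i + 1, len(feats)):
                ov = brute_force_overlap(feats[i], feats[j], L)
                if ov:
                    want[frozenset((feats[i].name, feats[j].name))] = ov
        assert got == want

    def test_adjacent(self):
        ann = AnnotationSet("g", [Feature("A", "PCG", 1, 10, "+", "g"),
                                  Feature("B", "PCG", 11, 20, "+", "g")])
        assert find_adjacent_pairs(ann, 100) == [("A", "B")]

    def test_gap_of_one_not_adjacent(self):
        ann = AnnotationSet("g", [Feature("A", "PCG", 1, 10, "+", "g"),
                                  Feature("B", "PCG", 12, 20, "+", "g")])
        assert find_adjacent_pairs(ann, 100) == []

    def test_adjacent_across_origin(self):
        ann = AnnotationSet("g", [Feature("A", "PCG", 95, 100, "+", "g"),
                                  Feature("B", "PCG", 1, 5, "+", "g")])
        assert find_adjacent_pairs(ann, 100) == [("A", "B")]


def plant_ir(rng, length, unit_len, gap, mismatches=0):
    seq = rng.choice(list("ACGT"), size=length, p=[.35, .15, .15, .35])
    unit = rng.choice(list("ACGT"), size=unit_len, p=[.35, .15, .15, .35])
    left = 200
    right = left + unit_len + gap
    seq[left:left + unit_len] = unit
    rc = list(reverse_complement("".join(unit)))
    seq[right:right + unit_len] = rc
    for i in range(mismatches):
        pos = right + 10 + 7 * i
        old = seq[pos]
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
    # guard flanks so the planted pair is maximal at exactly unit_len
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if seq[left - 1] == comp[seq[right + unit_len]]:
        seq[right + unit_len] = "A" if comp[seq[left - 1]] != "A" else "C"
    if seq[left + unit_len] == comp[seq[right - 1]]:
        seq[right - 1] = "A" if comp[seq[left + unit_len]] != "A" else "C"
    return CircularGenome("g", "".join(seq)), left + 1, right + 1


class TestInvertedRepeats:
    def test_exact_planted_pair(self):
        rng = np.random.default_rng(1)
        g, left, right = plant_ir(rng, 2000, 129, 300)
        pairs = find_inverted_repeats(g, min_len=50, max_spacer=2000, max_mismatch=0)
        assert any((p.left_start, p.right_start, p.unit_len, p.mismatches)
                   == (left, right, 129, 0) for p in pairs)

    def test_homopolymer_has_no_pair(self):
        g = CircularGenome("g", "A" * 40)
        assert find_inverted_repeats(g, min_len=8, max_spacer=40) == []

    def test_mismatch_budget(self):
        rng = np.random.default_rng(2)
        g, left, right = plant_ir(rng, 2000, 129, 300, mismatches=1)
        with_budget = find_inverted_repeats(g, min_len=50, max_spacer=2000, max_mismatch=1)
        assert any(p.unit_len == 129 and p.mismatches == 1 for p in with_budget)
        exact = find_inverted_repeats(g, min_len=50, max_spacer=2000, max_mismatch=0)
        assert all(p.unit_len < 129 for p in exact)

    def test_min_len_precondition(self):
        g = CircularGenome("g", "ACGT" * 10)
        with pytest.raises(ValueError):
            find_inverted_repeats(g, min_len=3)

    def test_invariant_under_genome_revcomp(self):
        rng = np.random.default_rng(3)
        g, _, _ = plant_ir(rng, 1500, 60, 100)
        L = g.length
        rc = CircularGenome("rc", reverse_complement(g.sequence))
        fwd = find_inverted_repeats(g, min_len=50, max_spacer=2000)
        rev = find_inverted_repeats(rc, min_len=50, max_spacer=2000)
        mapped = {
            (L - (p.right_start + p.unit_len - 1) + 1,
             L - (p.left_start + p.unit_len - 1) + 1,
             p.unit_len, p.mismatches)
            for p in fwd
        }
        got = {(p.left_start, p.right_start, p.unit_len, p.mismatches) for p in rev}
        assert mapped == got


class TestStartCodons:
    def test_plus_strand(self):
        g = CircularGenome("g", "ATGAAATAGC")
        ann = AnnotationSet("g", [Feature("nad1", "PCG", 1, 9, "+", "g")])
        assert start_codon_table(g, ann) == {"nad1": "ATG"}

    def test_minus_strand(self):
        g = CircularGenome("g", "CTATTTCAT")
        ann = AnnotationSet("g", [Feature("nad1", "PCG", 1, 9, "-", "g")])
        assert start_codon_table(g, ann) == {"nad1": "ATG"}

    def test_non_atg_reported_verbatim(self):
        g = CircularGenome("g", "ATCAAATAGC")
        ann = AnnotationSet("g", [Feature("atp8", "PCG", 1, 9, "+", "g")])
        assert start_codon_table(g, ann)["atp8"] == "ATC"

    def test_too_short_rejected(self):
        g = CircularGenome("g", "ATCAAATAGC")
        ann = AnnotationSet("g", [Feature("x", "PCG", 1, 2, "+", "g")])
        with pytest.raises(ValueError):
            start_codon_table(g, ann)

    def test_wrap_origin_feature(self):
        # gene starts 2 bp before the origin on the plus strand
        g = CircularGenome("g", "GTAAACCCAT")
        ann = AnnotationSet("g", [Feature("w", "PCG", 9, 6, "+", "g")])
        assert start_codon_table(g, ann) == {"w": "ATG"}


class TestGeneContent:
    def make(self, gid, names):
        return AnnotationSet(gid, [Feature(n, "PCG", 1 + 10 * i, 9 + 10 * i, "+", gid)
                                   for i, n in enumerate(names)])

    def test_absence_marked(self):
        anns = [self.make("g1", ["rps2", "rps4"]), self.make("g2", ["rps4"])]
        df = gene_content_matrix(anns, ["rps2", "rps4"])
        assert bool(df.loc["g1", "rps2"]) and not bool(df.loc["g2", "rps2"])
        assert bool(df.loc["__missing_anywhere__", "rps2"])

    def test_all_present(self):
        anns = [self.make("g1", ["cob", "cox1"]), self.make("g2", ["cox1", "cob"])]
        df = gene_content_matrix(anns, ["cob", "cox1"])
        assert df.drop(index="__missing_anywhere__").all().all()

    def test_synonym_resolution(self):
        anns = [self.make("g1", ["rnl"]), self.make("g2", ["LSU rRNA"])]
        df = gene_content_matrix(anns, ["rrnL"])
        assert df.drop(index="__missing_anywhere__").all().all()

    def test_split_gene_counts_when_both_halves_present(self):
        anns = [self.make("g1", ["nad11_1", "nad11_2"]), self.make("g2", ["nad11_1"])]
        df = gene_content_matrix(anns, ["nad11"])
        assert bool(df.loc["g1", "nad11"]) and not bool(df.loc["g2", "nad11"])
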