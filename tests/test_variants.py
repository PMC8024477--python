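import numpy as np
import pytest

from mtmarker.genome_io import CircularGenome, ReadRecord
from mtmarker.variants import (
    ColinearityError,
    DataConsistencyError,
    ReadFilterConfig,
    SnvRecord,
    build_snv_matrix,
    call_snvs_from_genomes,
    filter_homozygous,
    filter_reads,
    read_vcf_per_strain,
    write_matrix_vcf,
    write_strain_vcf,
)


class TestReadFilter:
    def make(self, bases, quals):
        return ReadRecord("r", bases, quals)

    def test_majority_lowqual_removed(self):
        reads = [self.make("ACGTACGTAC", [4] * 6 + [30] * 4)]
        kept, removed = filter_reads(reads)
        assert kept == [] and removed["low_quality"] == 1

    def test_half_lowqual_kept(self):
        # exactly 50% low-quality bases does not exceed the strict threshold
        reads = [self.make("ACGTACGTAC", [4] * 5 + [30] * 5)]
        kept, _ = filter_reads(reads)
        assert len(kept) == 1

    def test_ten_percent_n_removed(self):
        reads = [self.make("ACGTACGTAN", [30] * 10)]
        kept, removed = filter_reads(reads)
        assert kept == [] and removed["too_many_n"] == 1

    def test_clean_read_kept(self):
        reads = [self.make("ACGTACGTAC", [30] * 10)]
        kept, removed = filter_reads(reads)
        assert len(kept) == 1 and sum(removed.values()) == 0

    def test_first_matching_rule_attributed(self):
        reads = [self.make("NNNNNNNNNN", [2] * 10)]
        _, removed = filter_reads(reads)
        assert removed == {"low_quality": 1, "too_many_n": 0}

    def test_empty_input(self):
        kept, removed = filter_reads([])
        assert kept == [] and sum(removed.values()) == 0

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            ReadFilterConfig(max_lowqual_fraction=1.5)


class TestHomozygousFilter:
    def snv(self, freq):
        return SnvRecord("g", 5, "A", "G", "S1", freq)

    @pytest.mark.parametrize("freq,kept", [(0.90, True), (0.85, True), (0.84, False)])
    def test_boundary(self, freq, kept):
        assert bool(filter_homozygous([self.snv(freq)])) is kept

    def test_idempotent(self):
        snvs = [self.snv(f) for f in (0.2, 0.85, 0.9, 1.0)]
        once = filter_homozygous(snvs)
        assert filter_homozygous(once) == once

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            filter_homozygous([], min_freq=0.0)


REF = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTA"


class TestCallSnvs:
    def test_identical_genomes_empty(self):
        ref = CircularGenome("r", REF)
        strain = CircularGenome("s", REF)
        assert call_snvs_from_genomes(ref, strain) == []

    def test_single_substitution(self):
        seq = REF[:4] + "G" + REF[5:]  # pos 5 A->G
        calls = call_snvs_from_genomes(CircularGenome("r", REF), CircularGenome("s", seq))
        assert [(c.pos, c.ref_allele, c.alt_allele) for c in calls] == [(5, "A", "G")]

    def test_n_position_skipped(self):
        seq = REF[:4] + "N" + REF[5:]
        calls = call_snvs_from_genomes(CircularGenome("r", REF), CircularGenome("s", seq))
        assert calls == []

    def test_unrelated_sequences_not_colinear(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), size=500))
        b = "".join(rng.choice(list("ACGT"), size=500))
        with pytest.raises(ColinearityError):
            call_snvs_from_genomes(CircularGenome("r", a), CircularGenome("s", b))

    def test_indel_segment_masked_not_called(self, caplog):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        # deletion of 5 bp in the middle plus a substitution far away
        mutated = seq[:300] + seq[305:]
        mutated = "T" + mutated[1:] if seq[0] != "T" else "G" + mutated[1:]
        calls = call_snvs_from_genomes(CircularGenome("r", seq),
                                       CircularGenome("s", mutated))
        assert all(c.pos < 250 or c.pos > 350 for c in calls)

    @pytest.mark.parametrize("seed,n_mut", [(0, 10), (1, 50), (2, 200)])
    def test_parameter_recovery(self, seed, n_mut):
        """Random planted substitutions are recovered exactly."""
        rng = np.random.default_rng(seed)
        L = 8000
        seq = "".join(rng.choice(list("ACGT"), size=L, p=[.35, .15, .15, .35]))
        positions = sorted(rng.choice(L, size=n_mut, replace=False).tolist())
        mutated = list(seq)
        truth = []
        for p in positions:
            alt = rng.choice([b for b in "ACGT" if b != seq[p]])
            mutated[p] = alt
            truth.append((p + 1, seq[p], str(alt)))
        calls = call_snvs_from_genomes(CircularGenome("r", seq),
                                       CircularGenome("s", "".join(mutated)))
        assert [(c.pos, c.ref_allele, c.alt_allele) for c in calls] == truth


class TestMatrix:
    def ref(self):
        return CircularGenome("r", "GGAC" + "T" * 20)

    def test_union_merge_by_hand(self):
        ref = self.ref()  # pos3=A, pos4=C
        per = {"S1": [SnvRecord("r", 3, "A", "T", "S1")],
               "S2": [SnvRecord("r", 3, "A", "T", "S2"), SnvRecord("r", 4, "C", "G", "S2")]}
        m = build_snv_matrix(ref, per)
        assert m.positions.tolist() == [3, 4]
        assert m.strain_column("S1").tolist() == ["T", "C"]
        assert m.strain_column("S2").tolist() == ["T", "G"]

    def test_empty(self):
        m = build_snv_matrix(self.ref(), {"S1": [], "S2": []})
        assert m.n_positions == 0 and m.strains == ["S1", "S2"]

    def test_ref_claim_conflict(self):
        ref = self.ref()
        per = {"S1": [SnvRecord("r", 3, "A", "T", "S1")],
               "S2": [SnvRecord("r", 3, "C", "G", "S2")]}
        with pytest.raises(DataConsistencyError):
            build_snv_matrix(ref, per)

    def test_ref_mismatch_with_sequence(self):
        per = {"S1": [SnvRecord("r", 1, "A", "T", "S1")]}  # sequence has G at 1
        with pytest.raises(DataConsistencyError):
            build_snv_matrix(self.ref(), per)

    def test_order_independent(self):
        ref = self.ref()
        a = {"S1": [SnvRecord("r", 3, "A", "T", "S1")],
             "S2": [SnvRecord("r", 4, "C", "G", "S2")]}
        b = dict(reversed(list(a.items())))
        ma, mb = build_snv_matrix(ref, a), build_snv_matrix(ref, b)
        assert ma.strains == mb.strains
        assert (ma.alleles == mb.alleles).all()

    def test_missing_as_unknown_mode(self):
        ref = self.ref()
        per = {"S1": [SnvRecord("r", 3, "A", "T", "S1")], "S2": []}
        m = build_snv_matrix(ref, per, missing_as_unknown=True)
        assert m.strain_column("S2").tolist() == ["N"]


class TestVcf:
    def test_round_trip_single_strain(self, tmp_path):
        ref = CircularGenome("r", "GGACTTTT")
        records = [SnvRecord("r", 3, "A", "T", "S1", 0.9),
                   SnvRecord("r", 4, "C", "G", "S1", 1.0)]
        p = tmp_path / "s1.vcf"
        write_strain_vcf(records, ref, p)
        back = read_vcf_per_strain({"S1": p}, ref)["S1"]
        assert [(r.pos, r.ref_allele, r.alt_allele) for r in back] == \
               [(3, "A", "T"), (4, "C", "G")]
        assert back[0].alt_frequency == pytest.approx(0.9)

    def test_indel_rows_skipped(self, tmp_path):
        ref = CircularGenome("r", "GGACTTTT")
        p = tmp_path / "i.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=r,length=8>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "r\t3\t.\tAC\tA\t.\tPASS\t.\tGT\t1/1\n"
            "r\t4\t.\tC\tG\t.\tPASS\t.\tGT\t1/1\n")
        back = read_vcf_per_strain({"S1": p}, ref)["S1"]
        assert [(r.pos, r.alt_allele) for r in back] == [(4, "G")]

    def test_low_frequency_call_chains_into_filter(self, tmp_path):
        ref = CircularGenome("r", "GGACTTTT")
        p = tmp_path / "f.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=r,length=8>\n"
            '##INFO=<ID=AF,Number=1,Type=Float,Description="AF">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "r\t3\t.\tA\tG\t.\tPASS\tAF=0.80\tGT\t0/1\n")
        back = read_vcf_per_strain({"S1": p}, ref)["S1"]
        assert back[0].alt_frequency == pytest.approx(0.80)
        assert filter_homozygous(back) == []

    def test_chrom_mismatch_rejected(self, tmp_path):
        ref = CircularGenome("r", "GGACTTTT")
        p = tmp_path / "c.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=other,length=8>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "other\t3\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\n")
        with pytest.raises(DataConsistencyError):
            read_vcf_per_strain({"S1": p}, ref)

    def test_matrix_vcf_round_trip(self, tmp_path):
        ref = CircularGenome("r", "GGACTTTT")
        per = {"S1": [SnvRecord("r", 3, "A", "T", "S1")],
               "S2": [SnvRecord("r", 3, "A", "T", "S2"),
                      SnvRecord("r", 4, "C", "G", "S2")]}
        m = build_snv_matrix(ref, per)
        p = tmp_path / "m.vcf"
        write_matrix_vcf(m, ref, p)
        from cyvcf2 import VCF

        rows = list(VCF(str(p)))
        assert [(r.POS, r.REF, tuple(r.ALT)) for r in rows] == \
               [(3, "A", ("T",)), (4, "C", ("G",))]
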