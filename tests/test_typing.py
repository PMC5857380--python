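import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmlst.scheme import LocusDefinition, SequenceRecord
from kmlst.typing import (
    AlleleCatalog,
    CallError,
    MergeError,
    build_reference_allele,
    call_allele,
    classify_site,
    find_polymorphic_sites,
    merge_strand_reads,
)
from kmlst.iupac import reverse_complement


def _pair(fwd_seq, rev_oriented_seq):
    """Build a read pair whose reverse read, once flipped, reads
    ``rev_oriented_seq``."""
    fwd = SequenceRecord(id="s|L", sequence=fwd_seq, strand="forward")
    rev = SequenceRecord(id="s|L", sequence=reverse_complement(rev_oriented_seq),
                         strand="reverse")
    return fwd, rev


class TestMergeStrandReads:
    def test_identical_strands(self):
        res = merge_strand_reads(*_pair("ACGT", "ACGT"))
        assert res.record.sequence == "ACGT"
        assert res.conflicts == []
        assert res.heterozygous_positions == []

    def test_double_peak_on_both_strands_is_heterozygous(self):
        res = merge_strand_reads(*_pair("ARGT", "ARGT"))
        assert res.record.sequence == "ARGT"
        assert res.heterozygous_positions == [2]

    def test_intersection_resolves_one_sided_ambiguity(self):
        res = merge_strand_reads(*_pair("R", "A"))
        assert res.record.sequence == "A"
        assert res.heterozygous_positions == []

    def test_conflict_becomes_n_and_is_reported(self):
        res = merge_strand_reads(*_pair("ACGTACGTACGTACGTACGTA",
                                        "ACGTACGTACGTACGTACGTC"))
        assert res.record.sequence.endswith("N")
        assert res.conflicts == [(21, "A", "C")]

    def test_conflict_threshold(self):
        with pytest.raises(MergeError, match="conflict"):
            merge_strand_reads(*_pair("AAAA", "CCCC"))

    def test_length_mismatch(self):
        fwd = SequenceRecord(id="s", sequence="ACGT", strand="forward")
        rev = SequenceRecord(id="s", sequence="ACG", strand="reverse")
        with pytest.raises(MergeError, match="length"):
            merge_strand_reads(fwd, rev)

    def test_symmetric_up_to_strand_bookkeeping(self):
        # exchanging which physical read is labelled "forward" flips the
        # consensus onto the other strand but changes nothing else
        fwd, rev = _pair("ACGRWT", "ACGAWT")
        swapped_fwd = SequenceRecord(id="s", sequence=rev.sequence,
                                     strand="forward")
        swapped_rev = SequenceRecord(id="s", sequence=fwd.sequence,
                                     strand="reverse")
        a = merge_strand_reads(fwd, rev).record.sequence
        b = merge_strand_reads(swapped_fwd, swapped_rev).record.sequence
        assert a == reverse_complement(b)


class TestBuildReferenceAllele:
    def test_identical_inputs(self):
        assert build_reference_allele(["ACGT", "ACGT"]) == "ACGT"

    def test_majority_site(self):
        assert build_reference_allele(["ACGT", "ACGT", "ACGT", "GCGT"]) == "ACGT"

    def test_weighted_majority(self):
        # one allele carried by three strains outvotes two distinct singles
        assert build_reference_allele(["AAAA", "GAAA", "TAAA"],
                                      weights=[3, 1, 1]) == "AAAA"

    def test_tie_breaks_alphabetically(self):
        assert build_reference_allele(["AT", "AT", "GT", "GT"]) == "AT"

    def test_empty_input(self):
        with pytest.raises(ValueError):
            build_reference_allele([])


class TestAlleleCatalog:
    def test_reference_call_is_genotype_one(self):
        cat = AlleleCatalog.from_sequences("L", ["ACGT", "ACGA", "ACGT"])
        rec = SequenceRecord(id="q|L", sequence=cat.reference)
        assert call_allele(rec, cat).genotype == 1

    def test_novel_gets_next_number_and_registration_is_idempotent(self):
        import itertools
        cat = AlleleCatalog("SGA1", 4)
        for combo in itertools.islice(itertools.product("ACGT", repeat=4), 26):
            cat.add("".join(combo))
        assert len(cat) == 26
        novel = SequenceRecord(id="q|SGA1", sequence="GGGG")
        first = call_allele(novel, cat, allow_novel=True)
        assert first.genotype == 27 and first.is_novel
        again = call_allele(novel, cat, allow_novel=True)
        assert again.genotype == 27 and not again.is_novel

    def test_miss_without_novel_registration(self):
        cat = AlleleCatalog.from_sequences("L", ["ACGT"])
        res = call_allele(SequenceRecord(id="q", sequence="TTTT"), cat)
        assert res.genotype is None and not res.matched
        assert len(cat) == 1

    def test_single_site_difference_is_distinct_genotype(self):
        cat = AlleleCatalog.from_sequences("L", ["ACGT"], seed_reference=False)
        res = call_allele(SequenceRecord(id="q", sequence="ACGA"), cat,
                          allow_novel=True)
        assert res.genotype == 2 and res.is_novel

    def test_heterozygous_literal_identity(self):
        # A vs R differ as genotypes even though R contains A
        cat = AlleleCatalog.from_sequences("L", ["AAAA"], seed_reference=False)
        res = call_allele(SequenceRecord(id="q", sequence="AARA"), cat,
                          allow_novel=True)
        assert res.genotype == 2
        assert res.heterozygous_positions == [3]

    def test_length_mismatch_rejected(self):
        cat = AlleleCatalog.from_sequences("L", ["ACGT"])
        with pytest.raises(CallError, match="length"):
            call_allele(SequenceRecord(id="q", sequence="ACGTA"), cat)

    def test_self_consistency(self):
        cat = AlleleCatalog.from_sequences(
            "L", ["ACGT", "ACGA", "TCGA", "ARGT"])
        for num in cat.genotype_numbers:
            rec = SequenceRecord(id="q", sequence=cat.sequence(num))
            assert call_allele(rec, cat).genotype == num

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.text(alphabet="ACGT", min_size=6, max_size=6),
                    min_size=1, max_size=10))
    def test_registration_order_determinism(self, seqs):
        a = AlleleCatalog.from_sequences("L", seqs)
        b = AlleleCatalog.from_sequences("L", seqs)
        assert a.alleles() == b.alleles()

    def test_fasta_round_trip(self, tmp_path):
        cat = AlleleCatalog.from_sequences("GPH1", ["ACGT", "ACGA", "ARGT"])
        path = tmp_path / "GPH1.fasta"
        cat.to_fasta(path)
        back = AlleleCatalog.from_fasta(path)
        assert back.locus == "GPH1"
        assert back.alleles() == cat.alleles()


class TestFindPolymorphicSites:
    def test_single_allele_catalog(self):
        cat = AlleleCatalog.from_sequences("L", ["ACGT"], seed_reference=False)
        assert find_polymorphic_sites(cat) == []

    def test_sites_and_informativeness(self):
        cat = AlleleCatalog.from_sequences(
            "L", ["ACGT", "ACGA", "TCGA"], seed_reference=False)
        sites = find_polymorphic_sites(cat)
        assert [s.site for s in sites] == [1, 4]
        # site 1: A,A,T (T once) and site 4: T,A,A (T once) -> not informative
        assert [s.informative for s in sites] == [False, False]

    def test_all_informative(self):
        cat = AlleleCatalog.from_sequences(
            "L", ["AA", "AG", "GA", "GG"], seed_reference=False)
        sites = find_polymorphic_sites(cat)
        assert [s.site for s in sites] == [1, 2]
        assert all(s.informative for s in sites)

    def test_weights_shift_informativeness(self):
        cat = AlleleCatalog.from_sequences("L", ["AA", "GA"],
                                           seed_reference=False)
        unweighted = find_polymorphic_sites(cat)
        assert [s.informative for s in unweighted] == [False]
        weighted = find_polymorphic_sites(cat, weights={1: 5, 2: 5})
        assert [s.informative for s in weighted] == [True]


def _locus(start, size=9, name="X"):
    return LocusDefinition(
        name=name, gene_length=300, fwd_primer="A" * 10, rev_primer="C" * 10,
        amplicon_size=size + 20, fragment_start=start,
        fragment_end=start + size - 1, fragment_size=size)


class TestClassifySite:
    def test_synonymous_third_position(self):
        # in-frame fragment: codons GGT / GGA both encode Gly
        cat = AlleleCatalog.from_sequences("X", ["GGTAAA", "GGAAAA"],
                                           seed_reference=False)
        locus = _locus(start=1, size=6)
        res = classify_site(cat, 3, locus)
        assert res.kind == "synonymous"
        assert not res.substantive
        assert res.amino_acids == ("G",)

    def test_nonsynonymous_substantive(self):
        # AAA (Lys, basic) vs GAA (Glu, acidic)
        cat = AlleleCatalog.from_sequences("X", ["AAAGGG", "GAAGGG"],
                                           seed_reference=False)
        res = classify_site(cat, 1, _locus(start=1, size=6))
        assert res.kind == "non-synonymous"
        assert res.substantive
        assert set(res.amino_acids) == {"K", "E"}

    def test_nonsynonymous_conservative(self):
        # CTT (Leu) vs ATT (Ile): both nonpolar-aliphatic
        cat = AlleleCatalog.from_sequences("X", ["CTTGGG", "ATTGGG"],
                                           seed_reference=False)
        res = classify_site(cat, 1, _locus(start=1, size=6))
        assert res.kind == "non-synonymous"
        assert not res.substantive

    def test_ambiguity_expansion_makes_nonsynonymous(self):
        # site 1 R = A/G: AAA (Lys) vs GAA (Glu) within one allele
        cat = AlleleCatalog.from_sequences("X", ["RAAGGG", "AAAGGG"],
                                           seed_reference=False)
        res = classify_site(cat, 1, _locus(start=1, size=6))
        assert res.kind == "non-synonymous"

    def test_coordinate_bookkeeping_matches_frame_offset(self):
        # fragment starting at CDS position 44: site 1 -> gene 44,
        # codon 15, codon position 2; first codon truncated upstream
        cat = AlleleCatalog.from_sequences("X", ["ACGTGA", "TCGTGA"],
                                           seed_reference=False)
        res = classify_site(cat, 1, _locus(start=44, size=6))
        assert res.gene_position == 44
        assert res.codon_index == 15
        assert res.codon_position == 2
        assert res.kind == "indeterminate"

    def test_monomorphic_site_is_an_error(self):
        cat = AlleleCatalog.from_sequences("X", ["GGTAAA", "GGAAAA"],
                                           seed_reference=False)
        with pytest.raises(ValueError, match="monomorphic"):
            classify_site(cat, 2, _locus(start=1, size=6))

    def test_synonymous_plus_nonsynonymous_partition(self):
        # every determinate polymorphic site is exactly one of the two kinds
        cat = AlleleCatalog.from_sequences(
            "X", ["GGTAAAGAA", "GGAAAAAAA", "GGTCAAGAA"], seed_reference=False)
        locus = _locus(start=1, size=9)
        sites = find_polymorphic_sites(cat)
        kinds = [classify_site(cat, s.site, locus).kind for s in sites]
        assert all(k in ("synonymous", "non-synonymous") for k in kinds)
        assert len(kinds) == len(sites)
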