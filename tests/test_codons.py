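"""Codon extraction, start/stop comparison, RSCU and codon-class bias."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.annotation import GeneFeature, GenomeAnnotation, protein_lengths
from mitocomp.codons import (
    CodonError,
    at_rich_ratio,
    classify_at_rich,
    count_codons,
    differing_codon_genes,
    extract_codons,
    internal_stops,
    rscu,
    start_stop_table,
    synonymous_families,
)


def toy_genome(seq, features):
    return GenomeAnnotation("toy", len(seq), features, seq)


class TestGeneticCode:
    def test_invertebrate_mito_families(self):
        fams = synonymous_families(5)
        codons = [c for f in fams.values() for c in f]
        assert len(codons) == len(set(codons)) == 62  # TAA/TAG are stops
        assert "TGA" in fams["W"]          # Trp, not stop
        assert set(fams["S"]) >= {"AGA", "AGG"}  # Ser under this code
        assert "ATA" in fams["M"]

    def test_standard_code_differs(self):
        fams = synonymous_families(1)
        assert "AGA" in fams["R"]


class TestExtractCodons:
    def test_plus_strand_gene(self):
        g = toy_genome("ATGTAA", [GeneFeature("p", "PCG", 1, 6, "+", "ATG", "TAA")])
        assert extract_codons(g) == {"p": ["ATG", "TAA"]}

    def test_minus_strand_gene_is_reverse_complemented(self):
        g = toy_genome("TTACAT", [GeneFeature("p", "PCG", 1, 6, "-", "ATG", "TAA")])
        assert extract_codons(g) == {"p": ["ATG", "TAA"]}

    def test_frame_violations_skipped(self):
        g = toy_genome("ATGTAAC", [GeneFeature("p", "PCG", 1, 7, "+", "ATG", "TAA")])
        assert extract_codons(g) == {}

    def test_internal_stop_reported_not_fatal(self):
        g = toy_genome("ATGTAATGA" + "TAG",
                       [GeneFeature("p", "PCG", 1, 12, "+", "ATG", "TAG")])
        codons = extract_codons(g)
        assert codons["p"] == ["ATG", "TAA", "TGA", "TAG"]
        # TGA is Trp under the invertebrate code; only TAA is an early stop
        assert internal_stops(codons) == {"p": [1]}

    def test_codon_census_conservation(self, synthetic):
        codons = extract_codons(synthetic)
        for f in synthetic.pcgs:
            assert len(codons[f.name]) == f.length // 3
        pooled = count_codons(synthetic)
        assert sum(pooled.values()) == protein_lengths(synthetic)[1]


class TestStartStopTable:
    def test_two_fixture_genomes_differ_in_exactly_two_genes(self, harpago, lambis):
        table, n_diff = start_stop_table([harpago, lambis])
        assert n_diff == 2
        assert differing_codon_genes([harpago, lambis]) == ["cox1", "nad4"]
        assert table.loc["nad4", "Harpago chiragra:start"] == "GTG"
        assert table.loc["nad4", "Lambis lambis:start"] == "ATG"
        assert table.loc["cox1", "Harpago chiragra:stop"] == "TAG"
        assert table.loc["cox1", "Lambis lambis:stop"] == "TAA"

    def test_self_comparison_has_no_differences(self, harpago):
        _, n_diff = start_stop_table([harpago, harpago])
        assert n_diff == 0

    def test_forced_codon_change_detected(self, synthetic):
        from dataclasses import replace
        feats = [replace(f, start_codon="GTG") if f.name == "cox1" else f
                 for f in synthetic.features]
        altered = GenomeAnnotation("alt", synthetic.genome_length, feats,
                                   synthetic.sequence)
        _, n_diff = start_stop_table([synthetic, altered])
        assert n_diff == 1

    def test_differing_gene_sets_rejected(self, harpago):
        g = GenomeAnnotation("toy", 100,
                             [GeneFeature("cox1", "PCG", 1, 9, "+", "ATG", "TAA")])
        with pytest.raises(CodonError, match="PCG sets differ"):
            start_stop_table([harpago, g])


class TestRSCU:
    def test_uniform_counts_give_unit_rscu(self):
        fams = synonymous_families()
        counts = {c: 7 for f in fams.values() for c in f}
        table = rscu(counts)
        assert all(v == pytest.approx(1.0) for v in table.rscu.values())

    def test_two_codon_family_by_hand(self):
        table = rscu({"TTT": 30, "TTC": 10})
        assert table.rscu["TTT"] == pytest.approx(1.5)
        assert table.rscu["TTC"] == pytest.approx(0.5)

    def test_unused_family_is_undefined_not_zero(self):
        table = rscu({"TTT": 5})
        assert table.rscu["GGA"] is None

    def test_stop_codons_rejected(self):
        with pytest.raises(CodonError):
            rscu({"TAA": 3})

    @settings(deadline=None, max_examples=50)
    @given(st.dictionaries(
        st.sampled_from([c for f in synonymous_families().values() for c in f]),
        st.integers(min_value=0, max_value=500), max_size=40))
    def test_family_sums_and_scale_invariance(self, counts):
        fams = synonymous_families()
        table = rscu(counts)
        for codons in fams.values():
            total = sum(counts.get(c, 0) for c in codons)
            vals = [table.rscu[c] for c in codons]
            if total == 0:
                assert all(v is None for v in vals)
            else:
                assert sum(vals) == pytest.approx(len(codons))
        doubled = rscu({c: 2 * n for c, n in counts.items()})
        for c, v in table.rscu.items():
            w = doubled.rscu[c]
            assert (v is None and w is None) or v == pytest.approx(w)


class TestAtRichRatio:
    def test_classification_majority_rule(self):
        assert classify_at_rich("AAA") == "AT"
        assert classify_at_rich("ATG") == "AT"   # 2 of 3
        assert classify_at_rich("GCA") == "GC"
        assert classify_at_rich("UUU") == "AT"   # RNA spelling accepted

    def test_no_gc_rich_codons_is_undefined(self):
        assert at_rich_ratio({"AAA": 5, "TTT": 3}) is None

    def test_hand_ratio(self):
        assert at_rich_ratio({"AAA": 27, "GGG": 10}) == pytest.approx(2.7)

    def test_balanced_ratio(self):
        assert at_rich_ratio({"ATT": 8, "GCC": 8}) == pytest.approx(1.0)

    def test_empty_counts_rejected(self):
        with pytest.raises(CodonError):
            at_rich_ratio({})

    def test_synthetic_genome_prefers_at_rich_codons(self, synthetic):
        # A+T-biased composition must show up as an excess of A+T-rich codons
        ratio = at_rich_ratio(count_codons(synthetic))
        assert ratio > 1.5
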