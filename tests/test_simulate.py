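"""Synthetic mitogenome generator and K2P pair evolution."""

import math

import numpy as np
import pytest

from mitocomp.annotation import scan_spacers, validate_annotation
from mitocomp.composition import composition_stats
from mitocomp.codons import extract_codons, internal_stops
from mitocomp.distance import k2p_distance, site_tallies
from mitocomp.gene_order import GeneOrder, orders_equivalent
from mitocomp.simulate import (
    ConfigError,
    EvolutionConfig,
    GeneratorConfig,
    consensus_gene_order,
    evolve_pair,
    evolve_sequence,
    expected_pair_tallies,
    generate_genome,
    k2p_site_probs,
)


class TestGeneratorConfig:
    def test_defaults_are_valid(self):
        cfg = GeneratorConfig()
        assert cfg.gene_census == {"PCG": 13, "tRNA": 22, "rRNA": 2}
        assert len(cfg.gene_order_template) == 37

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(at_content_target=120)
        with pytest.raises(ConfigError):
            GeneratorConfig(at_skew_target=1.5)

    def test_census_mismatch_rejected(self):
        with pytest.raises(ConfigError, match="census"):
            GeneratorConfig(gene_order_template=GeneOrder.from_string("cox1,trnA"))

    def test_overlap_into_protein_gene_rejected(self):
        # trnD is immediately upstream of atp8 (a PCG) in the consensus order
        with pytest.raises(ConfigError, match="protein"):
            generate_genome(GeneratorConfig(overlaps={"trnD": 2}))

    def test_base_probs_hit_targets(self):
        p = GeneratorConfig(at_content_target=66.0, at_skew_target=-0.13,
                            gc_skew_target=0.02).base_probs()
        a, c, g, t = p
        assert a + c + g + t == pytest.approx(1.0)
        assert 100 * (a + t) == pytest.approx(66.0)
        assert (a - t) / (a + t) == pytest.approx(-0.13)
        assert (g - c) / (g + c) == pytest.approx(0.02)


class TestGenerateGenome:
    def test_census_and_order(self, synthetic):
        assert synthetic.census() == {"PCG": 13, "tRNA": 22, "rRNA": 2}
        assert orders_equivalent(GeneOrder.from_annotation(synthetic),
                                 consensus_gene_order())

    def test_deterministic_for_fixed_seed(self, synthetic):
        again = generate_genome(GeneratorConfig(seed=11),
                                organism_label="synthetic_11")
        assert again.sequence == synthetic.sequence
        assert again.features == synthetic.features

    def test_seeds_differ(self, synthetic):
        other = generate_genome(GeneratorConfig(seed=12))
        assert other.sequence != synthetic.sequence

    def test_validates_cleanly(self, synthetic):
        assert [f for f in validate_annotation(synthetic)
                if f.severity == "error"] == []

    def test_genome_length_near_target(self, synthetic):
        assert abs(synthetic.genome_length - 15500) < 600

    def test_spacer_structure(self, synthetic):
        rep = scan_spacers(synthetic)
        assert rep.overlap_count == 4
        assert rep.size_range[0] >= 1
        # the control-region gap upstream of cox3 dominates
        assert rep.largest_gap[0] == ("trnF", "cox3")
        assert 45 <= rep.largest_gap[1] <= 55

    def test_tiling_identity(self, synthetic):
        rep = scan_spacers(synthetic)
        assert sum(f.length for f in synthetic.features) + \
            sum(s for _, _, s in rep.pairs) == synthetic.genome_length

    def test_composition_near_target(self, synthetic):
        st = composition_stats(synthetic.sequence)
        assert st.at_content == pytest.approx(66.2, abs=1.5)
        assert st.at_skew < 0

    def test_coding_sequences_clean(self, synthetic):
        codons = extract_codons(synthetic)
        assert len(codons) == 13
        assert internal_stops(codons) == {}
        for f in synthetic.pcgs:
            assert codons[f.name][0] == f.start_codon
            assert codons[f.name][-1] == f.stop_codon


class TestK2PProcess:
    def test_site_probs_sum_to_one(self):
        p_id, p_ts, p_tv = k2p_site_probs(0.3, 2.0)
        assert p_id + p_ts + 2 * p_tv == pytest.approx(1.0)

    def test_expected_tallies_invert_to_true_distance(self):
        # plugging the expected P, Q into the K2P formula must return d
        for d in (0.05, 0.2, 0.5):
            p, q = expected_pair_tallies(EvolutionConfig(true_distance=d))
            est = -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)
            assert est == pytest.approx(d)

    def test_zero_distance_changes_nothing(self):
        rng = np.random.default_rng(1)
        seq = "ACGT" * 100
        assert evolve_sequence(seq, 0.0, 2.0, rng) == seq

    def test_mask_freezes_sites(self):
        rng = np.random.default_rng(1)
        seq = "A" * 50
        mask = np.zeros(50, dtype=bool)
        mask[:25] = True
        out = evolve_sequence(seq, 5.0, 2.0, rng, mask)
        assert out[:25] == "A" * 25
        assert out[25:] != "A" * 25

    def test_transition_fraction_matches_kappa(self):
        # observed transition/transversion counts within binomial error
        rng = np.random.default_rng(2)
        n = 40000
        base = "".join(rng.choice(list("ACGT"), size=n))
        a = evolve_sequence(base, 0.1, 3.0, rng)
        b = evolve_sequence(base, 0.1, 3.0, rng)
        tal = site_tallies(a, b)
        exp_p, exp_q = expected_pair_tallies(
            EvolutionConfig(true_distance=0.2, kappa=3.0))
        for obs, exp in ((tal.transitions, exp_p), (tal.transversions, exp_q)):
            se = math.sqrt(n * exp * (1 - exp))
            assert abs(obs - n * exp) < 4 * se


class TestEvolvePair:
    def test_zero_distance_identical_descendants(self, synthetic):
        a, b, truth = evolve_pair(synthetic, EvolutionConfig(true_distance=0.0))
        assert a.sequence == b.sequence == synthetic.sequence
        assert truth["expected_P"] == pytest.approx(0.0)

    def test_recovery_within_three_se(self, synthetic):
        a, b, truth = evolve_pair(synthetic, EvolutionConfig(
            true_distance=0.2, kappa=2.0, seed=4))
        pair = k2p_distance(a.sequence, b.sequence)
        assert abs(pair.k2p - 0.2) < 3 * pair.standard_error()

    def test_descendant_order_does_not_matter(self, synthetic):
        a, b, _ = evolve_pair(synthetic, EvolutionConfig(
            true_distance=0.2, seed=4))
        ab = k2p_distance(a.sequence, b.sequence)
        ba = k2p_distance(b.sequence, a.sequence)
        assert ab == ba

    def test_terminal_codons_preserved(self, synthetic):
        a, _, truth = evolve_pair(synthetic, EvolutionConfig(
            true_distance=1.0, seed=5))
        assert truth["masked_sites"] == 6 * 13
        for f in synthetic.pcgs:
            assert a.sequence[f.start - 1:f.start + 2] == \
                synthetic.sequence[f.start - 1:f.start + 2]
            assert a.sequence[f.end - 3:f.end] == \
                synthetic.sequence[f.end - 3:f.end]

    def test_saturation_flagged(self, synthetic):
        *_, truth = evolve_pair(synthetic, EvolutionConfig(
            true_distance=20.0, seed=6))
        assert truth["saturated"]

    def test_sequence_required(self, harpago):
        with pytest.raises(ConfigError, match="sequence"):
            evolve_pair(harpago)

    def test_invalid_configs(self):
        with pytest.raises(ConfigError):
            EvolutionConfig(true_distance=-1)
        with pytest.raises(ConfigError):
            EvolutionConfig(kappa=0)
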