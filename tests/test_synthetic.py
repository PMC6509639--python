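"""Generator correctness: construction identities, determinism, closure."""

import numpy as np
import pytest

from spacertrace.search import SpacerCatalog, find_protospacer_hits
from spacertrace.seq import revcomp, translate
from spacertrace.synthetic import (
    FragmentationSpec,
    HaplotypeSpec,
    LocusSpec,
    Mutation,
    PhageSpec,
    SimGenome,
    apply_mutations,
    diversify_population,
    make_fragmentable_gene,
    make_phage_genome,
    make_repeat_spacer_locus,
    mutation_consequence,
    plant_gene_fragmentation,
    simulate_read_pairs,
)
from spacertrace.types import Region


class TestLocusConstruction:
    def test_sequence_is_alternating_repeats_and_spacers(self):
        spec = LocusSpec("G" * 20 + "ACGTT", 2, (18, 20))
        seq, truth = make_repeat_spacer_locus(spec, rng_seed=0)
        s1, s2 = (sp.sequence for sp in truth.spacers)
        assert seq == spec.repeat_seq + s1 + spec.repeat_seq + s2 + spec.repeat_seq
        assert len(seq) == 3 * 25 + len(s1) + len(s2)

    def test_same_seed_reproduces_identical_output(self):
        spec = LocusSpec("ATTGCAATGGCGCATTAAGCC", 5, (18, 22))
        a, _ = make_repeat_spacer_locus(spec, rng_seed=7)
        b, _ = make_repeat_spacer_locus(spec, rng_seed=7)
        assert a == b

    def test_22_spacer_locus_has_23_repeats(self):
        spec = LocusSpec("ATTGCAATGGCGCATTAAGCC", 22, (30, 40))
        seq, truth = make_repeat_spacer_locus(spec, rng_seed=1)
        assert len(truth.repeat_instances) == 23
        assert len(truth.spacers) == 22
        assert len({sp.sequence for sp in truth.spacers}) == 22
        for reg in truth.repeat_instances:
            assert seq[reg.start : reg.end] == spec.repeat_seq

    def test_too_few_spacers_rejected(self):
        with pytest.raises(ValueError):
            LocusSpec("ATTGCAATGGCGCATTAAGCC", 1, (18, 20))


class TestDiversification:
    @pytest.fixture()
    def base(self):
        spec = LocusSpec("ATTGCAATGGCGCATTAAGCC", 6, (18, 20), leader_side="left")
        return make_repeat_spacer_locus(spec, rng_seed=3)

    def test_no_edits_is_identity(self, base):
        seq, truth = base
        out = diversify_population(seq, truth, [HaplotypeSpec(frequency=1.0)])
        assert out[0][0] == seq

    def test_added_spacer_sits_at_leader_end_with_own_repeat(self, base):
        seq, truth = base
        new = "ACGTACGTACGTACGTAC"
        out = diversify_population(
            seq, truth,
            [HaplotypeSpec(frequency=0.7),
             HaplotypeSpec(added_leader_spacers=(new,), frequency=0.3)],
        )
        hap_seq, order, _ = out[1]
        repeat = truth.repeat_consensus
        assert hap_seq.startswith(repeat + new + repeat)
        assert order[0] == new

    def test_six_haplotype_specific_additions_tracked(self, base):
        seq, truth = base
        rng = np.random.default_rng(10)
        from spacertrace.seq import random_dna

        adds = list({random_dna(18, rng) for _ in range(10)})[:6]
        assert len(adds) == 6
        haps = [HaplotypeSpec(added_leader_spacers=(a,), frequency=1 / 6) for a in adds]
        out = diversify_population(seq, truth, haps)
        heads = [order[0] for _, order, _ in out]
        assert sorted(heads) == sorted(adds)

    def test_lost_unit_removes_spacer_and_repeat(self, base):
        seq, truth = base
        out = diversify_population(
            seq, truth, [HaplotypeSpec(lost_unit_indices=(2,), frequency=1.0)]
        )
        hap_seq, order, _ = out[0]
        repeat_len = len(truth.repeat_consensus)
        lost = truth.spacers[2].sequence
        assert lost not in hap_seq
        assert len(hap_seq) == len(seq) - len(lost) - repeat_len

    def test_bad_frequencies_rejected(self, base):
        seq, truth = base
        with pytest.raises(ValueError, match="sum"):
            diversify_population(seq, truth, [HaplotypeSpec(frequency=0.5)])


class TestPhageGenome:
    def test_pam_planted_immediately_upstream(self):
        catalog = {"s1": "ACGTACGTACGTACGTACGTACGTACGTAC"}
        spec = PhageSpec(
            length=5000, planted_protospacers=(("s1", 1000, "+", "TA"),), name="p"
        )
        genome, truth = make_phage_genome(spec, catalog, rng_seed=0)
        assert genome[998:1000] == "TA"
        assert genome[1000:1030] == catalog["s1"]

    def test_minus_strand_placement_found_by_search(self):
        catalog = {"s1": "ACGTTCGGATCGATCCGTAACGTGCATGCA"}
        spec = PhageSpec(
            length=5000, planted_protospacers=(("s1", 2000, "-", "TG"),), name="p"
        )
        genome, truth = make_phage_genome(spec, catalog, rng_seed=1)
        cat = SpacerCatalog(sequences=catalog, multiplicity={"s1": 1})
        hits = find_protospacer_hits(cat, {"p": genome})
        planted = [h for h in hits if h.start == 2000]
        assert planted and planted[0].strand == "-"
        # PAM on the minus strand: revcomp of the two bases 3' of the interval
        assert revcomp(genome[2030:2032]) == "TG"

    def test_planted_pam_mix_totals(self):
        rng = np.random.default_rng(5)
        from spacertrace.seq import random_dna

        catalog = {f"s{i}": random_dna(30, rng) for i in range(34)}
        placements = tuple(
            (f"s{i}", 200 + 140 * i, "+", "TA" if i < 20 else "TG") for i in range(34)
        )
        spec = PhageSpec(length=5200, planted_protospacers=placements, name="p")
        _, truth = make_phage_genome(spec, catalog, rng_seed=2)
        pams = [h["pam"] for h in truth["protospacers"]]
        assert pams.count("TA") == 20 and pams.count("TG") == 14

    def test_overlapping_placements_rejected(self):
        catalog = {"s1": "ACGTACGTACGTACGTACGTACGTACGTAC", "s2": "TTGCATGCATGCATGCATGCATGCATGCAT"}
        spec = PhageSpec(
            length=5000,
            planted_protospacers=(("s1", 1000, "+", "TA"), ("s2", 1010, "+", "TG")),
            name="p",
        )
        with pytest.raises(ValueError, match="overlap"):
            make_phage_genome(spec, catalog, rng_seed=0)


class TestGeneFragmentation:
    def test_homopolymer_deletion_stop_five_codons_downstream(self):
        rng = np.random.default_rng(0)
        gene, del_off, _ = make_fragmentable_gene(rng, 80, del_codon=20, sub_codon=60)
        region = Region(0, len(gene))
        m = Mutation(del_off, "A", "", 1.0)
        cons, offset = mutation_consequence(gene, region, m)
        assert cons == "frameshift_stop"
        assert offset == 5

    def test_nonsense_substitution_emits_two_haplotypes(self):
        rng = np.random.default_rng(1)
        gene, _, sub_off = make_fragmentable_gene(rng, 80, del_codon=20, sub_codon=60)
        spec = FragmentationSpec(
            gene_region=Region(0, len(gene)),
            mutations=(Mutation(sub_off, "C", "T", 0.82),),
        )
        haps = plant_gene_fragmentation(gene, spec)
        fracs = sorted(round(f, 6) for _, f, _ in haps)
        assert fracs == [0.18, 0.82]
        mutated = apply_mutations(gene, [Mutation(sub_off, "C", "T", 0.82)])
        assert "*" in translate(mutated)

    def test_empty_mutation_list_is_identity(self):
        rng = np.random.default_rng(2)
        gene, _, _ = make_fragmentable_gene(rng, 60, del_codon=10, sub_codon=40)
        spec = FragmentationSpec(gene_region=Region(0, len(gene)), mutations=())
        haps = plant_gene_fragmentation(gene, spec)
        assert len(haps) == 1 and haps[0][0] == gene and haps[0][1] == 1.0

    def test_silent_mutation_rejected(self):
        rng = np.random.default_rng(3)
        gene, _, _ = make_fragmentable_gene(rng, 60, del_codon=10, sub_codon=40)
        # find a substitution that leaves translation stop-free
        for pos in range(0, len(gene), 3):
            for alt in "ACGT":
                if alt == gene[pos]:
                    continue
                mutated = apply_mutations(gene, [Mutation(pos, gene[pos], alt, 1.0)])
                if "*" not in translate(mutated):
                    spec = FragmentationSpec(
                        gene_region=Region(0, len(gene)),
                        mutations=(Mutation(pos, gene[pos], alt, 1.0),),
                    )
                    with pytest.raises(ValueError, match="disrupt"):
                        plant_gene_fragmentation(gene, spec)
                    return
        pytest.fail("no non-disruptive substitution found")


class TestReadSimulation:
    def test_error_free_reads_are_exact_substrings(self):
        rng = np.random.default_rng(4)
        from spacertrace.seq import random_dna

        g1 = random_dna(2000, rng)
        g2 = random_dna(1500, rng)
        pairs = simulate_read_pairs(
            [SimGenome("a", g1, 1.0), SimGenome("b", g2, 1.0, circular=True)],
            n_pairs=300, rng_seed=9,
        )
        doubled = {"a": g1, "b": g2 + g2}
        for p in pairs:
            src = doubled[p.source]
            assert p.r1 in src
            assert revcomp(p.r2) in src

    def test_abundance_ratio_within_three_binomial_sd(self):
        rng = np.random.default_rng(5)
        from spacertrace.seq import random_dna

        g = random_dna(3000, rng)
        h = random_dna(3000, rng)
        n = 10_000
        pairs = simulate_read_pairs(
            [SimGenome("hi", g, 10.0), SimGenome("lo", h, 1.0)], n_pairs=n, rng_seed=3
        )
        n_hi = sum(1 for p in pairs if p.source == "hi")
        p_exp = 10 / 11
        sd = (n * p_exp * (1 - p_exp)) ** 0.5
        assert abs(n_hi - n * p_exp) <= 3 * sd

    def test_linear_genome_reads_never_span_terminus(self):
        rng = np.random.default_rng(6)
        from spacertrace.seq import random_dna

        g = random_dna(2000, rng)
        pairs = simulate_read_pairs([SimGenome("a", g, 1.0)], n_pairs=500, rng_seed=1)
        for p in pairs:
            assert p.r1 in g and revcomp(p.r2) in g

    def test_short_linear_genome_skipped_with_warning(self):
        from spacertrace.seq import random_dna

        rng = np.random.default_rng(7)
        g = random_dna(100, rng)
        with pytest.warns(UserWarning, match="skipped"):
            pairs = simulate_read_pairs([SimGenome("tiny", g, 1.0)], n_pairs=10)
        assert pairs == []

    def test_byte_identical_regeneration(self, tmp_path):
        from spacertrace.io import write_scenario
        from spacertrace.scenarios import scenario_basic

        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_scenario(scenario_basic(11), d1)
        write_scenario(scenario_basic(11), d2)
        for name in ("scaffolds.fasta", "reads_R1.fastq", "reads_R2.fastq", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
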