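"""Evidence layers: mapping/pair filter, coverage, prophage, circularity,
fragmented genes and disruptive variants."""

import numpy as np
import pytest

from spacertrace import evidence as ev
from spacertrace.seq import random_dna, revcomp, translate
from spacertrace.synthetic import (
    FragmentationSpec,
    Mutation,
    ReadPair,
    SimGenome,
    make_fragmentable_gene,
    plant_gene_fragmentation,
    simulate_read_pairs,
)
from spacertrace.types import CoverageProfile, Region


RNG = np.random.default_rng(77)
GENOME = random_dna(6000, RNG)


def _pairs(genome, n, seed=0, **kw):
    return simulate_read_pairs([SimGenome("g", genome, 1.0)], n_pairs=n,
                               rng_seed=seed, **kw)


class TestMapping:
    def test_error_free_pairs_fully_retained(self):
        pairs = _pairs(GENOME, 400)
        mp = ev.map_reads(pairs, {"g": GENOME})
        assert len(mp.pairs) == 400
        assert mp.n_discarded_filter == 0 and mp.n_unmapped == 0

    def test_pair_with_two_combined_mismatches_discarded(self):
        frag = GENOME[1000:1300]
        r1 = list(frag[:150])
        r2 = list(revcomp(frag[-150:]))
        r1[70] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r1[70]]
        r2[80] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r2[80]]
        mp = ev.map_reads([ReadPair("p", "".join(r1), "".join(r2))], {"g": GENOME})
        assert mp.pairs == [] and mp.n_discarded_filter == 1

    def test_single_mismatch_pair_retained(self):
        frag = GENOME[1000:1300]
        r1 = list(frag[:150])
        r1[70] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r1[70]]
        mp = ev.map_reads([ReadPair("p", "".join(r1), revcomp(frag[-150:]))], {"g": GENOME})
        assert len(mp.pairs) == 1

    def test_coverage_conservation_and_depth_expectation(self):
        n_pairs = 1000
        pairs = _pairs(GENOME, n_pairs, seed=3)
        mp = ev.map_reads(pairs, {"g": GENOME})
        depth = mp.coverage["g"].depth
        assert depth.sum() == sum(
            a.read_len for pr in mp.pairs for a in pr
        )
        expected = n_pairs * 2 * 150 / len(GENOME)
        assert abs(mp.coverage["g"].mean_depth - expected) / expected < 0.1


class TestProphage:
    def _profile(self, region_depth, flank_depth, n=10_000, region=(4000, 6000)):
        depth = np.full(n, flank_depth, dtype=np.int32)
        depth[region[0]:region[1]] = region_depth
        return CoverageProfile("sc", depth)

    def test_equal_depth_is_integrated_only(self):
        call = ev.prophage_activity_call(self._profile(30, 30), Region(4000, 6000))
        assert call.ratio == pytest.approx(1.0)
        assert call.state == "integrated_only"

    def test_tenfold_excess_is_active(self):
        call = ev.prophage_activity_call(self._profile(300, 30), Region(4000, 6000))
        assert call.ratio == pytest.approx(10.0)
        assert call.state == "active_particles"

    def test_zero_flank_defers_to_circular_support(self):
        call = ev.prophage_activity_call(
            self._profile(50, 0), Region(4000, 6000), circular_support=5
        )
        assert call.ratio is None
        assert call.state == "active_particles"

    def test_planted_copy_excess_recovered(self):
        from spacertrace.scenarios import scenario_prophage

        sc = scenario_prophage(11)
        mp = ev.map_reads(sc.reads, sc.scaffolds)
        _, s, e = sc.truth.prophage_region
        call = ev.prophage_activity_call(mp.coverage["host"], Region(s, e))
        assert call.ratio == pytest.approx(8.0, rel=0.2)
        assert call.state == "active_particles"


class TestCircularity:
    def test_linear_genome_has_no_support(self):
        pairs = _pairs(GENOME, 500, seed=5)
        mp = ev.map_reads(pairs, {"g": GENOME})
        assert ev.detect_circularity(mp.pairs, "g", len(GENOME)) == 0

    def test_circular_genome_yields_outward_pairs(self):
        reads = simulate_read_pairs(
            [SimGenome("g", GENOME, 1.0, circular=True)], n_pairs=1000, rng_seed=6
        )
        mp = ev.map_reads(reads, {"g": GENOME})
        support = ev.detect_circularity(
            mp.pairs, "g", len(GENOME),
            unmapped_reads=mp.unmapped_reads, scaffold_seq=GENOME,
        )
        # expected junction fragments ~ n_pairs * insert / genome_len
        expected = 1000 * 300 / len(GENOME)
        assert support > 0
        assert abs(support - expected) <= 3 * np.sqrt(expected) + 10

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ev.detect_circularity([], "g", 800, end_window=500)


class TestFragmentedGene:
    def _orfs_from_reference(self, rng, n_codons=150):
        gene, _, _ = make_fragmentable_gene(rng, n_codons, del_codon=30, sub_codon=100)
        ref = translate(gene)
        cuts = [0, n_codons // 3, 2 * n_codons // 3, n_codons]
        orfs = [
            (Region(cuts[i] * 3, cuts[i + 1] * 3), "+") for i in range(3)
        ]
        return gene, ref, orfs

    def test_three_planted_fragments_tile_reference(self):
        rng = np.random.default_rng(8)
        gene, ref, orfs = self._orfs_from_reference(rng)
        call = ev.detect_fragmented_gene(orfs, ref, gene)
        assert call is not None
        assert call.tiling_coverage_of_reference > 0.95
        assert len(call.fragment_orfs) == 3

    def test_unrelated_orfs_make_no_call(self):
        rng = np.random.default_rng(9)
        gene, ref, orfs = self._orfs_from_reference(rng)
        decoy, _, _ = make_fragmentable_gene(rng, 150, del_codon=30, sub_codon=100)
        assert ev.detect_fragmented_gene(orfs, ref, decoy) is None

    def test_half_coverage_below_threshold_makes_no_call(self):
        rng = np.random.default_rng(10)
        gene, ref, _ = self._orfs_from_reference(rng, n_codons=200)
        orfs = [(Region(0, 150), "+"), (Region(150, 300), "+")]  # 100 of 200 aa
        assert ev.detect_fragmented_gene(orfs, ref, gene) is None

    def test_single_orf_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            ev.detect_fragmented_gene([(Region(0, 90), "+")], "M" * 30, "ACG" * 100)


class TestVariants:
    def _scenario(self, sub_fraction, seed=0, n_pairs=1500):
        rng = np.random.default_rng(seed)
        flank_l, flank_r = random_dna(1200, rng), random_dna(1200, rng)
        gene, del_off, sub_off = make_fragmentable_gene(
            rng, 120, del_codon=20, sub_codon=90
        )
        host = flank_l + gene + flank_r
        region = Region(1200, 1200 + len(gene))
        muts = (Mutation(1200 + del_off, "A", "", 1.0),
                Mutation(1200 + sub_off, "C", "T", sub_fraction))
        spec = FragmentationSpec(gene_region=region, mutations=muts)
        haps = plant_gene_fragmentation(host, spec)
        genomes = [SimGenome(f"h{i}", s, f) for i, (s, f, _) in enumerate(haps)]
        reads = simulate_read_pairs(genomes, n_pairs=n_pairs, rng_seed=seed + 1)
        return host, region, muts, reads

    def test_planted_fractions_and_consequences_recovered(self):
        host, region, muts, reads = self._scenario(0.82)
        mp = ev.map_reads(reads, {"host": host})
        calls = ev.call_disrupting_variants(mp.pairs, host, "host", region)
        by_alt = {c.alt: c for c in calls}
        assert set(by_alt) == {"", "T"}
        dele, sub = by_alt[""], by_alt["T"]
        assert dele.alt_fraction == pytest.approx(1.0)
        assert dele.consequence == "frameshift_stop"
        assert dele.stop_offset_codons == 5
        sd = np.sqrt(0.82 * 0.18 / sub.depth)
        assert abs(sub.alt_fraction - 0.82) <= 3 * sd
        assert sub.consequence == "nonsense"

    def test_no_variants_on_error_free_reference_reads(self):
        rng = np.random.default_rng(12)
        host = random_dna(3000, rng)
        reads = _pairs(host, 800, seed=13)
        mp = ev.map_reads(reads, {"g": host})
        calls = ev.call_disrupting_variants(mp.pairs, host, "g", Region(1000, 1600))
        assert calls == []

    def test_low_depth_sites_not_called(self):
        host, region, muts, reads = self._scenario(0.82, seed=20, n_pairs=1500)
        mp = ev.map_reads(reads, {"host": host})
        calls = ev.call_disrupting_variants(
            mp.pairs, host, "host", region, min_depth=10_000
        )
        assert calls == []

    def test_consequence_agrees_with_direct_haplotype_translation(self):
        """Caller labels match translating the mutated haplotype directly."""
        host, region, muts, reads = self._scenario(0.5, seed=30)
        mp = ev.map_reads(reads, {"host": host})
        calls = ev.call_disrupting_variants(mp.pairs, host, "host", region)
        gene = host[region.start : region.end]
        from spacertrace.synthetic import apply_mutations

        for c in calls:
            rel = Mutation(c.position - region.start, c.ref, c.alt or "", 1.0)
            mutated = apply_mutations(gene, [rel])
            assert "*" in translate(mutated)
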