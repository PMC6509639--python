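"""Ready-made synthetic study scenarios.

Each scenario wires the generator primitives into a complete desk-scale
dataset (scaffolds, annotations, bin table, paired reads, truth):

``fcasy``
    A host population with a diversifying CRISPR locus (16 shared spacers
    plus 6 haplotype-specific leader additions = 22 unique spacers), 12
    self-targeting protospacers on a second host scaffold with a 7xTA /
    4xTG / 1xAT PAM mix, a free phage carrying TA/TG protospacers, and an
    effector gene fragmented by a homopolymer deletion (population fraction
    1.00) and a nonsense substitution (fraction 0.82).
``pam``
    Two phage genomes carrying 39 unique protospacer locations with a
    20xTA / 14xTG / 5x-other PAM mix.
``prophage``
    A host scaffold with an integrated prophage plus excess free circular
    phage copies (default 8x coverage ratio).
``basic``
    A minimal host locus + phage pair for smoke tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .seq import random_dna, revcomp
from .synthetic import (
    FragmentationSpec,
    HaplotypeSpec,
    LocusSpec,
    Mutation,
    PhageSpec,
    ReadPair,
    SimGenome,
    TruthBundle,
    apply_mutations,
    diversify_population,
    make_fragmentable_gene,
    make_phage_genome,
    make_repeat_spacer_locus,
    mutation_consequence,
    pairs_for_depth,
    plant_gene_fragmentation,
    simulate_read_pairs,
)
from .types import CrisprArray, Region
from .seq import translate


@dataclass
class Scenario:
    name: str
    scaffolds: dict[str, str]
    reads: list[ReadPair]
    truth: TruthBundle
    annotations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["scaffold", "start", "end", "strand", "product"]
        )
    )
    bins: dict[str, str] = field(default_factory=dict)
    cas_gene_hint: Optional[int] = None
    base_array: Optional[CrisprArray] = None


def _plant(genome: list[str], pos: int, spacer: str, strand: str, pam: str) -> dict:
    """Overwrite genome[pos:pos+len] with a protospacer + 5' PAM."""
    m = len(spacer)
    if strand == "+":
        if pos - 2 < 0 or pos + m > len(genome):
            raise ValueError("protospacer out of bounds")
        genome[pos - 2 : pos + m] = pam + spacer
    else:
        if pos < 0 or pos + m + 2 > len(genome):
            raise ValueError("protospacer out of bounds")
        genome[pos : pos + m + 2] = revcomp(spacer) + revcomp(pam)
    return {"start": pos, "end": pos + m, "strand": strand, "pam": pam}


# ---------------------------------------------------------------------------


def scenario_fcasy(seed: int, depth: float = 50.0, read_len: int = 150) -> Scenario:
    """The fragmented-effector / self-targeting study scenario."""
    rng = np.random.default_rng(seed)

    repeat = random_dna(21, rng)
    locus_spec = LocusSpec(repeat, 16, spacer_len_range=(18, 20), leader_side="left")
    locus_seq, base_array = make_repeat_spacer_locus(
        locus_spec, rng_seed=int(rng.integers(2**31)), scaffold_id="host1"
    )
    base_spacers = [sp.sequence for sp in base_array.spacers]

    taken = set(base_spacers) | {repeat}
    recent: list[str] = []
    while len(recent) < 6:
        s = random_dna(18, rng)
        if s not in taken:
            taken.add(s)
            recent.append(s)
    haplotypes = [HaplotypeSpec(added_leader_spacers=(s,), frequency=1 / 6) for s in recent]
    locus_variants = diversify_population(locus_seq, base_array, haplotypes)

    # host scaffold 1: flank | cas1 | gap | locus | gap | effector gene | flank
    flank_l = random_dna(2000, rng)
    cas1 = random_dna(900, rng)
    gap1 = random_dna(200, rng)
    gap2 = random_dna(300, rng)
    gene, del_off, sub_off = make_fragmentable_gene(
        rng, n_codons=200, del_codon=40, sub_codon=120
    )
    flank_r = random_dna(2000, rng)

    prefix = flank_l + cas1 + gap1
    locus_start = len(prefix)
    locus_end = locus_start + len(locus_seq)
    gene_start = locus_end + len(gap2)
    gene_region = Region(gene_start, gene_start + len(gene))
    host1 = prefix + locus_seq + gap2 + gene + flank_r
    cas_hint = len(flank_l) + 450  # cas1 gene centre, leader side of the locus

    frag_spec = FragmentationSpec(
        gene_region=gene_region,
        mutations=(
            Mutation(gene_start + del_off, "A", "", 1.0),
            Mutation(gene_start + sub_off, "C", "T", 0.82),
        ),
    )
    gene_haps = plant_gene_fragmentation(host1, frag_spec)

    # host scaffold 2: 12 self-targeting protospacers, 7xTA/4xTG/1xAT
    host2_list = list(random_dna(12500, rng))
    self_ids = [f"b{i:02d}" for i in (1, 3, 5, 7, 9, 11, 12, 13, 14, 15)] + ["r01", "r02"]
    catalog = {f"b{i + 1:02d}": s for i, s in enumerate(base_spacers)}
    catalog.update({f"r{i + 1:02d}": s for i, s in enumerate(recent)})
    pams = ["TA"] * 7 + ["TG"] * 4 + ["AT"]
    host2_genes = [
        "PINc domain ribonuclease", "permease", "permease (second copy)",
        "sigma-70 family RNA polymerase", "hypothetical protein with transmembrane domain",
        "hypothetical protein with transmembrane domain 2",
        "hypothetical protein with transmembrane domain 3",
        "ATP synthase subunit", "ribosomal protein L2", "glycosyltransferase",
        "peptidase",
    ]
    self_truth = []
    ann_rows = []
    for i, (sid, pam) in enumerate(zip(self_ids, pams)):
        pos = 500 + 950 * i
        strand = "+" if i % 2 == 0 else "-"
        rec = _plant(host2_list, pos, catalog[sid], strand, pam)
        rec.update({"spacer_id": sid, "scaffold": "host2"})
        self_truth.append(rec)
        if i < 11:  # the last protospacer (an AT-PAM recent spacer) is intergenic
            ann_rows.append(
                {"scaffold": "host2", "start": pos - 100, "end": pos + 120,
                 "strand": "+", "product": host2_genes[i]}
            )
    host2 = "".join(host2_list)

    # free phage targeted by base-locus spacers (TA/TG PAMs)
    phage_spec = PhageSpec(
        length=12000,
        planted_protospacers=(
            ("b02", 2000, "+", "TA"),
            ("b04", 5000, "-", "TA"),
            ("b06", 8000, "+", "TG"),
        ),
        circular=False,
        keyword_genes=(
            "major capsid protein", "terminase large subunit", "portal protein",
            "Cas4-like protein", "tail fiber protein", "hypothetical protein",
        ),
        name="phage1",
    )
    phage_seq, phage_truth = make_phage_genome(
        phage_spec, catalog, rng_seed=int(rng.integers(2**31))
    )
    ann_rows.extend(phage_truth["annotations"])
    ann_rows.append(
        {"scaffold": "host1", "start": len(flank_l), "end": len(flank_l) + 900,
         "strand": "+", "product": "CRISPR-associated protein Cas1"}
    )

    # population haplotype pool: locus variants x gene variants
    genomes = []
    hap_freqs = {}
    order_truth = {}
    for li, (lseq, order, lhap) in enumerate(locus_variants):
        for gi, (gseq, gfrac, _) in enumerate(gene_haps):
            name = f"host1_h{li}{gi}"
            seq = gseq[:locus_start] + lseq + gseq[locus_end:]
            freq = lhap.frequency * gfrac
            genomes.append(SimGenome(name, seq, abundance=freq))
            hap_freqs[name] = freq
            order_truth[name] = [
                next(k for k, v in catalog.items() if v == s) for s in order
            ]
    genomes.append(SimGenome("host2", host2, abundance=1.0))
    genomes.append(SimGenome("phage1", phage_seq, abundance=2.0))

    n_pairs = pairs_for_depth(genomes, depth, read_len, reference="host1")
    reads = simulate_read_pairs(
        genomes, n_pairs=n_pairs, read_len=read_len,
        rng_seed=int(rng.integers(2**31)),
    )

    # population-consensus effector gene and its fragment ORFs (for the
    # fragmented-gene caller); coordinates on the mutated gene sequence
    population_gene = apply_mutations(
        gene,
        [Mutation(del_off, "A", "", 1.0), Mutation(sub_off, "C", "T", 0.82)],
    )
    dc, sc = 40, 120
    fragment_orfs = [
        Region(0, 3 * (dc + 6)),
        Region(3 * (dc + 8) - 1, 3 * sc - 1),
        Region(3 * sc + 2, 3 * 200 - 1),
    ]
    reference_protein = translate(gene)

    variant_truth = []
    for m in frag_spec.mutations:
        cons, offset = mutation_consequence(host1, gene_region, m)
        variant_truth.append(
            {"position": m.position, "ref": m.ref, "alt": m.alt,
             "fraction": m.fraction, "consequence": cons,
             "stop_offset_codons": offset}
        )

    truth = TruthBundle(
        spacer_catalog=catalog,
        locus_order=order_truth,
        haplotype_frequencies=hap_freqs,
        recent_spacers=[f"r{i + 1:02d}" for i in range(6)],
        protospacers=phage_truth["protospacers"],
        self_targets=self_truth,
        variant_fractions=variant_truth,
        arrays=[{"scaffold": "host1", "start": locus_start, "end": locus_end,
                 "repeat": repeat, "n_spacers": 16, "leader_side": "left"}],
        extras={
            "gene_region": [gene_region.start, gene_region.end],
            "population_gene": population_gene,
            "fragment_orfs": [[r.start, r.end] for r in fragment_orfs],
            "reference_protein": reference_protein,
            "consensus_spacer_ids": [f"b{i + 1:02d}" for i in range(16)],
            "n_pairs": n_pairs,
        },
    )

    return Scenario(
        name="fcasy",
        scaffolds={"host1": host1, "host2": host2, "phage1": phage_seq},
        reads=reads,
        truth=truth,
        annotations=pd.DataFrame(ann_rows),
        bins={"host1": "C2-Gp5", "host2": "C2-Gp5", "phage1": "phage_bin"},
        cas_gene_hint=cas_hint,
        base_array=base_array,
    )


# ---------------------------------------------------------------------------


def scenario_pam(seed: int) -> Scenario:
    """Two phage genomes with 39 unique target locations (20 TA / 14 TG)."""
    rng = np.random.default_rng(seed)
    spacers = {}
    while len(spacers) < 39:
        s = random_dna(30, rng)
        spacers[f"q{len(spacers) + 1:02d}"] = s
    ids = list(spacers)
    pams = ["TA"] * 20 + ["TG"] * 14 + ["AT", "CC", "GA", "AG", "CT"]
    # interleave so both phage carry both motifs
    perm = rng.permutation(39)
    placements_a, placements_b = [], []
    for j, idx in enumerate(perm):
        sid, pam = ids[idx], pams[idx]
        strand = "+" if j % 2 == 0 else "-"
        if j < 20:
            placements_a.append((sid, 400 + 750 * j, strand, pam))
        else:
            placements_b.append((sid, 400 + 700 * (j - 20), strand, pam))
    spec_a = PhageSpec(
        length=16000, planted_protospacers=tuple(placements_a), circular=False,
        keyword_genes=("major capsid protein", "terminase", "tail tape measure protein"),
        name="phageA",
    )
    spec_b = PhageSpec(
        length=14000, planted_protospacers=tuple(placements_b), circular=False,
        keyword_genes=("prohead protein", "portal protein", "lysozyme"),
        name="phageB",
    )
    seq_a, truth_a = make_phage_genome(spec_a, spacers, int(rng.integers(2**31)))
    seq_b, truth_b = make_phage_genome(spec_b, spacers, int(rng.integers(2**31)))

    truth = TruthBundle(
        spacer_catalog=spacers,
        protospacers=truth_a["protospacers"] + truth_b["protospacers"],
        extras={"pam_counts": {"TA": 20, "TG": 14}, "n_locations": 39},
    )
    return Scenario(
        name="pam",
        scaffolds={"phageA": seq_a, "phageB": seq_b},
        reads=[],
        truth=truth,
        annotations=pd.DataFrame(truth_a["annotations"] + truth_b["annotations"]),
        bins={},
    )


# ---------------------------------------------------------------------------


def scenario_prophage(
    seed: int,
    copy_excess: float = 8.0,
    depth: float = 50.0,
    read_len: int = 150,
    phage_len: int = 6000,
    host_len: int = 20000,
) -> Scenario:
    """Integrated prophage with excess free circular phage copies.

    ``copy_excess`` is the expected prophage/flank coverage ratio: free
    phage at abundance (copy_excess - 1) on top of one integrated copy.
    """
    rng = np.random.default_rng(seed)
    phage = random_dna(phage_len, rng)
    start = (host_len - phage_len) // 2
    host = random_dna(start, rng) + phage + random_dna(host_len - start - phage_len, rng)
    region = Region(start, start + phage_len)

    genomes = [SimGenome("host", host, abundance=1.0)]
    if copy_excess > 1:
        genomes.append(
            SimGenome("phage_free", phage, abundance=copy_excess - 1.0, circular=True)
        )
    n_pairs = pairs_for_depth(genomes, depth, read_len, reference="host")
    reads = simulate_read_pairs(
        genomes, n_pairs=n_pairs, read_len=read_len, rng_seed=int(rng.integers(2**31))
    )

    truth = TruthBundle(
        prophage_region=("host", region.start, region.end),
        prophage_copy_excess=copy_excess,
        extras={"phage_len": phage_len, "n_pairs": n_pairs},
    )
    ann = pd.DataFrame(
        [
            {"scaffold": "host", "start": start + 100, "end": start + 1000,
             "strand": "+", "product": "phage integrase"},
            {"scaffold": "host", "start": start + 1200, "end": start + 2400,
             "strand": "+", "product": "terminase large subunit"},
            {"scaffold": "host", "start": start + 2600, "end": start + 4000,
             "strand": "+", "product": "major tail protein"},
        ]
    )
    sc = Scenario(
        name="prophage",
        scaffolds={"host": host},
        reads=reads,
        truth=truth,
        annotations=ann,
        bins={"host": "hostbin"},
    )
    sc.truth.extras["phage_sequence"] = phage
    return sc


# ---------------------------------------------------------------------------


def scenario_basic(seed: int, depth: float = 30.0) -> Scenario:
    """Minimal host locus + phage pair (smoke tests, examples, CLI demo)."""
    rng = np.random.default_rng(seed)
    repeat = random_dna(24, rng)
    spec = LocusSpec(repeat, 6, spacer_len_range=(20, 24), leader_side="left")
    locus_seq, base_array = make_repeat_spacer_locus(
        spec, rng_seed=int(rng.integers(2**31)), scaffold_id="host"
    )
    host = random_dna(3000, rng) + locus_seq + random_dna(3000, rng)
    locus_start = 3000
    catalog = {f"b{i + 1:02d}": sp.sequence for i, sp in enumerate(base_array.spacers)}
    phage_spec = PhageSpec(
        length=8000,
        planted_protospacers=(("b01", 1500, "+", "TA"), ("b03", 4000, "-", "TG")),
        keyword_genes=("major capsid protein", "terminase"),
        name="phage",
    )
    phage_seq, phage_truth = make_phage_genome(
        phage_spec, catalog, int(rng.integers(2**31))
    )
    genomes = [
        SimGenome("host", host, abundance=1.0),
        SimGenome("phage", phage_seq, abundance=2.0),
    ]
    n_pairs = pairs_for_depth(genomes, depth, 150, reference="host")
    reads = simulate_read_pairs(genomes, n_pairs, rng_seed=int(rng.integers(2**31)))
    truth = TruthBundle(
        spacer_catalog=catalog,
        protospacers=phage_truth["protospacers"],
        arrays=[{"scaffold": "host", "start": locus_start,
                 "end": locus_start + len(locus_seq), "repeat": repeat,
                 "n_spacers": 6, "leader_side": "left"}],
        extras={"n_pairs": n_pairs},
    )
    return Scenario(
        name="basic",
        scaffolds={"host": host, "phage": phage_seq},
        reads=reads,
        truth=truth,
        annotations=pd.DataFrame(phage_truth["annotations"]),
        bins={"host": "hostbin", "phage": "phagebin"},
        base_array=base_array,
    )


SCENARIOS = {
    "fcasy": scenario_fcasy,
    "pam": scenario_pam,
    "prophage": scenario_prophage,
    "basic": scenario_basic,
}
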