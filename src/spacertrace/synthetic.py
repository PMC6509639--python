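"""Synthetic host/phage genomes, population haplotypes and paired reads.

This module generates desk-scale data with the statistical structure the
analysis stages assume: a host genome carrying a repeat-spacer CRISPR locus
whose leader end diversifies across population haplotypes, phage genomes
carrying protospacers flanked by a configurable PAM mix, an integrated
prophage with optional excess free-phage copy number, circular genomes, and
a protein-coding gene fragmented by a homopolymer deletion and a nonsense
substitution at configurable population fractions.  Every planted feature
is recorded in a machine-readable :class:`TruthBundle` so that recovery can
be tested against ground truth.

Conventions: coordinates 0-based half-open, strand '+'/'-', background
sequence i.i.d. with configurable GC (default 0.33), sequencing errors are
uniform substitutions only, base qualities are constant 'I'.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seq import DNA_ALPHABET, gc_content, hamming, random_dna, revcomp, translate
from .types import CrisprArray, Region, Spacer, to_plain

# codons that never appear in generated coding sequence
STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in DNA_ALPHABET
    for b in DNA_ALPHABET
    for c in DNA_ALPHABET
    if a + b + c not in STOP_CODONS
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class LocusSpec:
    """Architecture of a planted repeat-spacer locus."""

    repeat_seq: str
    spacer_count: int
    spacer_len_range: tuple[int, int] = (18, 20)
    leader_side: str = "left"

    def __post_init__(self) -> None:
        if not (21 <= len(self.repeat_seq) <= 48):
            raise ValueError("repeat length must be in [21, 48] nt")
        if set(self.repeat_seq) - set(DNA_ALPHABET):
            raise ValueError("repeat must be over {A,C,G,T}")
        if self.spacer_count < 2:
            raise ValueError("spacer_count must be >= 2")
        lo, hi = self.spacer_len_range
        if not (0 < lo <= hi):
            raise ValueError("bad spacer length range")
        if self.leader_side not in ("left", "right"):
            raise ValueError("leader_side must be left or right")


@dataclass(frozen=True)
class HaplotypeSpec:
    """One population haplotype derived from a base locus.

    ``added_leader_spacers`` are appended at the leader end (last element is
    the outermost, i.e. most recently acquired); ``lost_unit_indices`` name
    spacers of the base locus (by list index) whose repeat-spacer unit is
    deleted in this haplotype.
    """

    added_leader_spacers: tuple[str, ...] = ()
    lost_unit_indices: tuple[int, ...] = ()
    frequency: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.frequency <= 1):
            raise ValueError("frequency must be in (0, 1]")


@dataclass(frozen=True)
class PhageSpec:
    """A phage genome with planted protospacers.

    ``planted_protospacers`` entries are (spacer_id, position, strand,
    pam_2mer); the PAM dinucleotide sits immediately 5' of the protospacer
    on the targeted strand.
    """

    length: int
    planted_protospacers: tuple[tuple[str, int, str, str], ...] = ()
    circular: bool = False
    keyword_genes: tuple[str, ...] = ()
    name: str = "phage"

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError("phage length unrealistically short")
        for sid, pos, strand, pam in self.planted_protospacers:
            if strand not in "+-":
                raise ValueError(f"bad strand for {sid}")
            if len(pam) != 2 or set(pam) - set(DNA_ALPHABET):
                raise ValueError(f"bad PAM 2-mer {pam!r}")


@dataclass(frozen=True)
class Mutation:
    position: int  # 0-based on the host scaffold
    ref: str
    alt: str
    fraction: float

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError("mutation fraction must be in (0, 1]")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass(frozen=True)
class FragmentationSpec:
    """A gene region plus mutations that must disrupt its translation."""

    gene_region: Region
    mutations: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        if len(self.gene_region) % 3:
            raise ValueError("gene region length must be divisible by 3")
        for m in self.mutations:
            if not (self.gene_region.start <= m.position < self.gene_region.end):
                raise ValueError("mutation outside gene region")


@dataclass
class TruthBundle:
    """Machine-readable ground truth for one generated scenario."""

    spacer_catalog: dict[str, str] = field(default_factory=dict)  # id -> seq
    locus_order: dict[str, list[str]] = field(default_factory=dict)  # hap -> spacer ids
    haplotype_frequencies: dict[str, float] = field(default_factory=dict)
    recent_spacers: list[str] = field(default_factory=list)
    protospacers: list[dict] = field(default_factory=list)
    self_targets: list[dict] = field(default_factory=list)
    prophage_region: Optional[tuple[str, int, int]] = None
    prophage_copy_excess: float = 1.0
    variant_fractions: list[dict] = field(default_factory=list)
    arrays: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(to_plain(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------------------
# locus construction


def _resembles(a: str, b: str, tol: int = 2, min_overlap: int = 16) -> bool:
    """True when any >= min_overlap alignment of a vs b has <= tol mismatches.

    All relative shifts are considered, so shifted near-copies (which would
    blur the repeat/spacer boundary) are caught, not just contained ones.
    """
    for shift in range(-(len(a) - min_overlap), len(b) - min_overlap + 1):
        start_a, start_b = max(0, -shift), max(0, shift)
        n = min(len(a) - start_a, len(b) - start_b)
        if n < min_overlap:
            continue
        if hamming(a[start_a : start_a + n], b[start_b : start_b + n], limit=tol) <= tol:
            return True
    return False


def make_repeat_spacer_locus(
    spec: LocusSpec, rng_seed: int, scaffold_id: str = "locus", offset: int = 0
) -> tuple[str, CrisprArray]:
    """Build the sequence R S1 R S2 ... Sn R and its truth record.

    Spacers are mutually distinct i.i.d. random sequences with lengths drawn
    uniformly from the spec's range; a draw resembling the repeat (either
    orientation) is rejected so that the repeat-spacer architecture stays
    well defined.  ``offset`` shifts truth coordinates so the locus can be
    embedded in a larger scaffold.
    """
    rng = np.random.default_rng(rng_seed)
    lo, hi = spec.spacer_len_range
    rc_repeat = revcomp(spec.repeat_seq)
    spacers: list[str] = []
    seen = {spec.repeat_seq}
    while len(spacers) < spec.spacer_count:
        s = random_dna(int(rng.integers(lo, hi + 1)), rng)
        if s in seen:
            continue
        if _resembles(s, spec.repeat_seq) or _resembles(s, rc_repeat):
            continue
        seen.add(s)
        spacers.append(s)

    parts = [spec.repeat_seq]
    repeats = [Region(offset, offset + len(spec.repeat_seq))]
    spacer_objs = []
    pos = offset + len(spec.repeat_seq)
    n = spec.spacer_count
    for i, s in enumerate(spacers):
        parts.append(s)
        idx = i if spec.leader_side == "left" else n - 1 - i
        spacer_objs.append(Spacer(sequence=s, array_id=scaffold_id, index_from_leader=idx))
        pos += len(s)
        parts.append(spec.repeat_seq)
        repeats.append(Region(pos, pos + len(spec.repeat_seq)))
        pos += len(spec.repeat_seq)

    array = CrisprArray(
        scaffold_id=scaffold_id,
        repeat_consensus=spec.repeat_seq,
        repeat_instances=repeats,
        spacers=spacer_objs,
        leader_side=spec.leader_side,
        array_id=scaffold_id,
    )
    return "".join(parts), array


def diversify_population(
    base_seq: str,
    base_array: CrisprArray,
    haplotypes: Sequence[HaplotypeSpec],
) -> list[tuple[str, list[str], HaplotypeSpec]]:
    """Apply leader-end additions and unit losses to the base locus.

    Returns one (locus sequence, spacer order leader->distal, spec) triple
    per haplotype.  Added spacers get their own flanking repeat at the
    leader side; a lost unit removes one spacer and one repeat.
    """
    total = sum(h.frequency for h in haplotypes)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"haplotype frequencies sum to {total}, expected 1")

    repeat = base_array.repeat_consensus
    base_order = [sp.sequence for sp in base_array.spacers]
    if base_array.leader_side == "right":
        base_order = base_order[::-1]  # leader -> distal
    catalog = set(base_order)

    out = []
    for hap in haplotypes:
        for s in hap.added_leader_spacers:
            if s in catalog:
                raise ValueError(f"added spacer duplicates catalog entry: {s}")
        for idx in hap.lost_unit_indices:
            if not (0 <= idx < len(base_order)):
                raise ValueError(f"lost unit index {idx} out of range")
        order = [s for i, s in enumerate(base_order) if i not in set(hap.lost_unit_indices)]
        # most recently acquired spacer is outermost at the leader end
        order = list(hap.added_leader_spacers)[::-1] + order
        seq_order = order if base_array.leader_side == "left" else order[::-1]
        seq = repeat + "".join(s + repeat for s in seq_order)
        out.append((seq, order, hap))
    new = [s for hap in haplotypes for s in hap.added_leader_spacers]
    if len(new) != len(set(new)):
        raise ValueError("added leader spacers collide across haplotypes")
    return out


# ---------------------------------------------------------------------------
# phage construction


def make_phage_genome(
    spec: PhageSpec, spacer_catalog: dict[str, str], rng_seed: int, gc: float = 0.33
) -> tuple[str, dict]:
    """Random phage genome with exact protospacer copies planted.

    For a '+' placement the protospacer equals the spacer and the PAM 2-mer
    occupies ``[pos-2, pos)`` on the forward strand; for a '-' placement the
    interval carries the reverse complement of the spacer and the PAM (as
    read 5' of the protospacer on the minus strand) occupies ``[pos+m,
    pos+m+2)`` in forward coordinates.
    """
    rng = np.random.default_rng(rng_seed)
    genome = list(random_dna(spec.length, rng, gc=gc))
    occupied: list[Region] = []
    truth_hits = []
    for sid, pos, strand, pam in spec.planted_protospacers:
        if sid not in spacer_catalog:
            raise ValueError(f"unknown spacer id {sid}")
        s = spacer_catalog[sid]
        m = len(s)
        if strand == "+":
            iv = Region(pos - 2, pos + m)
            insert = pam + s
        else:
            iv = Region(pos, pos + m + 2)
            insert = revcomp(s) + revcomp(pam)
        if iv.start < 0 or iv.end > spec.length:
            raise ValueError(f"protospacer {sid} out of bounds")
        for other in occupied:
            if iv.overlaps(other):
                raise ValueError(f"protospacer placements overlap at {sid}")
        occupied.append(iv)
        genome[iv.start : iv.end] = insert
        truth_hits.append(
            {
                "spacer_id": sid,
                "scaffold": spec.name,
                "start": pos,
                "end": pos + m,
                "strand": strand,
                "pam": pam,
            }
        )

    annotations = _tile_genes(spec.length, spec.keyword_genes, occupied, rng, spec.name)
    truth = {"name": spec.name, "protospacers": truth_hits, "annotations": annotations,
             "circular": spec.circular}
    return "".join(genome), truth


def _tile_genes(length, products, protospacer_ivs, rng, scaffold):
    """Assign annotation rows; protospacer-bearing intervals fall inside genes."""
    rows = []
    n = len(products)
    if n == 0:
        return rows
    bounds = np.linspace(0, length, n + 1).astype(int)
    for i, product in enumerate(products):
        start, end = int(bounds[i]) + 10, int(bounds[i + 1]) - 10
        end = start + ((end - start) // 3) * 3
        rows.append(
            {"scaffold": scaffold, "start": start, "end": end,
             "strand": "+" if i % 2 == 0 else "-", "product": product}
        )
    return rows


# ---------------------------------------------------------------------------
# gene fragmentation


def apply_mutations(seq: str, mutations: Sequence[Mutation]) -> str:
    """Apply substitutions/deletions (coordinates refer to the input)."""
    out = seq
    for m in sorted(mutations, key=lambda m: -m.position):
        if out[m.position : m.position + len(m.ref)] != m.ref:
            raise ValueError(f"ref allele mismatch at {m.position}")
        out = out[: m.position] + m.alt + out[m.position + len(m.ref) :]
    return out


def _premature_stop(gene: str, mutated_gene: str):
    """First stop in the mutated frame that is premature vs the original."""
    orig = translate(gene)
    mut = translate(mutated_gene)
    orig_stop = orig.find("*")
    mut_stop = mut.find("*")
    if mut_stop == -1:
        return None
    if orig_stop != -1 and mut_stop >= orig_stop:
        return None
    return mut_stop


def plant_gene_fragmentation(
    host: str, spec: FragmentationSpec
) -> list[tuple[str, float, tuple[Mutation, ...]]]:
    """Emit host haplotype sequences carrying the disruptive mutations.

    Mutations combine independently: a mutation at fraction f is present in
    fraction f of cells regardless of the others, so k mutations yield up to
    2**k haplotypes (zero-fraction combinations are dropped).  Each mutation
    is verified, by translation, to introduce a premature stop codon in the
    gene frame; otherwise it is rejected.
    """
    g = spec.gene_region
    gene = host[g.start : g.end]
    for m in spec.mutations:
        rel = Mutation(m.position - g.start, m.ref, m.alt, m.fraction)
        stop = _premature_stop(gene, apply_mutations(gene, [rel]))
        if stop is None:
            raise ValueError(
                f"mutation at {m.position} does not disrupt translation"
            )
    haplotypes = []
    k = len(spec.mutations)
    for mask in range(2 ** k):
        chosen = tuple(m for i, m in enumerate(spec.mutations) if mask >> i & 1)
        frac = 1.0
        for i, m in enumerate(spec.mutations):
            frac *= m.fraction if mask >> i & 1 else 1 - m.fraction
        if frac <= 1e-12:
            continue
        haplotypes.append((apply_mutations(host, chosen), frac, chosen))
    total = sum(f for _, f, _ in haplotypes)
    haplotypes = [(s, f / total, ms) for s, f, ms in haplotypes]
    return haplotypes


def mutation_consequence(host: str, region: Region, m: Mutation) -> tuple[str, Optional[int]]:
    """Consequence of one mutation on the gene frame, by translation.

    Returns (consequence, stop_offset_codons) where the offset counts codons
    from the codon containing the mutated position to the new stop codon, in
    the mutated sequence.
    """
    gene = host[region.start : region.end]
    rel = Mutation(m.position - region.start, m.ref, m.alt, m.fraction)
    mutated = apply_mutations(gene, [rel])
    stop = _premature_stop(gene, mutated)
    if stop is None:
        return "other", None
    kind = "frameshift_stop" if len(m.ref) != len(m.alt) else "nonsense"
    mut_codon = rel.position // 3
    return kind, stop - mut_codon


def make_fragmentable_gene(rng: np.random.Generator, n_codons: int,
                           del_codon: int, sub_codon: int) -> tuple[str, int, int]:
    """Random stop-free coding sequence with two engineered mutation sites.

    At ``del_codon`` an ``AAAAA`` homopolymer is laid down such that deleting
    one A shifts the frame and exposes a TAA stop exactly five codons
    downstream of the deletion codon; at ``sub_codon`` a CAA codon is placed
    whose C->T substitution creates an immediate TAA stop.  Returns the gene
    plus the 0-based in-gene offsets of the deleted A and the substituted C.
    """
    if not (0 < del_codon + 8 < sub_codon < n_codons - 1):
        raise ValueError("mutation sites too close or out of range")
    codons = [
        _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))] for _ in range(n_codons)
    ]
    # AAA AAC ACG GAT CGG TCA CTA ACC: deleting one A of the AAAAA run
    # shifts the frame to AAA ACA CGG ATC GGT CAC TAA -> stop exactly five
    # codons downstream of the deletion codon; the downstream bases are
    # deliberately non-repetitive so a shifted (deleted) read cannot align
    # ungapped without rapidly accruing mismatches
    engineered = ["AAA", "AAC", "ACG", "GAT", "CGG", "TCA", "CTA", "ACC"]
    codons[del_codon : del_codon + 8] = engineered
    codons[sub_codon] = "CAA"
    gene = "".join(codons)
    assert "*" not in translate(gene)
    del_offset = del_codon * 3 + 4  # last A of the AAAAA run
    sub_offset = sub_codon * 3  # the C of CAA
    return gene, del_offset, sub_offset


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class SimGenome:
    name: str
    sequence: str
    abundance: float
    circular: bool = False

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be > 0")


@dataclass(frozen=True)
class ReadPair:
    name: str
    r1: str
    r2: str
    source: str = ""


def simulate_read_pairs(
    genomes: Sequence[SimGenome],
    n_pairs: int,
    read_len: int = 150,
    insert_mean: int = 300,
    insert_sd: float = 30.0,
    error_rate: float = 0.0,
    rng_seed: int = 0,
) -> list[ReadPair]:
    """Simulate paired-end reads (uniform fragment start, FR orientation).

    Fragments are allocated to genomes proportional to abundance x length;
    circular genomes yield wrap-around fragments.  Linear genomes shorter
    than a read are skipped with a warning.  Deterministic per seed.
    """
    import warnings

    if read_len >= insert_mean:
        raise ValueError("read_len must be < insert_mean")
    usable = []
    for g in genomes:
        if not g.circular and len(g.sequence) < read_len:
            warnings.warn(f"genome {g.name} shorter than read length; skipped")
            continue
        usable.append(g)
    if not usable:
        return []

    rng = np.random.default_rng(rng_seed)
    weights = np.array([g.abundance * len(g.sequence) for g in usable], float)
    counts = rng.multinomial(n_pairs, weights / weights.sum())

    pairs: list[ReadPair] = []
    serial = 0
    for g, cnt in zip(usable, counts):
        L = len(g.sequence)
        doubled = g.sequence + g.sequence if g.circular else g.sequence
        inserts = rng.normal(insert_mean, insert_sd, size=cnt)
        inserts = np.clip(np.rint(inserts), read_len, max(read_len, L)).astype(int)
        for ins in inserts:
            if g.circular:
                start = int(rng.integers(0, L))
            else:
                ins = min(ins, L)
                start = int(rng.integers(0, L - ins + 1))
            frag = doubled[start : start + ins]
            r1, r2 = frag[:read_len], revcomp(frag[-read_len:])
            if error_rate > 0:
                r1 = _add_errors(r1, error_rate, rng)
                r2 = _add_errors(r2, error_rate, rng)
            pairs.append(ReadPair(f"{g.name}_{serial}", r1, r2, source=g.name))
            serial += 1
    return pairs


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    out = list(read)
    sites = rng.choice(len(read), size=n_err, replace=False)
    for i in sites:
        choices = [b for b in DNA_ALPHABET if b != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def pairs_for_depth(genomes: Sequence[SimGenome], depth: float, read_len: int,
                    reference: Optional[str] = None) -> int:
    """Number of pairs so that the given genome group reaches ``depth``.

    With ``reference`` set, depth refers to genomes whose name starts with
    that prefix (reads land there in proportion to abundance x length).
    """
    w = {g.name: g.abundance * len(g.sequence) for g in genomes}
    total = sum(w.values())
    if reference is None:
        target_w = total
        target_len = sum(len(g.sequence) for g in genomes)
    else:
        sel = [g for g in genomes if g.name.startswith(reference)]
        if not sel:
            raise ValueError(f"no genome matches prefix {reference!r}")
        target_w = sum(w[g.name] for g in sel)
        # haplotypes of one replicon share length; use weighted mean
        target_len = sum(w[g.name] * len(g.sequence) for g in sel) / target_w
    frac = target_w / total
    return int(np.ceil(depth * target_len / (2 * read_len * frac)))
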