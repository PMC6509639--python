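"""Read-level evidence: mapping, prophage activity, circularity, variants.

The internal mapper is exact-k-mer-seeded (k = 31 by default), ungapped and
substitution-only, with a short-deletion rescue: a read whose left and
right seeds place at offsets differing by a small positive shift is aligned
as two segments around a deletion.  Pairs with two or more substitution
mismatches combined across both mates are discarded (configurable), the
filter used when curating population read sets against an assembled
scaffold.  Downstream layers turn retained alignments into coverage-ratio
prophage calls, circularization support, pileup-based disruptive-variant
calls, and fragmented-gene (split-ORF) calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align

from .seq import revcomp, translate
from .synthetic import Mutation, ReadPair, apply_mutations
from .types import (
    CoverageProfile,
    FragmentationCall,
    ProphageCall,
    Region,
    VariantCall,
)

log = logging.getLogger(__name__)


@dataclass
class Alignment:
    """One ungapped (or single-deletion) read placement."""

    read_id: str
    scaffold: str
    start: int  # leftmost reference coordinate
    strand: str
    mismatches: int
    read_len: int
    deletion: Optional[tuple[int, int]] = None  # (ref position, length)
    query: str = ""  # read in reference orientation

    @property
    def end(self) -> int:
        d = self.deletion[1] if self.deletion else 0
        return self.start + self.read_len + d


@dataclass
class MappingResult:
    pairs: list[tuple[Alignment, Alignment]]
    coverage: dict[str, CoverageProfile]
    n_input_pairs: int = 0
    n_discarded_filter: int = 0
    n_unmapped: int = 0
    unmapped_reads: list[tuple[str, str]] = field(default_factory=list)


class _SeedIndex:
    def __init__(self, scaffolds: dict[str, str], k: int):
        self.k = k
        self.table: dict[str, list[tuple[str, int]]] = {}
        for name, seq in scaffolds.items():
            for i in range(len(seq) - k + 1):
                self.table.setdefault(seq[i : i + k], []).append((name, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.table.get(kmer, [])


def _count_mm(ref: str, start: int, query: str, limit: int) -> Optional[int]:
    if start < 0 or start + len(query) > len(ref):
        return None
    mm = 0
    for a, b in zip(query, ref[start : start + len(query)]):
        if a != b:
            mm += 1
            if mm > limit:
                return None
    return mm


def _align_read(
    read_id: str,
    read: str,
    scaffolds: dict[str, str],
    index: _SeedIndex,
    max_mismatch: int,
    max_deletion: int,
) -> Optional[Alignment]:
    """Best ungapped placement of a read; deletion rescue as fallback."""
    k = index.k
    L = len(read)
    if L < k:
        return None
    best: Optional[Alignment] = None
    for strand, query in (("+", read), ("-", revcomp(read))):
        seen: set[tuple[str, int]] = set()
        for off in (0, L - k, (L - k) // 2):
            for name, pos in index.lookup(query[off : off + k]):
                cand = (name, pos - off)
                if cand in seen:
                    continue
                seen.add(cand)
                mm = _count_mm(scaffolds[name], cand[1], query, max_mismatch)
                if mm is None:
                    continue
                aln = Alignment(read_id, name, cand[1], strand, mm, L, query=query)
                if best is None or (aln.mismatches, aln.start) < (best.mismatches, best.start):
                    best = aln
        if best is not None and best.mismatches == 0:
            break
    if best is not None:
        return best

    # deletion rescue: left and right seeds shifted by the deletion length
    for strand, query in (("+", read), ("-", revcomp(read))):
        lefts = index.lookup(query[:k])
        rights = index.lookup(query[L - k :])
        for name_l, pos_l in lefts:
            for name_r, pos_r in rights:
                if name_l != name_r:
                    continue
                d = (pos_r - (L - k)) - pos_l
                if not (1 <= d <= max_deletion):
                    continue
                ref = scaffolds[name_l]
                # greedy split: longest matching prefix
                p = 0
                while p < L and pos_l + p < len(ref) and query[p] == ref[pos_l + p]:
                    p += 1
                p = min(p, L - 1)
                mm = _count_mm(ref, pos_l + p + d, query[p:], max_mismatch)
                if mm is None:
                    continue
                return Alignment(
                    read_id, name_l, pos_l, strand, mm, L,
                    deletion=(pos_l + p, d), query=query,
                )
    return None


def map_reads(
    pairs: Iterable[ReadPair],
    scaffolds: dict[str, str],
    max_pair_mismatch: int = 1,
    seed_k: int = 31,
    max_read_mismatch: int = 4,
    max_deletion: int = 5,
) -> MappingResult:
    """Map read pairs and apply the combined pair-mismatch filter.

    Each mate is placed at its best exact-seeded ungapped position (with
    short-deletion rescue); pairs whose mates' substitution mismatches sum
    to more than ``max_pair_mismatch`` are discarded, as are pairs with an
    unmappable mate.  Coverage profiles count aligned bases of retained
    pairs only.
    """
    if not scaffolds:
        raise ValueError("no scaffolds supplied")
    index = _SeedIndex(scaffolds, seed_k)
    depth = {name: np.zeros(len(seq), dtype=np.int32) for name, seq in scaffolds.items()}
    retained: list[tuple[Alignment, Alignment]] = []
    n_input = n_filtered = n_unmapped = 0
    unmapped: list[tuple[str, str]] = []
    for pair in pairs:
        n_input += 1
        a1 = _align_read(pair.name + "/1", pair.r1, scaffolds, index,
                         max_read_mismatch, max_deletion)
        a2 = _align_read(pair.name + "/2", pair.r2, scaffolds, index,
                         max_read_mismatch, max_deletion)
        if a1 is None or a2 is None:
            n_unmapped += 1
            if a1 is None:
                unmapped.append((pair.name + "/1", pair.r1))
            if a2 is None:
                unmapped.append((pair.name + "/2", pair.r2))
            continue
        if a1.mismatches + a2.mismatches > max_pair_mismatch:
            n_filtered += 1
            continue
        retained.append((a1, a2))
        for aln in (a1, a2):
            arr = depth[aln.scaffold]
            if aln.deletion is None:
                arr[aln.start : aln.end] += 1
            else:
                dpos, dlen = aln.deletion
                arr[aln.start : dpos] += 1
                arr[dpos + dlen : aln.end] += 1

    coverage = {
        name: CoverageProfile(
            scaffold_id=name, depth=depth[name],
            mapped_pairs=sum(
                1 for a1, a2 in retained if a1.scaffold == name or a2.scaffold == name
            ),
        )
        for name in scaffolds
    }
    return MappingResult(
        pairs=retained, coverage=coverage, n_input_pairs=n_input,
        n_discarded_filter=n_filtered, n_unmapped=n_unmapped,
        unmapped_reads=unmapped,
    )


# ---------------------------------------------------------------------------
# prophage activity and circularity


def prophage_activity_call(
    profile: CoverageProfile,
    region: Region,
    flank_len: int = 2000,
    ratio_threshold: float = 3.0,
    circular_support: int = 0,
    min_circular_pairs: int = 3,
) -> ProphageCall:
    """Coverage-ratio call for a (user- or truth-supplied) prophage region.

    ``active_particles`` requires the region/flank depth ratio to reach the
    threshold or independent circularization support; otherwise the
    prophage is called integrated only.
    """
    n = len(profile.depth)
    if not (0 <= region.start < region.end <= n):
        raise ValueError("region outside scaffold")
    left = profile.depth[max(0, region.start - flank_len) : region.start]
    right = profile.depth[region.end : min(n, region.end + flank_len)]
    flank = np.concatenate([left, right])
    if flank.size == 0:
        raise ValueError("no flanking sequence on either side")
    region_mean = float(profile.depth[region.start : region.end].mean())
    flank_mean = float(flank.mean())
    ratio = region_mean / flank_mean if flank_mean > 0 else None
    active = (ratio is not None and ratio >= ratio_threshold) or (
        circular_support >= min_circular_pairs
    )
    return ProphageCall(
        region=region,
        region_mean_depth=region_mean,
        flank_mean_depth=flank_mean,
        ratio=ratio,
        circular_support=circular_support,
        state="active_particles" if active else "integrated_only",
    )


def detect_circularity(
    alignments: Sequence[tuple[Alignment, Alignment]],
    scaffold_id: str,
    scaffold_len: int,
    end_window: int = 500,
    unmapped_reads: Optional[Sequence[tuple[str, str]]] = None,
    scaffold_seq: Optional[str] = None,
    seed_k: int = 31,
) -> int:
    """Read support for a circular template.

    Counts pairs with the '+' mate in the terminal window and the '-' mate
    in the initial window (outward orientation, consistent only with a
    fragment spanning the junction of a circular template), plus unmapped
    reads whose prefix matches the scaffold end and suffix the scaffold
    start (junction-spanning split reads), when a sequence is supplied.
    """
    if scaffold_len <= 2 * end_window:
        raise ValueError("invalid window: end_window >= half the scaffold")
    support = 0
    for a1, a2 in alignments:
        if a1.scaffold != scaffold_id or a2.scaffold != scaffold_id:
            continue
        if {a1.strand, a2.strand} != {"+", "-"}:
            continue
        plus = a1 if a1.strand == "+" else a2
        minus = a2 if plus is a1 else a1
        if plus.start >= scaffold_len - end_window and minus.end <= end_window:
            support += 1
    if unmapped_reads and scaffold_seq:
        junction = scaffold_seq[-seed_k:] + scaffold_seq[:seed_k]
        for _, read in unmapped_reads:
            for q in (read, revcomp(read)):
                if _spans_junction(q, scaffold_seq, seed_k):
                    support += 1
                    break
    return support


def _spans_junction(read: str, ref: str, k: int) -> bool:
    """Prefix anchors near the end of ref and suffix near its start."""
    L = len(read)
    if L < 2 * k:
        return False
    p = ref.rfind(read[:k])
    q = ref.find(read[L - k :])
    if p == -1 or q == -1:
        return False
    # split position: prefix runs to the end of ref, remainder wraps
    tail = len(ref) - p
    if not (0 < tail < L):
        return False
    return ref[p:] == read[:tail] and ref[: L - tail] == read[tail:]


# ---------------------------------------------------------------------------
# disruptive variants


def call_disrupting_variants(
    alignments: Sequence[tuple[Alignment, Alignment]],
    scaffold: str,
    scaffold_id: str,
    gene_region: Region,
    min_depth: int = 10,
    min_alt_fraction: float = 0.1,
) -> list[VariantCall]:
    """Pileup-based substitution and short-deletion calls over a gene.

    ``alt_fraction`` is alt reads / (alt + ref reads) per site; every alt
    is applied in silico to the gene frame (frame taken from the supplied
    region, assumed '+'/frame 0) and the consequence plus the offset (in
    codons) to the introduced stop is recorded.  Sites below ``min_depth``
    are not called.
    """
    n = len(scaffold)
    counts = {b: np.zeros(n, dtype=np.int32) for b in "ACGT"}
    del_support: dict[tuple[int, int], int] = {}
    ungapped_spans: list[tuple[int, int]] = []

    for a1, a2 in alignments:
        for aln in (a1, a2):
            if aln.scaffold != scaffold_id:
                continue
            segs = []
            if aln.deletion is None:
                segs.append((aln.start, aln.query))
                ungapped_spans.append((aln.start, aln.end, aln.query))
            else:
                dpos, dlen = aln.deletion
                split = dpos - aln.start
                segs.append((aln.start, aln.query[:split]))
                segs.append((dpos + dlen, aln.query[split:]))
                del_support[(dpos, dlen)] = del_support.get((dpos, dlen), 0) + 1
            for start, seg in segs:
                for i, b in enumerate(seg):
                    if b in counts:
                        counts[b][start + i] += 1

    depth = sum(counts.values())
    calls: list[VariantCall] = []
    for pos in range(gene_region.start, gene_region.end):
        d = int(depth[pos])
        ref_base = scaffold[pos]
        if d < min_depth:
            continue
        ref_count = int(counts.get(ref_base, np.zeros(1))[pos]) if ref_base in counts else 0
        for alt in "ACGT":
            if alt == ref_base:
                continue
            alt_count = int(counts[alt][pos])
            if alt_count + ref_count == 0:
                continue
            frac = alt_count / (alt_count + ref_count)
            if frac < min_alt_fraction or alt_count == 0:
                continue
            cons, offset = _consequence(scaffold, gene_region, pos, ref_base, alt)
            calls.append(
                VariantCall(
                    scaffold_id=scaffold_id, position=pos, ref=ref_base, alt=alt,
                    alt_fraction=frac, consequence=cons,
                    stop_offset_codons=offset, depth=d,
                )
            )
    for (dpos, dlen), alt_count in sorted(del_support.items()):
        if not (gene_region.start <= dpos < gene_region.end):
            continue
        # a read supports the reference allele only if it matches the
        # reference exactly across the deletion's homopolymer context plus
        # one anchor base each side; reads starting or ending inside the
        # run (or shifted across it) are consistent with both alleles
        run_start, run_end = dpos, dpos + dlen
        while run_start > 0 and scaffold[run_start - 1] == scaffold[dpos]:
            run_start -= 1
        while run_end < n and scaffold[run_end] == scaffold[dpos]:
            run_end += 1
        w0, w1 = run_start - 1, run_end + 1
        ref_count = sum(
            1
            for s, e, q in ungapped_spans
            if s <= w0 and e >= w1 and q[w0 - s : w1 - s] == scaffold[w0:w1]
        )
        total = alt_count + ref_count
        if total < min_depth:
            continue
        frac = alt_count / total
        if frac < min_alt_fraction:
            continue
        ref_allele = scaffold[dpos : dpos + dlen]
        cons, offset = _consequence(scaffold, gene_region, dpos, ref_allele, "")
        calls.append(
            VariantCall(
                scaffold_id=scaffold_id, position=dpos, ref=ref_allele, alt="",
                alt_fraction=frac, consequence=cons,
                stop_offset_codons=offset, depth=total,
            )
        )
    calls.sort(key=lambda c: (c.position, c.alt))
    return calls


def _consequence(scaffold: str, region: Region, pos: int, ref: str, alt: str):
    from .synthetic import mutation_consequence

    m = Mutation(position=pos, ref=ref, alt=alt if alt else "", fraction=1.0)
    return mutation_consequence(scaffold, region, m)


# ---------------------------------------------------------------------------
# fragmented genes


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def detect_fragmented_gene(
    orfs: Sequence[tuple[Region, str]],
    reference_protein: str,
    scaffold: str,
    min_tiling_coverage: float = 0.6,
    min_fragment_aa: int = 15,
    min_score_per_aa: float = 1.5,
    max_overlap_aa: int = 5,
) -> Optional[FragmentationCall]:
    """Call a gene split into consecutive same-strand ORF fragments.

    Each ORF translation is locally aligned to the reference protein
    (match 2, mismatch -1, gap -2); a fragmentation is called when the
    accepted fragments cover ordered, near-non-overlapping reference
    segments with combined coverage >= ``min_tiling_coverage``.  Returns
    None when the evidence does not reach the thresholds.
    """
    if len(orfs) < 2:
        raise ValueError("need >= 2 adjacent ORFs")
    strands = {s for _, s in orfs}
    if len(strands) != 1:
        raise ValueError("ORFs must share a strand")
    strand = strands.pop()

    aligner = _protein_aligner()
    accepted: list[tuple[Region, tuple[int, int]]] = []
    for region, _ in orfs:
        dna = scaffold[region.start : region.end]
        if strand == "-":
            dna = revcomp(dna)
        prot = translate(dna).rstrip("*")
        if not prot or "*" in prot:
            prot = prot.split("*")[0]
        if len(prot) < min_fragment_aa:
            continue
        alns = aligner.align(reference_protein, prot)
        if len(alns) == 0:
            continue
        best = alns[0]
        ref_span = (int(best.aligned[0][0][0]), int(best.aligned[0][-1][1]))
        aligned_len = ref_span[1] - ref_span[0]
        if aligned_len < min_fragment_aa:
            continue
        if best.score < min_score_per_aa * aligned_len:
            continue
        accepted.append((region, ref_span))

    if len(accepted) < 2:
        return None
    accepted.sort(key=lambda t: t[0].start)
    if strand == "-":
        accepted = accepted[::-1]
    spans = [s for _, s in accepted]
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < s1 or e2 < e1 or s2 < e1 - max_overlap_aa:
            return None
    covered = set()
    for s, e in spans:
        covered.update(range(s, e))
    coverage = len(covered) / len(reference_protein)
    if coverage < min_tiling_coverage:
        return None
    frag_regions = sorted((r for r, _ in accepted), key=lambda r: r.start)
    gene = Region(frag_regions[0].start, frag_regions[-1].end)
    return FragmentationCall(
        gene_region=gene,
        fragment_orfs=frag_regions,
        tiling_coverage_of_reference=round(coverage, 6),
    )
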