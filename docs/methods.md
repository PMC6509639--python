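# Methods

This note documents the models, parameter choices and numerical decisions
behind spacertrace, and what the synthetic study conditions do and do not
establish about real data.

## Scope and data model

All coordinates are 0-based half-open on the forward strand; strand is
'+'/'-'. Inputs are assembled scaffolds (FASTA), paired reads (FASTQ),
an optional gene table (scaffold, start, end, strand, product) and an
optional scaffold→bin table. The analysis treats the assembled scaffold as
the population reference: reads are interpreted against it, and
population structure (leader-end spacer additions, unit losses, variant
fractions) is read out of the reads, not the assembly.

## Array detection

A k-mer seed (k = 8) occurring twice at a distance within
[repeat_min + spacer_min, repeat_max + spacer_max] starts an anchor chain;
the chain greedily appends further occurrences at admissible gaps. Chains
with ≥ min_units anchors are extended outward column-by-column across the
aligned instances: a column extends the repeat while the majority base is
unanimous (for ≤ 10 instances) or has at most one deviant (> 10). The
consensus is the column-wise majority; instances exceeding the mismatch
budget are dropped unless they are terminal and ≥ 60% identical (arrays
commonly end in a degenerate repeat). Gaps between consecutive instances
must lie within the spacer-length bounds; the longest valid run is kept,
and overlapping candidates resolve to more units, then longer span.

Defaults: repeat 21–48 nt, spacer 18–72 nt, min_units 3, ≤ 2 substitutions
per instance. These follow common array statistics and are exposed in
`ArrayParams`; they are choices, not measurements. With these settings the
detector reports zero arrays on 10 Mb of i.i.d. random sequence (the
extension step cannot reach the 21-nt minimum repeat length by chance)
while recalling every planted 3–30-unit array.

Boundary precision: for 3–4 instances there is a ~6% chance per side that
one boundary column agrees by chance across all instances, shifting the
repeat/spacer boundary by one base. Detection (unit counts, spans) is
unaffected; exact spacer sequences from very small arrays can carry a
one-base offset. Loci with many instances do not have this problem.

The leader end is called from per-spacer read support when available (the
end enriched for support-1 spacers), else from the position of a supplied
cas gene coordinate (new spacers are acquired at the cas-proximal end);
conflicts resolve in favour of read support and are logged.

## Locus reconstruction

Reads containing a full-length repeat match (≤ 2 substitutions, either
strand) are recruited and oriented to the array strand. The contract
splitter returns only spacers flanked on both sides by full repeat
matches. For cataloguing and support counts, terminal-partial evidence is
also admitted: a substring bounded by one full repeat and a read-terminal
partial repeat (≥ 8 matching bases, ≤ 1 mismatch) counts when exactly one
placement is consistent with the spacer-length bounds. This is the device
used by read-level CRISPR tools to see rare leader-end spacers in short
reads: a spacer present at ~8× local depth yields only ~4–5 strict
both-flank windows in 150-bp reads, so the strict rule alone misses one of
six rare spacers a few percent of the time, while the partial rule makes
recovery routine. Graph *edges* are built from strict splits only.

The consensus is the maximum-weight path through the spacer graph after
cycle collapse (repeatedly dropping the minimum-weight edge of any cycle;
ties break lexicographically). Because a low-frequency leader addition
contributes a positive-weight edge into the first shared spacer, the raw
maximum-weight path would always absorb exactly one such addition;
terminal path nodes whose support falls below 0.5× the median path
support are therefore trimmed. The factor 0.5 separates
subpopulation-specific additions (support ≈ frequency × depth, well below
half the shared-locus support for any minority subpopulation) from shared
spacers, including units lost in up to half the population. A spacer off
the consensus is flagged **recent** when its edges (if any) all touch the
leader-end consensus node; isolated observations (no strict adjacency at
all) are folded into the recent list with a warning, since in these study
conditions leader-end additions are the only source of such nodes. Edges
skipping consensus spacers yield loss fractions
w_skip/(w_skip + w_through), a direct binomial estimate of the planted
loss frequency.

Identical spacer sequences at different locus positions collapse to one
node (warned); disambiguation would need paired-repeat context beyond the
read length, and the loci this package models have unique spacers.
Reconstruction is deterministic given the graph: all ties (path choice,
ordering of reported lists) break lexicographically.

## Protospacer search

Matching is full-length on both strands with ≤ m substitutions (default
m = 0, i.e. 100% identity and coverage; partial alignments are not
modelled). The scanner splits each spacer into m+1 equal chunks — at
least one must occur exactly in any ≤ m-mismatch placement — looks chunks
up in a per-scaffold exact-substring index, and verifies candidates by
direct comparison. The naive sliding-window scan (`scan_bruteforce`,
vectorized mismatch counting at every offset) is retained as the reference
implementation; the test suite asserts exact agreement of the two routes
across sizes and mismatch budgets. Reverse-complement spacer pairs remain
distinct catalog entries (array orientation matters for PAM work) with a
cross-link to prevent double counting.

Hits overlapping any detected array span are excluded from targeting
statistics. A spacer is self-targeting iff it retains a hit on a scaffold
in the same bin as its source array; hits on unbinned scaffolds are
tallied as unresolved. Targeted scaffolds are classified phage-like by
case-insensitive substring match of their product annotations against the
standard phage keyword list (capsid, phage, virus, prophage, terminase,
prohead, tape measure, tail, head, portal, DNA packaging).

## PAM inference

For each hit the 5 bp upstream and downstream on the targeted strand are
extracted ('+': upstream = scaffold[start−5:start]; '−': reverse
complement of scaffold[end:end+5]); observations closer than 5 bp to a
scaffold end are flagged incomplete and excluded from counts but listed.
Observations are deduplicated to unique (scaffold, start, end, strand)
locations before counting, so multiply-targeted locations count once.
The motif is the upstream dinucleotide at positions −2,−1 (the PAM length
reported for this effector family); the full 5-bp flank feeds the PFM and
per-position information content 2 + Σ_b f_b log₂ f_b. Motifs with
count/n ≥ 0.2 are called, ordered by count then lexicographically. The
0.2 floor keeps singleton flanks out of the call at the n ≈ 12–39
location counts typical here while accepting a genuine secondary motif
(e.g. TG at 4/12).

## Read-level evidence

The internal mapper is exact-31-mer-seeded (three seed offsets per read),
ungapped, substitution-only, with a short-deletion rescue: when the left
and right seeds of an otherwise unmappable read place at offsets differing
by 1–5 bp, the read is aligned as two segments around the deletion,
localized greedily at the first disagreement (equivalently, right-aligned
in a homopolymer). Pairs with ≥ 2 substitution mismatches combined across
both mates are discarded — the population-curation filter this package
standardizes on; deletions are not counted against the pair budget.
Coverage counts aligned bases of retained pairs only, so Σ depth equals
the aligned base total exactly.

Prophage activity compares mean depth inside a supplied region against up
to 2 kb of flank on each side. The ratio threshold for calling free
particles is 3.0 and the alternative circularity route needs ≥ 3
junction-consistent observations; both are exposed configuration, chosen
as conservative defaults since "much higher coverage" has no canonical
cutoff. Prophage boundaries are user- or truth-supplied, not inferred.
Circularity support counts read pairs with the '+' mate in the terminal
window and the '−' mate in the initial window (outward orientation, only
consistent with a fragment spanning the junction of a circular template),
plus unmapped reads whose prefix matches the scaffold end and suffix its
start.

Variant calling is a per-column pileup over a supplied gene region:
substitutions with alt/(alt+ref) ≥ 0.1 at depth ≥ 10, plus deletions from
rescued split alignments. For a deletion, reference support counts only
reads matching the reference exactly across the full homopolymer context
plus one anchor base each side — reads starting or ending inside the run,
or aligned shifted across it, are consistent with both alleles and carry
no information. Every alt is applied in silico to the gene frame and
translated: a new stop at the altered codon is `nonsense`, a stop exposed
by a length-changing allele is `frameshift_stop`, and the stop offset is
reported in codons from the variant codon. Consequence labels therefore
agree with direct translation of the mutated haplotype by construction,
which the tests cross-check against generator truth.

Fragmented genes: each candidate ORF translation is locally aligned to the
reference protein (match 2, mismatch −1, gap −2). Fragments must align
≥ 15 aa at ≥ 1.5 score/aa; a fragmentation is called when the accepted
fragments cover ordered reference segments (≤ 5 aa overlap) with combined
coverage ≥ 0.6. The score floor corresponds to ≥ ~83% identity over the
aligned block, which random proteins do not reach at ≥ 15 aa.

## Synthetic data: what it emulates, and what it does not

The generator plants: (1) a host CRISPR locus (default 21-nt repeat,
18–20-nt spacers) with haplotype-specific leader additions and unit
losses at specified frequencies; (2) protospacers as exact spacer copies
with a 5′ PAM dinucleotide on the targeted strand, non-overlapping, on
phage and host scaffolds; (3) an integrated prophage with free circular
copies at a configured coverage excess; (4) a protein-coding gene whose
planted homopolymer deletion shifts the frame onto a stop exactly five
codons downstream and whose C→T substitution creates an immediate stop,
at configured population fractions (defaults 1.00 and 0.82). Planted
spacers are rejected if any ≥ 16-base alignment against the repeat
(either orientation, any shift) has ≤ 2 mismatches, so the repeat/spacer
architecture stays well defined. Reads are Illumina-like 150-bp pairs
(insert 300 ± 30) with uniform fragment starts proportional to
abundance × length, wrap-around fragments for circular genomes, optional
uniform substitution errors (default 0), constant 'I' qualities, and
byte-identical regeneration per seed.

Background sequence is i.i.d. at 33% GC, matching the low-GC genomes this
package was designed around and keeping motif statistics analyzable.

Deliberately not emulated: base-quality structure, indel sequencing
errors, chimeric fragments, strain-variable repeat sequences, assembly
artifacts. Passing the recovery suite therefore demonstrates correctness
of the inference machinery under clean population structure — not
robustness to assembly error or sequencing noise, which on real data is
handled upstream (QC, assembly polishing) or by the standard
alignment-format escape hatch into the evidence layers.

In the main study scenario the six leader additions are carried by six
equal-frequency subpopulations (1/6 each): every cell carries the shared
16-spacer core plus exactly one recent acquisition, the regime in which
recent spacers are rare enough to be interesting but recoverable at 50×.
The deletion and substitution sites sit ~230 bp apart so that no 150-bp
read spans both.

## Problem sizes and determinism

Scenario scaffolds are 6–20 kb and read sets 7–10 k pairs (50× host
coverage); the acceptance script additionally scans 10 × 1 Mb random
scaffolds for false arrays and 10 × 50 kb instances for oracle agreement.
These sizes were chosen so that the full suite and the acceptance script
each complete in well under a minute on one CPU while keeping every
binomial recovery check adequately powered. All randomness flows from
numpy `default_rng` seeds; scenario builders derive stage seeds from a
single parent seed, and reports exclude wall-clock and path information so
that reruns are byte-identical.

## Known limitations

* Ungapped mapping with deletion-only rescue: insertions relative to the
  reference are not placed (reads spanning a subpopulation's added spacer
  junction are simply dropped from coverage; the locus stage recovers
  them separately from raw reads).
* One locus per reconstruction: the pipeline reconstructs the array with
  the most units; multiple coexisting loci require separate invocations
  with their own repeat consensus.
* Exact-interval deduplication of PAM locations; overlapping but
  non-identical target locations count separately.
* The consensus trim assumes recent additions are minority features; a
  leader spacer swept to > ~half the population is reported as consensus,
  which is arguably the correct call at that frequency.
* Self-targeting requires a bin assignment for both the array's scaffold
  and the target; unbinned targets are only tallied as unresolved.
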