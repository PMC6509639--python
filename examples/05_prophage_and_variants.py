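"""Read-level evidence: prophage activity, circularity, disruptive variants.

Maps pairs with the <=1-combined-mismatch filter, compares prophage-region
to flanking coverage, counts junction-spanning evidence for a circular
template, and calls the two planted gene-disrupting mutations with their
population fractions.
"""

from spacertrace import evidence as ev
from spacertrace.scenarios import scenario_fcasy, scenario_prophage
from spacertrace.types import Region

# prophage + free circular phage at 8x copy excess
sc = scenario_prophage(seed=3)
mp = ev.map_reads(sc.reads, sc.scaffolds)
_, start, end = sc.truth.prophage_region
call = ev.prophage_activity_call(mp.coverage["host"], Region(start, end))
print(f"prophage region    : host:{start}-{end}")
print(f"coverage ratio     : {call.ratio:.2f} (planted excess "
      f"{sc.truth.prophage_copy_excess}x) -> {call.state}")

phage = sc.truth.extras["phage_sequence"]
mp2 = ev.map_reads(sc.reads, {"phage": phage})
support = ev.detect_circularity(
    mp2.pairs, "phage", len(phage),
    unmapped_reads=mp2.unmapped_reads, scaffold_seq=phage,
)
print(f"circular support   : {support} junction-consistent observations")

# fragmented effector gene: deletion in all cells, substitution in 82%
fc = scenario_fcasy(seed=1)
mp3 = ev.map_reads(fc.reads, fc.scaffolds)
g0, g1 = fc.truth.extras["gene_region"]
variants = ev.call_disrupting_variants(
    mp3.pairs, fc.scaffolds["host1"], "host1", Region(g0, g1)
)
for v in variants:
    kind = "deletion" if not v.alt else f"{v.ref}->{v.alt}"
    print(f"variant            : {kind} at {v.position}, "
          f"{100 * v.alt_fraction:.0f}% of reads, {v.consequence}"
          + (f", stop {v.stop_offset_codons} codons downstream"
             if v.stop_offset_codons else ""))
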