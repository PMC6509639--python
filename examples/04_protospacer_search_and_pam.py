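"""Link spacers to targets and infer the PAM.

Spacers are dereplicated and searched full-length, zero-mismatch, on both
strands of every scaffold; hits inside any array span are excluded, hits in
the host's own bin are flagged self-targeting, and the 5-bp upstream flanks
of unique target locations yield the PAM motif call.
"""

from spacertrace import (
    build_pam_summary,
    call_pam_motifs,
    dereplicate_spacers,
    exclude_array_self_hits,
    extract_pam_observation,
    find_arrays,
    find_protospacer_hits,
    flag_self_targeting,
)
from spacertrace.scenarios import scenario_fcasy
from spacertrace.types import Spacer

sc = scenario_fcasy(seed=1)
arrays = find_arrays(sc.scaffolds["host1"], scaffold_id="host1")

catalog = dereplicate_spacers(
    [Spacer(sequence=s, array_id=arrays[0].array_id)
     for s in sc.truth.spacer_catalog.values()]
)
hits = find_protospacer_hits(catalog, sc.scaffolds, max_mismatch=0)
kept, excluded = exclude_array_self_hits(hits, arrays)
self_records, _ = flag_self_targeting(
    kept, sc.bins, arrays, dict(catalog.source_array), sc.annotations
)

print(f"catalog        : {len(catalog)} unique spacers")
print(f"hits           : {len(kept)} (plus {len(excluded)} inside the source array)")
print(f"self-targeting : {len({r.spacer_id for r in self_records})} spacers, e.g. "
      f"{self_records[0].target_gene or 'intergenic'}")

self_ids = {r.spacer_id for r in self_records}
obs = [extract_pam_observation(h, sc.scaffolds[h.target_scaffold])
       for h in kept if h.spacer_id in self_ids]
summary = build_pam_summary(obs)
print(f"self-target PAM: {summary.motif_counts} over {summary.n_locations} locations")
print(f"motif call     : {call_pam_motifs(summary)}  "
      "(the 5' dinucleotide adjacent to the protospacer)")
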